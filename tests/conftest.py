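import numpy as np
import pytest

from clonetrack import (BranchSpec, SimulationConfig, simulate_patient,
                        synthetic_signature_catalog)


@pytest.fixture(scope="session")
def catalog():
    """Synthetic 27-signature catalogue in the COSMIC 96-channel layout."""
    return synthetic_signature_catalog(K=27, seed=20170814)


@pytest.fixture(scope="session")
def small_catalog():
    return synthetic_signature_catalog(K=8, seed=11)


def two_sample_config(seed=42, depth=80.0, trunk_n=300, sub_n=300,
                      sub_ccfs=((0.5, 0.0), (0.0, 0.6)), purity=1.0,
                      wgd=False, wgd_time=0.5, n_null=0):
    """Two-sample patient: trunk plus subclones private to each sample."""
    samples = ["P", "R"]
    branches = [BranchSpec("trunk", None, {"P": 1.0, "R": 1.0}, trunk_n,
                           {"Signature 1": 0.4, "Signature 3": 0.6})]
    for k, (cp, cr) in enumerate(sub_ccfs):
        branches.append(BranchSpec(f"sub{k}", "trunk", {"P": cp, "R": cr}, sub_n,
                                   {"Signature 2": 1.0}))
    return SimulationConfig(samples=samples, branches=branches,
                            purity={"P": purity, "R": purity},
                            depth_mean=depth, wgd=wgd, wgd_time_true=wgd_time,
                            n_null_sites=n_null, seed=seed)


@pytest.fixture(scope="session")
def two_cluster_patient():
    """One well-separated subclone under the trunk, depth 80."""
    return simulate_patient(two_sample_config(seed=42, sub_ccfs=((0.5, 0.0),)))


@pytest.fixture(scope="session")
def chain_config():
    """trunk -> A -> B nested chain with clear CCF gaps."""
    samples = ["P", "R"]
    branches = [
        BranchSpec("trunk", None, {"P": 1.0, "R": 1.0}, 300,
                   {"Signature 1": 1.0}),
        BranchSpec("A", "trunk", {"P": 0.6, "R": 0.9}, 250, {"Signature 2": 1.0}),
        BranchSpec("B", "A", {"P": 0.3, "R": 0.2}, 250, {"Signature 3": 1.0}),
    ]
    return SimulationConfig(samples=samples, branches=branches,
                            purity={"P": 1.0, "R": 1.0}, depth_mean=80.0, seed=7)
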