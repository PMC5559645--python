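"""Synthetic multi-sample tumour cohorts with known ground truth.

A patient is specified by a clone tree (one trunk plus nested/sibling
subclones), per-sample CCFs for every branch, per-sample purity, an
optional whole-genome duplication with a true relative timing, and a
signature mixture per branch.  Read counts at each mutation are drawn
binomially at Poisson-distributed depth from the expected VAF implied by
purity, copy number, multiplicity and the branch CCF, so that every
downstream stage (QC, clustering, tree building, WGD timing, signature
refitting) can be tested by parameter recovery.

What this emulates — and what it does not — is described in the package
methods note; in particular segments are uniform per sample (diploid, or
tetraploid under WGD) and mutation positions are uniform on a single
synthetic chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, parse_channel
from .exceptions import ConfigurationError
from .io import (MutationTable, SegmentTable, SignatureCatalog,
                 read_mutation_table, read_segments, write_mutation_table,
                 write_segments)

__all__ = [
    "BranchSpec", "SimulationConfig", "SyntheticPatient",
    "simulate_patient", "sample_spectrum", "write_fixture", "read_fixture",
    "synthetic_signature_catalog",
]

GENOME_LENGTH = 100_000_000  # single synthetic chromosome "1"


@dataclass
class BranchSpec:
    """One branch of the true clone tree."""

    branch_id: str
    parent: str | None                    # None marks the trunk
    ccf: dict[str, float]                 # per-sample true CCF
    n_mutations: int
    signature_weights: dict[str, float]   # mixture over catalogue signatures


@dataclass
class SimulationConfig:
    samples: list[str]
    branches: list[BranchSpec]
    purity: dict[str, float]
    depth_mean: float = 40.0
    wgd: bool = False
    wgd_time_true: float = 0.5
    error_rate: float = 0.005
    n_null_sites: int = 0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 2 <= len(self.samples) <= 8:
            raise ConfigurationError("need 2-8 samples per patient")
        for s in self.samples:
            if s not in self.purity:
                raise ConfigurationError(f"no purity for sample {s}")
            if not 0.1 <= self.purity[s] <= 1.0:
                raise ConfigurationError(f"purity of {s} outside [0.1, 1.0]")
        by_id = {b.branch_id: b for b in self.branches}
        trunks = [b for b in self.branches if b.parent is None]
        if len(trunks) != 1:
            raise ConfigurationError("exactly one trunk (parent=None) required")
        trunk = trunks[0]
        for s in self.samples:
            if abs(trunk.ccf.get(s, 0.0) - 1.0) > 1e-9:
                raise ConfigurationError(f"trunk CCF must be 1.0 in sample {s}")
        for b in self.branches:
            if b.parent is not None:
                if b.parent not in by_id:
                    raise ConfigurationError(f"branch {b.branch_id}: unknown parent {b.parent}")
                parent = by_id[b.parent]
                for s in self.samples:
                    if b.ccf.get(s, 0.0) > parent.ccf.get(s, 0.0) + 1e-9:
                        raise ConfigurationError(
                            f"branch {b.branch_id}: CCF {b.ccf.get(s, 0.0)} exceeds "
                            f"parent {b.parent} CCF {parent.ccf.get(s, 0.0)} in sample {s}")
            w = np.array(list(b.signature_weights.values()), dtype=float)
            if (w < 0).any():
                raise ConfigurationError(f"branch {b.branch_id}: negative signature weight")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"branch {b.branch_id}: weights sum to {w.sum()}")
        if not 0.0 <= self.wgd_time_true <= 1.0:
            raise ConfigurationError("wgd_time_true must lie in [0, 1]")
        if not 0.0 < self.error_rate < 1.0:
            raise ConfigurationError("error_rate must lie in (0, 1)")

    @property
    def trunk(self) -> BranchSpec:
        return next(b for b in self.branches if b.parent is None)


@dataclass
class SyntheticPatient:
    mutations: MutationTable
    segments: SegmentTable
    purity: dict[str, float]
    truth: pd.DataFrame
    config: SimulationConfig

    def truth_branch_sizes(self) -> pd.Series:
        real = self.truth[self.truth["branch_id"] != "none"]
        return real.groupby("branch_id").size()


def sample_spectrum(weights, catalog: SignatureCatalog, n_mut: int, rng) -> np.ndarray:
    """Multinomial 96-channel counts from a signature mixture.

    ``weights`` maps signature names (columns of ``catalog``) to
    non-negative weights summing to one.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    w = np.array([weights.get(name, 0.0) for name in catalog.names], dtype=float)
    if (w < 0).any():
        raise ValueError("negative signature weight")
    missing = set(weights) - set(catalog.names)
    if missing:
        raise ValueError(f"weights refer to unknown signatures {sorted(missing)}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()}, expected 1")
    if n_mut == 0:
        return np.zeros(96, dtype=int)
    probs = catalog.matrix() @ w
    probs = probs / probs.sum()
    return rng.multinomial(n_mut, probs)


def synthetic_signature_catalog(K: int = 27, seed: int = 20170814,
                                sparsity: float = 1.0) -> SignatureCatalog:
    """Generate a synthetic signature catalogue in the COSMIC layout.

    Columns are sparse Dirichlet draws over the 96 channels, one per
    signature, named ``Signature 1`` .. ``Signature K``.  This is a
    synthetic stand-in for a consensus catalogue, for tests and
    simulations; real analyses should load a published catalogue with
    :func:`clonetrack.io.read_signature_catalog`.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(K):
        active = rng.choice(96, size=rng.integers(6, 18), replace=False)
        col = np.zeros(96)
        col[active] = rng.dirichlet(np.full(len(active), sparsity))
        # small floor keeps every channel possible without flattening the shape
        col = 0.995 * col + 0.005 / 96
        cols[f"Signature {k + 1}"] = col
    df = pd.DataFrame(cols, index=list(CHANNELS))
    return SignatureCatalog(df)


def _mutation_rows_for_branch(branch, channels, rng, start_id):
    rows = []
    for k, chan in enumerate(channels):
        ref, alt, context = parse_channel(chan)
        rows.append({
            "mutation_id": f"mut{start_id + k:06d}",
            "chrom": "1",
            "pos": 0,  # filled later
            "ref": ref, "alt": alt, "var_class": "substitution",
            "gene": "", "consequence": "", "context": context,
        })
    return rows


def simulate_patient(config: SimulationConfig,
                     catalog: SignatureCatalog | None = None) -> SyntheticPatient:
    """Draw one synthetic patient.

    Deterministic given ``config.seed``.  Clonal (trunk) mutations on a
    duplicated genome carry multiplicity two with probability
    ``t / (2 - t)`` for true WGD time ``t`` — the pre-duplication
    fraction implied by the timing estimator — and multiplicity one
    otherwise; subclonal mutations always have multiplicity one.
    """
    config.validate()
    if catalog is None:
        catalog = synthetic_signature_catalog()
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    total_cn = 4 if config.wgd else 2
    minor_cn = 2 if config.wgd else 1

    seg_rows = [{"sample": s, "chrom": "1", "start": 0, "end": GENOME_LENGTH,
                 "total_cn": total_cn, "minor_cn": minor_cn, "frac": 1.0}
                for s in samples]
    segments = SegmentTable(pd.DataFrame(seg_rows))

    rows, truth_rows = [], []
    counter = 0
    for b in config.branches:
        # per-mutation generating signature, then a channel from its column
        names = list(b.signature_weights)
        w = np.array([b.signature_weights[nm] for nm in names])
        sig_idx = rng.choice(len(names), size=b.n_mutations, p=w / w.sum())
        mat = catalog.matrix()
        chan_labels = []
        for k in range(b.n_mutations):
            col = mat[:, catalog.names.index(names[sig_idx[k]])]
            chan_labels.append(CHANNELS[rng.choice(96, p=col)])
        rows_b = _mutation_rows_for_branch(b, chan_labels, rng, counter)

        is_trunk = b.parent is None
        if config.wgd and is_trunk:
            t = config.wgd_time_true
            pre_frac = t / (2.0 - t) if t > 0 else 0.0
            mult = np.where(rng.uniform(size=b.n_mutations) < pre_frac, 2, 1)
        else:
            mult = np.ones(b.n_mutations, dtype=int)

        for k, row in enumerate(rows_b):
            for s in samples:
                rho = config.purity[s]
                f = rho * mult[k] * b.ccf.get(s, 0.0) / (rho * total_cn + 2 * (1 - rho))
                n = max(int(rng.poisson(config.depth_mean)), 1)
                X = int(rng.binomial(n, min(f, 1.0)))
                row[f"X:{s}"] = X
                row[f"n:{s}"] = n
            truth_rows.append({
                "mutation_id": row["mutation_id"], "branch_id": b.branch_id,
                "multiplicity": int(mult[k]),
                "signature_id": names[sig_idx[k]],
                **{f"true_ccf:{s}": b.ccf.get(s, 0.0) for s in samples},
            })
        rows.extend(rows_b)
        counter += b.n_mutations

    # null sites exercising presence calling: no true mutation, error reads only
    for k in range(config.n_null_sites):
        row = {"mutation_id": f"null{k:05d}", "chrom": "1", "pos": 0,
               "ref": "C", "alt": "T", "var_class": "substitution",
               "gene": "", "consequence": "", "context": "ACA"}
        for s in samples:
            n = max(int(rng.poisson(config.depth_mean)), 1)
            row[f"X:{s}"] = int(rng.binomial(n, config.error_rate))
            row[f"n:{s}"] = n
        rows.append(row)
        truth_rows.append({"mutation_id": row["mutation_id"], "branch_id": "none",
                           "multiplicity": 0, "signature_id": "none",
                           **{f"true_ccf:{s}": 0.0 for s in samples}})

    positions = rng.choice(np.arange(1, GENOME_LENGTH + 1), size=len(rows), replace=False)
    positions.sort()
    for row, pos in zip(rows, positions):
        row["pos"] = int(pos)

    cols = ["mutation_id", "chrom", "pos", "ref", "alt", "var_class",
            "gene", "consequence", "context"]
    cols += [f"{p}:{s}" for s in samples for p in ("X", "n")]
    mutations = MutationTable(pd.DataFrame(rows, columns=cols), list(samples))
    truth_cols = (["mutation_id", "branch_id", "multiplicity", "signature_id"]
                  + [f"true_ccf:{s}" for s in samples])
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return SyntheticPatient(mutations, segments, dict(config.purity), truth, config)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(patient: SyntheticPatient, directory) -> dict[str, Path]:
    """Write mutation, segment, purity and truth tables as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": directory / "mutations.tsv",
        "segments": directory / "segments.tsv",
        "purity": directory / "purity.tsv",
        "truth": directory / "truth.tsv",
    }
    write_mutation_table(patient.mutations, paths["mutations"])
    write_segments(patient.segments, paths["segments"])
    pd.DataFrame({"sample": list(patient.purity),
                  "purity": list(patient.purity.values())}
                 ).to_csv(paths["purity"], sep="\t", index=False)
    patient.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_fixture(directory):
    """Read back a fixture directory; returns (mutations, segments, purity, truth)."""
    directory = Path(directory)
    mutations = read_mutation_table(directory / "mutations.tsv")
    segments = read_segments(directory / "segments.tsv")
    pur = pd.read_csv(directory / "purity.tsv", sep="\t")
    purity = dict(zip(pur["sample"], pur["purity"]))
    truth = pd.read_csv(directory / "truth.tsv", sep="\t")
    return mutations, segments, purity, truth
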