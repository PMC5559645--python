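import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from clonetrack import (DirichletProcessCCF, estimate_multiplicity,
                        expected_vaf, qc_filter, simulate_patient)
from clonetrack.exceptions import ConfigurationError
from clonetrack.io import MutationTable, SegmentTable

from conftest import two_sample_config


class TestExpectedVaf:
    def test_early_clonal_tetraploid(self):
        assert expected_vaf(1.0, 4, 2, 1.0) == pytest.approx(0.5)

    def test_hand_evaluated_case(self):
        # rho=0.5, c=4, m=1, p=0.8 -> 0.5*0.8 / (0.5*4 + 2*0.5) = 0.4/3
        assert expected_vaf(0.5, 4, 1, 0.8) == pytest.approx(0.4 / 3)

    def test_low_purity_limit(self):
        assert expected_vaf(1e-9, 2, 1, 1.0) < 1e-8

    def test_monotone_in_all_arguments(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rho = rng.uniform(0.1, 1.0)
            c = rng.integers(1, 8)
            m = rng.integers(1, c + 1)
            p = rng.uniform(0, 1)
            f = expected_vaf(rho, c, m, p)
            assert 0 <= f <= 1
            if p < 0.999:
                assert expected_vaf(rho, c, m, min(p + 0.001, 1.0)) >= f
            if m < c:
                assert expected_vaf(rho, c, m + 1, p) >= f
            if m * p < c and rho < 0.999:
                assert expected_vaf(min(rho + 0.001, 1.0), c, m, p) >= f

    def test_multiplicity_cannot_exceed_copies(self):
        with pytest.raises(ValueError, match="multiplicity"):
            expected_vaf(1.0, 2, 3, 1.0)


class TestEstimateMultiplicity:
    @pytest.mark.parametrize("X,n,rho,c,expected_m", [
        (50, 100, 1.0, 2, 1),
        (50, 100, 1.0, 4, 2),   # VAF 0.5 on tetraploid: two mutated copies
        (25, 100, 1.0, 4, 1),
    ])
    def test_enumeration_against_residual_oracle(self, X, n, rho, c, expected_m):
        m, ccf = estimate_multiplicity(X, n, rho, c)
        assert m == expected_m
        # oracle: brute-force residual minimisation when CCF(m=1) is superclonal
        vaf = X / n
        denom = rho * c + 2 * (1 - rho)
        if vaf * denom / rho <= 1.2:
            assert m == 1
        else:
            resid = [abs(vaf - rho * mm / denom) for mm in range(1, c + 1)]
            assert m == 1 + int(np.argmin(resid))

    def test_untyped_site(self):
        m, ccf = estimate_multiplicity(0, 0, 1.0, 2)
        assert m == 1 and np.isnan(ccf)


def _patient_with_segments(seg_rows):
    cfg = two_sample_config(seed=3, trunk_n=30, sub_n=0, sub_ccfs=())
    pat = simulate_patient(cfg)
    pat = pat.__class__(pat.mutations, SegmentTable(pd.DataFrame(seg_rows)),
                        pat.purity, pat.truth, pat.config)
    return pat


class TestQcFilter:
    def test_lost_region_and_undefined_cn(self):
        cfg = two_sample_config(seed=3, trunk_n=50, sub_n=0, sub_ccfs=())
        pat = simulate_patient(cfg)
        pos = pat.mutations.df["pos"]
        lo, hi = int(pos.min()), int(pos.max())
        third = (hi - lo) // 3
        # P: diploid everywhere; R: first third deleted, middle third missing
        rows = [{"sample": "P", "chrom": "1", "start": 0, "end": 10**9,
                 "total_cn": 2, "minor_cn": 1, "frac": 1.0},
                {"sample": "R", "chrom": "1", "start": 0, "end": lo + third,
                 "total_cn": 0, "minor_cn": 0, "frac": 1.0},
                {"sample": "R", "chrom": "1", "start": lo + 2 * third, "end": 10**9,
                 "total_cn": 2, "minor_cn": 1, "frac": 1.0}]
        pat = _patient_with_segments(rows)
        retained, excluded, stats = qc_filter(pat.mutations, pat.segments, pat.purity)
        assert set(excluded["reason"]) <= {"lost-region", "undefined-CN"}
        lost = excluded[excluded["reason"] == "lost-region"]
        undef = excluded[excluded["reason"] == "undefined-CN"]
        assert (lost["pos"] <= lo + third).all()
        assert len(lost) > 0 and len(undef) > 0
        # fully covered diploid mutations are retained with c and m columns
        assert (retained["pos"] > lo + 2 * third - 1).all()
        assert (retained["c:P"] == 2).all() and (retained["m:P"] == 1).all()
        assert stats["n_retained"] + len(excluded) == stats["n_total"]

    def test_default_synthetic_config_retains_most(self, two_cluster_patient):
        _, _, stats = qc_filter(two_cluster_patient.mutations,
                                two_cluster_patient.segments,
                                two_cluster_patient.purity)
        assert stats["retained_fraction"] > 0.77

    def test_zero_retained_warns_not_raises(self):
        rows = [{"sample": "P", "chrom": "1", "start": 0, "end": 10**9,
                 "total_cn": 0, "minor_cn": 0, "frac": 1.0},
                {"sample": "R", "chrom": "1", "start": 0, "end": 10**9,
                 "total_cn": 2, "minor_cn": 1, "frac": 1.0}]
        pat = _patient_with_segments(rows)
        with pytest.warns(UserWarning, match="no mutations retained"):
            retained, excluded, stats = qc_filter(pat.mutations, pat.segments,
                                                  pat.purity)
        assert len(retained) == 0 and stats["n_retained"] == 0


def _em_binomial_mixture_1d(X, n, fs, iters=500):
    """Independent oracle: 1-D EM for a binomial mixture with free success
    probabilities, initialised from the true component VAFs."""
    X, n = np.asarray(X, float), np.asarray(n, float)
    fs = np.array(fs, float)
    pis = np.full(len(fs), 1 / len(fs))
    for _ in range(iters):
        lik = binom.pmf(X[:, None], n[:, None], fs[None, :]).clip(1e-300)
        R = lik * pis
        R /= R.sum(axis=1, keepdims=True)
        pis = R.mean(axis=0)
        fs = (R * X[:, None]).sum(axis=0) / (R * n[:, None]).sum(axis=0)
    return fs, pis


class TestDirichletProcess:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(12)
        N = 300
        n = rng.poisson(100, (N, 2)).clip(1)
        X = rng.binomial(n, 0.5)  # clonal diploid at purity 1
        model = DirichletProcessCCF(X, n, np.full((N, 2), 2), np.ones((N, 2)),
                                    [1.0, 1.0])
        res = model.fit(sweeps=300, burn_in=150, seed=0)
        sizes = res.clusters["n_mutations"]
        assert sizes.max() >= 0.99 * N

    def test_two_cluster_recovery_vs_truth(self, two_cluster_patient):
        pat = two_cluster_patient
        retained, _, _ = qc_filter(pat.mutations, pat.segments, pat.purity)
        model = DirichletProcessCCF.from_dataframe(retained, pat.purity,
                                                   samples=["P", "R"])
        res = model.fit(sweeps=400, burn_in=200, seed=1)
        truth = pat.truth.set_index("mutation_id").loc[res.mutation_ids, "branch_id"]
        df = pd.DataFrame({"truth": truth.values, "inferred": res.labels_})
        # majority mapping accuracy
        acc = (df.groupby("inferred")["truth"]
               .agg(lambda g: (g == g.mode()[0]).sum()).sum()) / len(df)
        assert res.n_clusters == 2
        assert acc >= 0.90
        # trunk cluster CCF credible interval covers 1.0 in both samples
        trunk_row = res.clusters.loc[res.clusters[[f"ccf:{s}" for s in "PR"]]
                                     .sum(axis=1).idxmax()]
        for s in ["P", "R"]:
            assert trunk_row[f"ci_low:{s}"] <= 1.0 <= trunk_row[f"ci_high:{s}"] + 0.2

    def test_one_sample_matches_em_oracle(self):
        rng = np.random.default_rng(8)
        N = 400
        n = rng.poisson(120, N).clip(1)
        comp = rng.uniform(size=N) < 0.5
        X = np.where(comp, rng.binomial(n, 0.5), rng.binomial(n, 0.2))
        model = DirichletProcessCCF(X[:, None], n[:, None],
                                    np.full((N, 1), 2), np.ones((N, 1)), [1.0])
        res = model.fit(sweeps=400, burn_in=200, seed=2)
        fs, _ = _em_binomial_mixture_1d(X, n, [0.45, 0.25])
        oracle_ccfs = sorted(2 * fs)  # p = f * c / (rho * m) at rho=1, c=2, m=1
        got = sorted(res.clusters["ccf:S0"])
        assert len(got) == 2
        assert abs(got[0] - oracle_ccfs[0]) < 0.05
        assert abs(got[1] - min(oracle_ccfs[1], 1.0)) < 0.05

    def test_input_order_invariance(self, two_cluster_patient):
        pat = two_cluster_patient
        retained, _, _ = qc_filter(pat.mutations, pat.segments, pat.purity)
        retained = retained.iloc[:150]
        model = DirichletProcessCCF.from_dataframe(retained, pat.purity,
                                                   samples=["P", "R"])
        res = model.fit(sweeps=150, burn_in=100, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(retained))
        model2 = DirichletProcessCCF.from_dataframe(
            retained.iloc[perm].reset_index(drop=True), pat.purity,
            samples=["P", "R"])
        res2 = model2.fit(sweeps=150, burn_in=100, seed=5)
        a = pd.Series(res.labels_, index=res.mutation_ids)
        b = pd.Series(res2.labels_, index=res2.mutation_ids)
        assert (a.sort_index() == b.sort_index()).all()

    def test_sweeps_must_exceed_burn_in(self):
        model = DirichletProcessCCF([[5]], [[10]], [[2]], [[1]], [1.0])
        with pytest.raises(ConfigurationError, match="burn_in"):
            model.fit(sweeps=100, burn_in=100)
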