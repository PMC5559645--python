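"""Relative timing of whole-genome duplication from clonal mutations.

On a duplicated (tetraploid, c = 4) genome, trunk mutations fall into
three kinds of state: early-clonal (acquired before duplication, so
present on two copies: m = 2, p = 1), late-clonal (m = 1, p = 1) and
subclonal (m = 1, p < 1).  Variant reads are binomial at the expected
VAF of each state, giving a finite binomial mixture whose proportions
``pi`` are estimated by EM.  The relative molecular time of duplication
is

    t = 2 * pi_early / (2 * pi_early + pi_late)

— the early proportion rescaled for the doubled mutation target after
duplication.  Confidence intervals come from a percentile bootstrap over
mutations (100 resamples by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .ccf import expected_vaf

__all__ = ["wgd_time", "WGDTimingModel", "WGDTimingResults"]


def wgd_time(pi_early: float, pi_late: float) -> float:
    """Relative WGD time from early/late clonal mixture proportions."""
    if pi_early < 0 or pi_late < 0:
        raise ValueError("mixture proportions must be non-negative")
    if pi_early == 0 and pi_late == 0:
        raise ValueError("t undefined when both clonal proportions are zero")
    return 2.0 * pi_early / (2.0 * pi_early + pi_late)


@dataclass
class WGDTimingResults:
    """EM estimates of mixture proportions and the implied WGD time."""

    t_: float
    ci_: tuple[float, float]
    pi_: np.ndarray
    state_names: list[str]
    state_vafs: np.ndarray
    loglik_: float
    loglik_trace_: np.ndarray
    posteriors_: np.ndarray
    n_mutations: int
    n_bootstrap: int
    bootstrap_t_: np.ndarray | None = None

    @property
    def pi_early(self) -> float:
        return float(self.pi_[self.state_names.index("early")])

    @property
    def pi_late(self) -> float:
        return float(self.pi_[self.state_names.index("late")])

    def summary(self) -> str:
        lines = ["Whole-genome duplication timing (binomial mixture EM)",
                 "=" * 56,
                 f"mutations: {self.n_mutations}   log-likelihood: {self.loglik_:.2f}",
                 f"{'state':>12} {'E[VAF]':>8} {'pi':>8}"]
        for name, f, pi in zip(self.state_names, self.state_vafs, self.pi_):
            lines.append(f"{name:>12} {f:8.4f} {pi:8.4f}")
        lines.append(f"\nrelative WGD time t = {self.t_:.3f} "
                     f"(95% CI {self.ci_[0]:.3f}-{self.ci_[1]:.3f}, "
                     f"{self.n_bootstrap} bootstrap resamples)")
        return "\n".join(lines)


class WGDTimingModel:
    """Binomial mixture over early/late/subclonal states on a tetraploid
    genome.

    Parameters
    ----------
    X, n : arrays of variant reads and depths for clonal trunk mutations
        on copy-number-constant tetraploid segments.
    purity : tumour purity of the sample.
    subclonal_ccfs : CCFs of known subclones (from the clustering stage),
        each contributing a subclonal state with m = 1.
    c : total copy number; timing is defined for duplicated genomes and
        only c = 4 is accepted.
    """

    def __init__(self, X, n, purity: float, subclonal_ccfs=(), c: int = 4):
        if c != 4:
            raise ValueError("WGD timing is defined on tetraploid regions (c = 4)")
        self.X = np.asarray(X, dtype=int)
        self.n = np.asarray(n, dtype=int)
        if self.X.shape != self.n.shape or self.X.ndim != 1:
            raise ValueError("X and n must be 1-D arrays of equal length")
        if np.any(self.X > self.n):
            raise ValueError("variant reads exceed depth")
        if np.all(self.X == 0):
            raise ValueError("all variant read counts are zero")
        if len(self.X) < 20:
            warnings.warn("fewer than 20 mutations: timing will be unstable")
        self.purity = float(purity)
        self.c = c

        names = ["early", "late"]
        fs = [expected_vaf(self.purity, c, 2, 1.0), expected_vaf(self.purity, c, 1, 1.0)]
        for k, p in enumerate(subclonal_ccfs):
            names.append(f"subclonal_{k}")
            fs.append(expected_vaf(self.purity, c, 1, float(p)))
        fs = np.array(fs)
        keep = np.ones(len(fs), dtype=bool)
        for i in range(len(fs)):
            for j in range(i + 1, len(fs)):
                if keep[j] and abs(fs[i] - fs[j]) < 1e-9:
                    keep[j] = False
                    warnings.warn(f"state {names[j]} has the same expected VAF as "
                                  f"{names[i]}; collapsed")
        self.state_names = [nm for nm, k in zip(names, keep) if k]
        self.state_vafs = fs[keep]

    # -- EM -----------------------------------------------------------------

    def _emission(self, X, n):
        # (N, S) likelihoods, clipped away from zero for stability
        B = binom.pmf(X[:, None], n[:, None], self.state_vafs[None, :])
        return np.maximum(B, 1e-300)

    def _em(self, B, pi0, max_iter=1000, tol=1e-8):
        pi = pi0.copy()
        trace = []
        for _ in range(max_iter):
            joint = B * pi[None, :]
            denom = joint.sum(axis=1, keepdims=True)
            ll = float(np.log(denom).sum())
            if trace and ll < trace[-1] - 1e-9:
                raise AssertionError("EM log-likelihood decreased")
            trace.append(ll)
            R = joint / denom
            new_pi = R.mean(axis=0)
            if np.max(np.abs(new_pi - pi)) < tol:
                pi = new_pi
                break
            pi = new_pi
        joint = B * pi[None, :]
        denom = joint.sum(axis=1, keepdims=True)
        trace.append(float(np.log(denom).sum()))
        return pi, np.array(trace), joint / denom

    def fit(self, n_restarts: int = 10, max_iter: int = 1000, tol: float = 1e-8,
            bootstrap: int = 100, seed=None, ci_level: float = 0.95
            ) -> WGDTimingResults:
        """Fit mixture proportions, the WGD time and its bootstrap CI."""
        if bootstrap < 2:
            raise ValueError("need at least 2 bootstrap resamples")
        rng = np.random.default_rng(seed)
        S = len(self.state_vafs)
        B = self._emission(self.X, self.n)

        def best_fit(Bmat, restarts):
            if Bmat.shape[1] == 1:
                pi = np.array([1.0])
                ll = float(np.log(Bmat[:, 0]).sum())
                return pi, np.array([ll, ll]), np.ones((Bmat.shape[0], 1))
            starts = [np.full(S, 1.0 / S)]
            starts += [rng.dirichlet(np.ones(S)) for _ in range(restarts - 1)]
            out = None
            for pi0 in starts:
                pi, trace, R = self._em(Bmat, pi0, max_iter, tol)
                if out is None or trace[-1] > out[1][-1]:
                    out = (pi, trace, R)
            return out

        pi, trace, R = best_fit(B, n_restarts)
        ie, il = self.state_names.index("early"), self.state_names.index("late")
        t_hat = wgd_time(pi[ie], pi[il])

        N = len(self.X)
        ts = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, N, size=N)
            pib, _, _ = best_fit(B[idx], max(2, n_restarts // 5))
            ts[b] = wgd_time(max(pib[ie], 0.0), max(pib[il], 0.0)) \
                if (pib[ie] > 0 or pib[il] > 0) else np.nan
        ts = ts[~np.isnan(ts)]
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(ts, [alpha, 1.0 - alpha])
        ci = (min(float(lo), t_hat), max(float(hi), t_hat))

        return WGDTimingResults(
            t_=float(t_hat), ci_=ci, pi_=pi,
            state_names=list(self.state_names), state_vafs=self.state_vafs.copy(),
            loglik_=float(trace[-1]), loglik_trace_=trace, posteriors_=R,
            n_mutations=N, n_bootstrap=bootstrap, bootstrap_t_=ts,
        )
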