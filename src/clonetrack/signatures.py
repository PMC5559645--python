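"""Refitting consensus mutational signatures to 96-channel spectra.

Exposures for a candidate signature subset are the non-negative
least-squares (NNLS) reconstruction of the observed spectrum from the
subset's catalogue columns, scored by the Pearson correlation ``r``
between the observed and reconstructed 96-vectors.  Model selection
evaluates subsets of size 1..7 exhaustively and applies three rules:

* a solution is inadmissible if any selected signature contributes less
  than 2% of the mutations or fewer than 50 mutations — except the
  designated "clock-like" signatures (Signatures 1 and 5 by default),
  which may remain at any exposure;
* among admissible solutions of one size, the best ``r`` wins;
* a larger size is preferred over the selected smaller one only when it
  improves ``r`` by at least 0.02 (a best-of-size ladder, ascending
  until the improvement rule first fails).

With a 27-signature catalogue the full search space is
sum_k C(27, k) for k = 1..7 = 1,285,623 candidate solutions; the ladder
stops enumerating larger sizes once they can no longer be selected,
and ``search="full"`` forces evaluation of every size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .channels import CHANNEL_INDEX, channel_of
from .io import SignatureCatalog

__all__ = [
    "count_combinations", "fit_exposures", "SignatureRefitModel",
    "ExposureResults", "branch_signatures",
]

DEFAULT_EXEMPT = ("Signature 1", "Signature 5")
MIN_BRANCH_MUTATIONS = 20


def count_combinations(K: int, max_size: int) -> int:
    """Number of candidate signature subsets of size 1..max_size from K."""
    if not 1 <= max_size <= K:
        raise ValueError("need 1 <= max_size <= K")
    return sum(math.comb(K, k) for k in range(1, max_size + 1))


def fit_exposures(spectrum, subset, catalog: SignatureCatalog):
    """NNLS exposures (mutation counts) and Pearson r for one subset.

    ``subset`` is a sequence of signature names from the catalogue.
    """
    b = np.asarray(spectrum, dtype=float)
    if b.shape != (96,):
        raise ValueError("spectrum must be a 96-vector")
    if b.sum() <= 0:
        raise ValueError("all-zero spectrum")
    if len(subset) == 0:
        raise ValueError("empty signature subset")
    cols = [catalog.names.index(s) for s in subset]
    A = catalog.matrix()[:, cols]
    x, _ = nnls(A, b)
    recon = A @ x
    r = _pearson(b, recon)
    return x, float(r)


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


@dataclass
class ExposureResults:
    """Selected signature subset with exposures and reconstruction score."""

    signatures: list[str]
    exposures: np.ndarray
    r_: float
    total_mutations: float
    audit: list[dict] = field(default_factory=list)
    fallback: bool = False

    @property
    def exposure_fractions(self) -> np.ndarray:
        return self.exposures / max(self.total_mutations, 1e-12)

    def as_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=self.signatures)

    def summary(self) -> str:
        lines = ["Signature refit (exhaustive subset search)",
                 "=" * 48,
                 f"mutations: {self.total_mutations:.0f}   Pearson r: {self.r_:.4f}"
                 + ("   [fallback: no admissible solution]" if self.fallback else ""),
                 f"{'signature':>16} {'exposure':>10} {'fraction':>9}"]
        for s, e, fr in zip(self.signatures, self.exposures, self.exposure_fractions):
            lines.append(f"{s:>16} {e:10.1f} {fr:9.3f}")
        for entry in self.audit:
            lines.append(f"  size {entry['size']}: best admissible r = "
                         f"{entry['best_r'] if entry['best_r'] is not None else float('nan'):.4f}"
                         f" -> {entry['decision']}")
        return "\n".join(lines)


class SignatureRefitModel:
    """Exhaustive signature-subset selection for one mutation spectrum."""

    def __init__(self, spectrum, catalog: SignatureCatalog,
                 exempt=DEFAULT_EXEMPT):
        self.spectrum = np.asarray(spectrum, dtype=float)
        if self.spectrum.shape != (96,):
            raise ValueError("spectrum must be a 96-vector")
        if self.spectrum.sum() <= 0:
            raise ValueError("all-zero spectrum")
        self.catalog = catalog
        self.exempt = set(exempt)

    # -- batched scoring ----------------------------------------------------

    def _score_size(self, k: int, min_fraction: float, min_count: float,
                    chunk: int = 20000):
        """Best admissible (r, subset, exposures) across all subsets of size k."""
        A = self.catalog.matrix()
        K = A.shape[1]
        b = self.spectrum
        G = A.T @ A
        cb = A.T @ b
        total = b.sum()
        bc = b - b.mean()
        bnorm = np.sqrt((bc * bc).sum())
        names = self.catalog.names
        exempt_mask = np.array([nm in self.exempt for nm in names])

        best = (-np.inf, None, None)
        subsets = np.fromiter(
            (i for combo in combinations(range(K), k) for i in combo),
            dtype=np.int64)
        subsets = subsets.reshape(-1, k)
        for lo in range(0, len(subsets), chunk):
            idx = subsets[lo:lo + chunk]
            GS = G[idx[:, :, None], idx[:, None, :]]
            cS = cb[idx]
            # unconstrained solution on the normal equations; exact NNLS when
            # it is already non-negative, scipy NNLS fallback otherwise
            try:
                x = np.linalg.solve(GS, cS[..., None])[..., 0]
            except np.linalg.LinAlgError:
                x = np.linalg.solve(GS + 1e-10 * np.eye(k)[None], cS[..., None])[..., 0]
            neg = (x < -1e-12).any(axis=1)
            if neg.any():
                for q in np.flatnonzero(neg):
                    L = np.linalg.cholesky(GS[q])
                    y = np.linalg.solve(L, cS[q])
                    x[q], _ = nnls(L.T, y)
            x = np.maximum(x, 0.0)
            # Pearson r of reconstructions, vectorised: A[:, idx] is (96, B, k)
            recon = np.einsum("gbk,bk->bg", A[:, idx], x)
            rc = recon - recon.mean(axis=1, keepdims=True)
            denom = np.sqrt((rc * rc).sum(axis=1)) * bnorm
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (rc @ bc) / denom, 0.0)
            # admissibility: non-exempt members need >= min_fraction and
            # >= min_count mutations
            frac = x / max(total, 1e-12)
            nonexempt = ~exempt_mask[idx]
            bad = nonexempt & ((frac < min_fraction) | (x < min_count))
            admissible = ~bad.any(axis=1)
            r_adm = np.where(admissible, r, -np.inf)
            q = int(np.argmax(r_adm))
            if r_adm[q] > best[0]:
                best = (float(r_adm[q]), idx[q].copy(), x[q].copy())
        return best

    def fit(self, max_size: int = 7, min_fraction: float = 0.02,
            min_count: float = 50.0, min_improvement: float = 0.02,
            search: str = "ladder") -> ExposureResults:
        """Select the signature subset for this spectrum.

        ``search="ladder"`` stops enumerating larger sizes at the first
        failure of the +``min_improvement`` rule (they could no longer be
        selected); ``search="full"`` evaluates every size regardless.
        """
        if search not in ("ladder", "full"):
            raise ValueError("search must be 'ladder' or 'full'")
        K = self.catalog.K
        max_size = min(max_size, K)
        total = float(self.spectrum.sum())

        audit = []
        selected = None  # (r, idx, exposures)
        stopped = False
        for k in range(1, max_size + 1):
            if stopped and search == "ladder":
                break
            r_k, idx_k, x_k = self._score_size(k, min_fraction, min_count)
            if idx_k is None:
                audit.append({"size": k, "best_r": None,
                              "decision": "no admissible solution"})
                continue
            if selected is None:
                selected = (r_k, idx_k, x_k)
                audit.append({"size": k, "best_r": r_k, "decision": "selected"})
            elif not stopped and r_k >= selected[0] + min_improvement:
                selected = (r_k, idx_k, x_k)
                audit.append({"size": k, "best_r": r_k, "decision": "selected"})
            else:
                audit.append({"size": k, "best_r": r_k,
                              "decision": f"rejected (improvement < {min_improvement})"})
                stopped = True

        fallback = False
        if selected is None:
            # no admissible solution at any size: best single-signature fit
            warnings.warn("no admissible signature solution; "
                          "reporting best single-signature fit")
            fallback = True
            best = (-np.inf, None, None)
            for j, nm in enumerate(self.catalog.names):
                x, r = fit_exposures(self.spectrum, [nm], self.catalog)
                if r > best[0]:
                    best = (r, np.array([j]), x)
            selected = best
            audit.append({"size": 1, "best_r": best[0],
                          "decision": "fallback best single signature"})

        r_sel, idx_sel, x_sel = selected
        order = np.argsort(idx_sel)
        names = [self.catalog.names[j] for j in idx_sel[order]]
        return ExposureResults(
            signatures=names, exposures=np.asarray(x_sel)[order],
            r_=float(r_sel), total_mutations=total, audit=audit,
            fallback=fallback)


def spectrum_of_branch(mutation_df: pd.DataFrame) -> np.ndarray:
    """96-channel counts from a frame of substitutions with contexts."""
    out = np.zeros(96, dtype=int)
    subs = mutation_df[mutation_df["var_class"] == "substitution"]
    for _, row in subs.iterrows():
        ctx = row.get("context", "")
        if not isinstance(ctx, str) or len(ctx) != 3:
            raise ValueError(f"mutation {row['mutation_id']}: missing trinucleotide context")
        lab = channel_of(row["ref"], row["alt"], ctx)
        out[CHANNEL_INDEX[lab]] += 1
    return out


def branch_signatures(tree, mutation_df: pd.DataFrame, assignments: pd.DataFrame,
                      catalog: SignatureCatalog,
                      min_mutations: int = MIN_BRANCH_MUTATIONS,
                      **fit_kwargs) -> dict:
    """Refit signatures per branch of a clone tree.

    Branches with ``min_mutations`` (default 20) or fewer substitutions
    are skipped with a reason.  Returns {cluster id: ExposureResults or
    {"skipped": reason}}.
    """
    merged = assignments.merge(mutation_df, on="mutation_id", how="left")
    out = {}
    for k in tree.clusters:
        grp = merged[merged["cluster"] == k]
        subs = grp[grp["var_class"] == "substitution"]
        if len(subs) <= min_mutations:
            out[k] = {"skipped": f"branch has {len(subs)} substitutions (<= {min_mutations})"}
            continue
        spectrum = spectrum_of_branch(subs)
        out[k] = SignatureRefitModel(spectrum, catalog).fit(**fit_kwargs)
    return out
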