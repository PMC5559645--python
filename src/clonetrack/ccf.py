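"""Cancer-cell-fraction arithmetic and multi-sample Dirichlet-process clustering.

The observed variant allele fraction of a mutation is linked to the
cancer cell fraction (CCF) ``p`` of the clone carrying it through sample
purity ``rho``, local total copy number ``c`` and mutation multiplicity
``m``::

    f = rho * m * p / (rho * c + 2 * (1 - rho))

Variant read counts are modelled as X ~ Binomial(n, f), independently
across the related samples of one patient.  Mutations are clustered
across samples with a Dirichlet-process binomial mixture whose component
parameters are per-sample CCFs, sampled by Gibbs sampling with auxiliary
components for the non-conjugate emission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from .exceptions import ConfigurationError, ValidationError
from .io import MutationTable, SegmentTable

__all__ = [
    "expected_vaf", "estimate_multiplicity", "qc_filter",
    "DirichletProcessCCF", "CCFClusterResults",
]


def expected_vaf(rho, c, m, p):
    """Expected variant allele fraction for purity, copy number,
    multiplicity and CCF.

    Parameters are broadcast together.  ``m`` may not exceed ``c``:
    a cell cannot carry more mutated copies than total copies.
    """
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((rho <= 0) | (rho > 1)):
        raise ValueError("purity must lie in (0, 1]")
    if np.any(c < 1):
        raise ValueError("total copy number must be >= 1")
    if np.any(m < 1):
        raise ValueError("multiplicity must be >= 1")
    if np.any((p < 0) | (p > 1.2000001)):
        raise ValueError("CCF must lie in [0, 1] (<=1.2 transiently in sampling)")
    if np.any(m > c):
        raise ValueError("multiplicity exceeds total copy number")
    f = rho * m * p / (rho * c + 2.0 * (1.0 - rho))
    return f if f.ndim else float(f)


def _vaf_denominator(rho, c):
    return np.asarray(rho, float) * np.asarray(c, float) + 2.0 * (1.0 - np.asarray(rho, float))


def estimate_multiplicity(X, n, rho, c, clonal_ccf_cap: float = 1.2):
    """Integer multiplicity and implied CCF for one mutation in one sample.

    A mutation whose VAF already implies a CCF <= ``clonal_ccf_cap`` at
    multiplicity one keeps ``m = 1``; otherwise the multiplicity in
    ``1..c`` minimising the residual to the clonal expected VAF is used
    (ties broken toward the smaller m).  The escalation threshold allows
    three binomial standard errors of read-sampling noise on the implied
    CCF, so a clonal single-copy mutation at moderate depth is not
    reinterpreted as multi-copy just because its VAF fluctuated high.

    Returns ``(m, ccf)``; with ``n == 0`` the site is untyped and
    ``(1, nan)`` is returned.
    """
    if n == 0:
        return 1, float("nan")
    c = int(c)
    if c < 1:
        raise ValueError("total copy number must be >= 1")
    vaf = X / n
    denom = float(_vaf_denominator(rho, c))
    ccf_m1 = vaf * denom / rho
    se_ccf = denom / rho * np.sqrt(max(vaf * (1 - vaf), 1e-12) / n)
    if ccf_m1 <= max(clonal_ccf_cap, 1.0 + 3.0 * se_ccf):
        return 1, float(ccf_m1)
    ms = np.arange(1, c + 1)
    resid = np.abs(vaf - rho * ms / denom)
    m = int(ms[np.argmin(resid)])
    return m, float(vaf * denom / (rho * m))


def _segment_lookup_arrays(segments: SegmentTable, sample: str):
    """Per-chromosome sorted (starts, ends, total_cn) for one sample."""
    out = {}
    g = segments.df[segments.df["sample"] == sample]
    for chrom, grp in g.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        out[str(chrom)] = (grp["start"].to_numpy(), grp["end"].to_numpy(),
                           grp["total_cn"].to_numpy())
    return out


def qc_filter(mutations: MutationTable, segments: SegmentTable, purity: dict):
    """Apply the pre-clustering quality-control rules.

    Excluded with reason codes:

    * ``lost-region`` — the site lies in a segment with total copy number
      zero in any related sample, so absence there could reflect the
      deletion rather than subclonal structure;
    * ``undefined-CN`` — the site falls outside every copy-number segment
      in at least one sample, so its copy number is undefined;
    * ``untyped`` — zero depth in every sample.

    Returns ``(retained, excluded, stats)``; ``retained`` is the mutation
    DataFrame augmented with per-sample ``c:<s>`` / ``m:<s>`` columns
    (copy number and estimated multiplicity), ``excluded`` carries a
    ``reason`` column, and ``stats`` reports the retained fraction.
    """
    df = mutations.df.copy()
    samples = mutations.samples
    n_total = len(df)
    reason = np.array([""] * n_total, dtype=object)
    cn = {s: np.full(n_total, -1, dtype=int) for s in samples}

    for s in samples:
        tables = _segment_lookup_arrays(segments, s)
        chroms = df["chrom"].astype(str).to_numpy()
        pos = df["pos"].to_numpy()
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            if chrom not in tables:
                continue
            starts, ends, totals = tables[chrom]
            idx = np.searchsorted(starts, pos[sel] - 1, side="right") - 1
            ok = (idx >= 0) & (pos[sel] - 1 < ends[np.clip(idx, 0, None)])
            vals = np.full(sel.sum(), -1, dtype=int)
            vals[ok] = totals[idx[ok]]
            cn[s][sel] = vals

    for s in samples:
        undef = (cn[s] < 0) & (reason == "")
        reason[undef] = "undefined-CN"
    for s in samples:
        lost = (cn[s] == 0) & (reason == "")
        reason[lost] = "lost-region"
    all_untyped = np.all(mutations.n_matrix() == 0, axis=1) & (reason == "")
    reason[all_untyped] = "untyped"

    keep = reason == ""
    retained = df[keep].copy()
    for s in samples:
        retained[f"c:{s}"] = cn[s][keep]
        ms = []
        for X, n, c in zip(retained[f"X:{s}"], retained[f"n:{s}"], retained[f"c:{s}"]):
            m, _ = estimate_multiplicity(X, n, purity[s], c)
            ms.append(m)
        retained[f"m:{s}"] = ms
    excluded = df[~keep].copy()
    excluded["reason"] = reason[~keep]
    stats = {"n_total": n_total, "n_retained": int(keep.sum()),
             "retained_fraction": float(keep.mean()) if n_total else float("nan")}
    if stats["n_retained"] == 0 and n_total > 0:
        warnings.warn("no mutations retained by QC")
    return retained.reset_index(drop=True), excluded.reset_index(drop=True), stats


# ---------------------------------------------------------------------------
# Dirichlet-process clustering
# ---------------------------------------------------------------------------

@dataclass
class CCFClusterResults:
    """Posterior clustering of mutations across related samples.

    ``labels_`` assigns each input mutation (original order) to a cluster
    id; ``clusters`` holds per-cluster sizes, posterior-median CCFs and
    95% credible intervals per sample.
    """

    labels_: np.ndarray
    clusters: pd.DataFrame
    samples: list[str]
    mutation_ids: np.ndarray
    n_partitions_sampled: int
    sweeps: int
    burn_in: int
    alpha_trace: np.ndarray
    merged_: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def ccf_matrix(self, truncate: bool = True) -> np.ndarray:
        cols = [f"ccf:{s}" for s in self.samples]
        p = self.clusters[cols].to_numpy(dtype=float)
        return np.clip(p, 0.0, 1.0) if truncate else p

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({"mutation_id": self.mutation_ids, "cluster": self.labels_})

    def summary(self) -> str:
        lines = ["Dirichlet-process CCF clustering",
                 "=" * 48,
                 f"mutations: {len(self.labels_)}   samples: {len(self.samples)}   "
                 f"clusters: {self.n_clusters}",
                 f"sweeps: {self.sweeps} (burn-in {self.burn_in}), "
                 f"{self.n_partitions_sampled} partitions sampled",
                 ""]
        hdr = f"{'cluster':>8} {'size':>6}" + "".join(
            f" {('ccf[' + s + ']'):>18}" for s in self.samples)
        lines.append(hdr)
        for _, row in self.clusters.iterrows():
            cells = "".join(
                f" {row[f'ccf:{s}']:6.3f} ({row[f'ci_low:{s}']:.2f}-{row[f'ci_high:{s}']:.2f})"
                for s in self.samples)
            lines.append(f"{int(row['cluster']):>8} {int(row['n_mutations']):>6}" + cells)
        if self.merged_:
            lines.append(f"small clusters merged: {self.merged_}")
        return "\n".join(lines)


class DirichletProcessCCF:
    """Dirichlet-process binomial mixture over per-sample CCFs.

    Parameters
    ----------
    X, n : (N, S) int arrays
        Variant reads and depths per mutation and sample.
    c, m : (N, S) int arrays
        Total copy number and assigned multiplicity at each site.
    purity : (S,) floats
        Tumour purity per sample.

    The emission is ``X_ij ~ Binomial(n_ij, f(rho_j, c_ij, m_ij, p_kj))``
    with cluster CCFs ``p_k`` living on a grid over [0, 1.2]; CCFs above 1
    absorb multiplicity misestimates and are truncated to 1 for reporting.
    The DP concentration has a Gamma(1, 1) hyperprior resampled each sweep.
    """

    def __init__(self, X, n, c, m, purity, samples=None, mutation_ids=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=int))
        self.n = np.atleast_2d(np.asarray(n, dtype=int))
        self.c = np.atleast_2d(np.asarray(c, dtype=int))
        self.m = np.atleast_2d(np.asarray(m, dtype=int))
        self.purity = np.atleast_1d(np.asarray(purity, dtype=float))
        N, S = self.X.shape
        if not (self.n.shape == self.c.shape == self.m.shape == (N, S)):
            raise ValidationError("X, n, c, m must share shape (mutations, samples)")
        if self.purity.shape != (S,):
            raise ValidationError("purity must have one value per sample")
        if np.any(self.X > self.n):
            raise ValidationError("variant reads exceed depth")
        if N < 1:
            raise ValidationError("need at least one mutation")
        self.samples = list(samples) if samples is not None else [f"S{j}" for j in range(S)]
        self.mutation_ids = (np.asarray(mutation_ids) if mutation_ids is not None
                             else np.arange(N))

    @classmethod
    def from_dataframe(cls, retained: pd.DataFrame, purity: dict, samples=None):
        """Build from a QC-retained mutation frame carrying X/n/c/m columns."""
        if samples is None:
            samples = [col.split(":", 1)[1] for col in retained.columns
                       if col.startswith("c:")]
        X = np.column_stack([retained[f"X:{s}"] for s in samples])
        n = np.column_stack([retained[f"n:{s}"] for s in samples])
        c = np.column_stack([retained[f"c:{s}"] for s in samples])
        m = np.column_stack([retained[f"m:{s}"] for s in samples])
        rho = np.array([purity[s] for s in samples])
        return cls(X, n, c, m, rho, samples=samples,
                   mutation_ids=retained["mutation_id"].to_numpy())

    # -- likelihood table ---------------------------------------------------

    def _log_table(self, grid):
        """L[i, j, g] = log P(X_ij | n_ij, p = grid[g])."""
        rho = self.purity[None, :, None]
        cc = self.c[:, :, None].astype(float)
        mm = self.m[:, :, None].astype(float)
        f = rho * mm * grid[None, None, :] / (rho * cc + 2.0 * (1.0 - rho))
        f = np.clip(f, 1e-9, 1.0 - 1e-9)
        return binom.logpmf(self.X[:, :, None], self.n[:, :, None], f)

    def fit(self, sweeps: int = 1000, burn_in: int = 500, thin: int = 5,
            seed=None, min_cluster_size=None, grid_step: float = 0.01,
            n_aux: int = 3) -> CCFClusterResults:
        if sweeps <= burn_in:
            raise ConfigurationError("sweeps must exceed burn_in")
        rng = np.random.default_rng(seed)
        N, S = self.X.shape
        grid = np.arange(0.0, 1.2 + grid_step / 2, grid_step)
        G = len(grid)

        # canonical internal order: the sampler sees rows sorted by their
        # data content, so the fitted partition cannot depend on input order
        key = np.hstack([self.X, self.n, self.c, self.m])
        order = np.lexsort(key.T[::-1])
        inv = np.empty(N, dtype=int)
        inv[order] = np.arange(N)

        L = self._log_table(grid)[order]          # (N, S, G)

        cap = 32
        live = np.zeros(cap, dtype=bool)
        counts = np.zeros(cap, dtype=int)
        params = np.zeros((cap, S), dtype=int)    # grid indices per cluster/sample
        cols = np.full((N, cap), -np.inf)

        def column(gidx):
            return L[:, np.arange(S), gidx].sum(axis=1)

        # initial state: everything in one cluster at the empirical mean CCF
        live[0] = True
        counts[0] = N
        z = np.zeros(N, dtype=int)
        for j in range(S):
            params[0, j] = int(np.argmax(L[:, j, :].sum(axis=0)))
        cols[:, 0] = column(params[0])

        alpha = 1.0
        aux_params = rng.integers(0, G, size=(n_aux, S))
        aux_cols = np.column_stack([column(aux_params[a]) for a in range(n_aux)])

        partitions = []
        param_draws = []
        alpha_trace = []

        for sweep in range(sweeps):
            gumbel = rng.gumbel(size=(N, cap + n_aux))
            log_alpha_aux = np.log(alpha / n_aux)
            for i in range(N):
                k_old = z[i]
                counts[k_old] -= 1
                if counts[k_old] == 0:
                    live[k_old] = False
                idx_live = np.flatnonzero(live)
                w_live = cols[i, idx_live] + np.log(counts[idx_live])
                w_aux = aux_cols[i] + log_alpha_aux
                w = np.concatenate([w_live, w_aux])
                choice = int(np.argmax(w + gumbel[i, :len(w)]))
                if choice < len(idx_live):
                    k_new = int(idx_live[choice])
                    counts[k_new] += 1
                    z[i] = k_new
                else:
                    a = choice - len(idx_live)
                    free = np.flatnonzero(~live)
                    if len(free) == 0:  # grow capacity
                        extra = cap
                        live = np.concatenate([live, np.zeros(extra, bool)])
                        counts = np.concatenate([counts, np.zeros(extra, int)])
                        params = np.vstack([params, np.zeros((extra, S), int)])
                        cols = np.hstack([cols, np.full((N, extra), -np.inf)])
                        gumbel = np.hstack([gumbel, rng.gumbel(size=(N, extra))])
                        free = np.flatnonzero(~live)
                        cap += extra
                    slot = int(free[0])
                    live[slot] = True
                    counts[slot] = 1
                    params[slot] = aux_params[a]
                    cols[:, slot] = aux_cols[:, a]
                    z[i] = slot
                    aux_params[a] = rng.integers(0, G, size=S)
                    aux_cols[:, a] = column(aux_params[a])

            # resample cluster CCFs on the grid (exact conditional)
            for k in np.flatnonzero(live):
                members = np.flatnonzero(z == k)
                post = L[members].sum(axis=0)          # (S, G)
                gu = rng.gumbel(size=post.shape)
                params[k] = np.argmax(post + gu, axis=1)
                cols[:, k] = column(params[k])

            # resample concentration (Escobar & West, Gamma(1,1) prior)
            k_live = int(live.sum())
            eta = rng.beta(alpha + 1.0, N)
            a0, b0 = 1.0, 1.0
            odds = (a0 + k_live - 1) / (N * (b0 - np.log(eta)))
            if rng.uniform() < odds / (1.0 + odds):
                alpha = rng.gamma(a0 + k_live, 1.0 / (b0 - np.log(eta)))
            else:
                alpha = rng.gamma(a0 + k_live - 1, 1.0 / (b0 - np.log(eta)))
            alpha_trace.append(alpha)

            if sweep >= burn_in and (sweep - burn_in) % thin == 0:
                partitions.append(z.copy())
                # per-mutation CCF draw this sweep (its cluster's parameter)
                param_draws.append(params[z].copy())

        # summary partition: maximum posterior-expected adjusted Rand among
        # the sampled partitions
        T = len(partitions)
        scores = np.zeros(T)
        for a in range(T):
            for b in range(a + 1, T):
                s = adjusted_rand_score(partitions[a], partitions[b])
                scores[a] += s
                scores[b] += s
        best = partitions[int(np.argmax(scores))]

        # marginal posterior CCFs: pool the per-sweep parameter draws of each
        # summary cluster's members, so the interval reflects both emission
        # noise and assignment uncertainty across sampled partitions
        draws = grid[np.stack(param_draws)]  # (T, N, S) CCF draws
        labels = np.unique(best)
        rows = []
        label_map = {}
        half = grid_step / 2.0  # grid cells have width grid_step
        for new_id, k in enumerate(labels):
            members = np.flatnonzero(best == k)
            label_map[k] = new_id
            row = {"cluster": new_id, "n_mutations": len(members), "merged": False}
            cluster_draws = np.median(draws[:, members, :], axis=1)  # (T, S)
            for j, s in enumerate(self.samples):
                med = float(np.median(cluster_draws[:, j]))
                lo, hi = np.quantile(cluster_draws[:, j], [0.025, 0.975])
                row[f"ccf_raw:{s}"] = med
                row[f"ccf:{s}"] = min(med, 1.0)
                row[f"ci_low:{s}"] = max(float(lo) - half, 0.0)
                row[f"ci_high:{s}"] = float(hi) + half
            rows.append(row)
        clusters = pd.DataFrame(rows)
        z_final = np.array([label_map[k] for k in best])

        # merge clusters below the minimum size into their nearest neighbour
        if min_cluster_size is None:
            min_cluster_size = max(5, int(np.ceil(0.01 * N)))
        merged = []
        ccf_cols = [f"ccf_raw:{s}" for s in self.samples]
        while len(clusters) > 1:
            sizes = clusters["n_mutations"].to_numpy()
            small = np.flatnonzero(sizes < min_cluster_size)
            if len(small) == 0:
                break
            k = int(small[np.argmin(sizes[small])])
            p = clusters[ccf_cols].to_numpy(float)
            d = np.linalg.norm(p - p[k], axis=1)
            d[k] = np.inf
            target = int(np.argmin(d))
            merged.append(int(clusters.iloc[k]["cluster"]))
            z_final[z_final == clusters.iloc[k]["cluster"]] = clusters.iloc[target]["cluster"]
            clusters.loc[clusters.index[target], "n_mutations"] += sizes[k]
            clusters.loc[clusters.index[target], "merged"] = True
            clusters = clusters.drop(clusters.index[k]).reset_index(drop=True)

        # canonical ids: by first occurrence in canonical data order
        first_seen = {}
        for lab in z_final:
            if lab not in first_seen:
                first_seen[lab] = len(first_seen)
        z_final = np.array([first_seen[lab] for lab in z_final])
        clusters["cluster"] = [first_seen[int(c0)] for c0 in clusters["cluster"]]
        clusters = clusters.sort_values("cluster").reset_index(drop=True)

        return CCFClusterResults(
            labels_=z_final[inv],
            clusters=clusters,
            samples=self.samples,
            mutation_ids=self.mutation_ids,
            n_partitions_sampled=T,
            sweeps=sweeps,
            burn_in=burn_in,
            alpha_trace=np.array(alpha_trace),
            merged_=merged,
        )
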