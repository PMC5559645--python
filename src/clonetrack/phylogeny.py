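"""Clone trees from cluster CCFs by pigeonhole ordering, and branch statistics.

A cluster A can be ancestral to B only if A's CCF dominates B's in every
sample (within a tolerance tau), and siblings under one parent must not
sum above the parent's CCF in any sample — the pigeonhole principle.
All rooted arrangements satisfying both constraints are enumerated; the
deepest-nesting tree is reported as primary, with any other valid trees
kept as ranked alternatives.

Presence of a point mutation in a sample is decided against sequencing
error with an exact binomial tail test at an expected error rate of
1/200; structural variants count as present when supported by at least
four split reads.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, fisher_exact

from .exceptions import PhylogenyError

__all__ = [
    "presence_call", "presence_matrix", "sv_presence", "classify_sv",
    "build_tree", "PhyloTree", "deletion_enrichment",
]

DEFAULT_ERROR_RATE = 1.0 / 200.0
SV_SPLIT_READ_MIN = 4


def presence_call(X: int, n: int, error_rate: float = DEFAULT_ERROR_RATE) -> str:
    """Classify one site in one sample as present / absent / untyped.

    Present iff the upper binomial tail P(Binom(n, error_rate) >= X) is
    <= 0.05; a site with zero depth is untyped, which is distinct from
    absent.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie in (0, 1)")
    if n < 0 or X < 0 or X > n:
        raise ValueError("need 0 <= X <= n")
    if n == 0:
        return "untyped"
    if X == 0:
        return "absent"
    p = float(binom.sf(X - 1, n, error_rate))
    return "present" if p <= 0.05 else "absent"


def presence_matrix(X, n, error_rate: float = DEFAULT_ERROR_RATE) -> np.ndarray:
    """Vectorised presence calls; returns an object array of labels."""
    X = np.asarray(X)
    n = np.asarray(n)
    out = np.where(np.asarray(binom.sf(X - 1, n, error_rate)) <= 0.05, "present", "absent")
    out = np.where(X == 0, "absent", out)
    out = np.where(n == 0, "untyped", out)
    return out


def sv_presence(split_reads, reconstructed=None,
                threshold: int = SV_SPLIT_READ_MIN) -> np.ndarray:
    """Per-sample presence of a structural variant.

    Present where the breakpoint was reconstructed in that sample or is
    supported by ``threshold`` (default 4) or more split reads.
    """
    sr = np.asarray(split_reads, dtype=int)
    if (sr < 0).any():
        raise ValueError("negative split-read count")
    present = sr >= threshold
    if reconstructed is not None:
        present = present | np.asarray(reconstructed, dtype=bool)
    return present


def classify_sv(split_reads, samples, reconstructed=None) -> str:
    """Label an SV as shared, private to one sample, or absent everywhere."""
    present = sv_presence(split_reads, reconstructed)
    k = int(present.sum())
    if k == 0:
        return "none"
    if k == 1:
        return f"private:{samples[int(np.flatnonzero(present)[0])]}"
    return "shared"


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted clone tree over CCF clusters.

    ``parent`` maps cluster id -> parent cluster id (root maps to None).
    ``ccf`` holds the (clusters x samples) CCF matrix used for ordering,
    ``sizes`` the per-cluster mutation counts used as branch lengths.
    """

    samples: list[str]
    clusters: list[int]
    ccf: dict[int, np.ndarray]
    sizes: dict[int, int]
    parent: dict[int, int | None]
    alternatives: list[dict] = field(default_factory=list)
    tau: float = 0.05
    branch_mutations: dict[int, list] = field(default_factory=dict)
    branch_class_counts: pd.DataFrame | None = None

    @property
    def root(self) -> int:
        return next(k for k, v in self.parent.items() if v is None)

    def children(self, node: int) -> list[int]:
        return [k for k, v in self.parent.items() if v == node]

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] is not None:
            node = self.parent[node]
            d += 1
        return d

    def path_to_root(self, node: int) -> list[int]:
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def leaves(self) -> list[int]:
        have_child = set(v for v in self.parent.values() if v is not None)
        return [k for k in self.clusters if k not in have_child]

    def present_in(self, node: int, sample: str, threshold: float | None = None) -> bool:
        thr = self.tau if threshold is None else threshold
        j = self.samples.index(sample)
        return bool(self.ccf[node][j] > thr)

    def validate(self) -> None:
        """Assert CCF monotonicity and the sibling pigeonhole constraint."""
        for k, par in self.parent.items():
            if par is None:
                continue
            if np.any(self.ccf[k] > self.ccf[par] + self.tau + 1e-12):
                raise PhylogenyError(f"cluster {k} CCF exceeds parent {par}")
        for node in self.clusters:
            kids = self.children(node)
            if kids:
                tot = np.sum([self.ccf[k] for k in kids], axis=0)
                if np.any(tot > self.ccf[node] + self.tau + 1e-12):
                    raise PhylogenyError(f"children of {node} violate pigeonhole sum")

    # -- mutation attachment ------------------------------------------------

    def attach_mutations(self, assignments: pd.DataFrame,
                         mutation_df: pd.DataFrame | None = None) -> None:
        """Attach mutation ids (and class counts) to branches.

        ``assignments`` needs columns mutation_id and cluster; cluster ids
        merged during tree building are remapped by the caller beforehand.
        """
        self.branch_mutations = {
            int(k): list(g["mutation_id"])
            for k, g in assignments.groupby("cluster")
        }
        for k in self.clusters:
            self.sizes[k] = len(self.branch_mutations.get(k, []))
        if mutation_df is not None:
            merged = assignments.merge(mutation_df[["mutation_id", "var_class"]],
                                       on="mutation_id", how="left")
            counts = (merged.groupby(["cluster", "var_class"]).size()
                      .unstack(fill_value=0))
            self.branch_class_counts = counts

    def branch_lengths(self, counts: dict[int, int] | None = None) -> dict[int, int]:
        """Substitution counts per branch (or caller-supplied counts)."""
        if counts is not None:
            return counts
        if self.branch_class_counts is not None and "substitution" in self.branch_class_counts:
            return {int(k): int(v) for k, v in
                    self.branch_class_counts["substitution"].items()}
        return dict(self.sizes)

    # -- branch statistics --------------------------------------------------

    def divergence_fraction(self, primary: str, recurrence: str,
                            counts: dict[int, int] | None = None,
                            threshold: float | None = None) -> float:
        """Fraction of the primary tumour's molecular time at which the
        recurrence-seeding lineage diverges.

        Numerator: substitutions on the shared lineage from the root down
        to the divergence node (the deepest node on the recurrence
        lineage still present in the primary).  Denominator:
        substitutions on the primary's longest root-to-tip lineage.
        """
        lengths = self.branch_lengths(counts)
        # recurrence tip: deepest node present in the recurrence
        rec_nodes = [k for k in self.clusters if self.present_in(k, recurrence, threshold)]
        if not rec_nodes:
            raise PhylogenyError(f"no branch present in sample {recurrence}")
        tip = max(rec_nodes, key=lambda k: (self.depth(k),
                                            self.ccf[k][self.samples.index(recurrence)]))
        path = self.path_to_root(tip)
        shared = [k for k in path if self.present_in(k, primary, threshold)]
        numerator = sum(lengths.get(k, 0) for k in shared)

        denom = 0
        for node in self.clusters:
            p = self.path_to_root(node)
            if all(self.present_in(k, primary, threshold) for k in p):
                denom = max(denom, sum(lengths.get(k, 0) for k in p))
        if denom == 0:
            raise PhylogenyError(f"primary lineage of {primary} carries no substitutions")
        return min(numerator / denom, 1.0)

    def recurrence_excess(self, primary: str, recurrence: str,
                          counts: dict[int, int] | None = None,
                          threshold: float | None = None) -> float:
        """Recurrence-specific mutation excess, in percent.

        100 x (substitutions private to the recurrence minus those
        private to the primary) / all substitutions in the primary.
        """
        lengths = self.branch_lengths(counts)
        in_prim = {k: self.present_in(k, primary, threshold) for k in self.clusters}
        in_rec = {k: self.present_in(k, recurrence, threshold) for k in self.clusters}
        priv_rec = sum(lengths.get(k, 0) for k in self.clusters
                       if in_rec[k] and not in_prim[k])
        priv_prim = sum(lengths.get(k, 0) for k in self.clusters
                        if in_prim[k] and not in_rec[k])
        total_primary = sum(lengths.get(k, 0) for k in self.clusters if in_prim[k])
        if total_primary == 0:
            raise PhylogenyError("no substitutions identified in the primary tumour")
        return 100.0 * (priv_rec - priv_prim) / total_primary

    # -- export -------------------------------------------------------------

    def to_newick(self, counts: dict[int, int] | None = None) -> str:
        """Newick string with branch lengths equal to substitution counts."""
        import dendropy
        lengths = self.branch_lengths(counts)
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for k in sorted(self.clusters, key=self.depth):
            nd = dendropy.Node()
            nd.taxon = taxa.new_taxon(label=f"cluster{k}")
            nd.edge.length = float(lengths.get(k, 0))
            nodes[k] = nd
            if self.parent[k] is None:
                tree.seed_node.add_child(nd)
            else:
                nodes[self.parent[k]].add_child(nd)
        return tree.as_string(schema="newick").strip()

    def branch_stats_table(self) -> pd.DataFrame:
        rows = []
        lengths = self.branch_lengths()
        for k in self.clusters:
            row = {"cluster": k, "parent": self.parent[k],
                   "depth": self.depth(k), "n_substitutions": lengths.get(k, 0),
                   "n_mutations": self.sizes.get(k, 0)}
            for j, s in enumerate(self.samples):
                row[f"ccf:{s}"] = self.ccf[k][j]
            rows.append(row)
        return pd.DataFrame(rows)


def _merge_mutual(ccf: np.ndarray, sizes: np.ndarray, tau: float):
    """Union clusters whose CCFs agree within tau in every sample."""
    K = len(ccf)
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(range(K), 2):
        if np.all(np.abs(ccf[a] - ccf[b]) <= tau):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(K):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def build_tree(clusters: pd.DataFrame, samples: list[str], tau: float = 0.05,
               max_enumeration: int = 200_000) -> PhyloTree:
    """Order CCF clusters into a rooted clone tree by the pigeonhole
    principle.

    ``clusters`` needs columns ``cluster``, ``n_mutations`` and
    ``ccf:<sample>`` (CCFs truncated to [0, 1]).  Exactly one cluster must
    qualify as the trunk (CCF >= 1 - tau in every sample).  Clusters whose
    CCFs are indistinguishable within tau are merged with a warning.  All
    valid parent assignments are enumerated; the deepest tree is primary
    and the rest are kept in ``alternatives``.
    """
    ids = clusters["cluster"].to_numpy()
    P = clusters[[f"ccf:{s}" for s in samples]].to_numpy(dtype=float)
    P = np.clip(P, 0.0, 1.0)
    sizes = clusters["n_mutations"].to_numpy()

    groups = _merge_mutual(P, sizes, tau)
    if len(groups) < len(ids):
        warnings.warn("merged clusters with mutually indistinguishable CCFs")
    merged_ids, merged_P, merged_sizes, merge_map = [], [], [], {}
    for grp in groups:
        keep = int(ids[grp[0]])
        w = sizes[grp].astype(float)
        merged_ids.append(keep)
        merged_P.append(np.average(P[grp], axis=0, weights=np.maximum(w, 1)))
        merged_sizes.append(int(sizes[grp].sum()))
        for g in grp:
            merge_map[int(ids[g])] = keep
    P = np.array(merged_P)
    K = len(merged_ids)

    trunk_mask = np.all(P >= 1.0 - tau, axis=1)
    if not trunk_mask.any():
        raise PhylogenyError("no clonal cluster: no cluster has CCF ~1 in every sample")
    trunk = int(np.flatnonzero(trunk_mask)[0])

    dominates = np.zeros((K, K), dtype=bool)
    for a in range(K):
        for b in range(K):
            if a != b:
                dominates[a, b] = np.all(P[a] >= P[b] - tau)

    candidates = {}
    for b in range(K):
        if b == trunk:
            continue
        cand = [a for a in range(K) if dominates[a, b] and not dominates[b, a]]
        if trunk not in cand:
            cand.append(trunk)
        candidates[b] = cand

    non_trunk = [b for b in range(K) if b != trunk]
    n_combos = int(np.prod([len(candidates[b]) for b in non_trunk])) if non_trunk else 1
    if n_combos > max_enumeration:
        raise PhylogenyError(f"too many candidate trees to enumerate ({n_combos})")

    valid = []
    for combo in itertools.product(*(candidates[b] for b in non_trunk)):
        par = {trunk: None}
        for b, a in zip(non_trunk, combo):
            par[b] = a
        # acyclicity
        ok = True
        for b in non_trunk:
            seen, node = set(), b
            while par[node] is not None:
                node = par[node]
                if node in seen:
                    ok = False
                    break
                seen.add(node)
            if not ok:
                break
        if not ok:
            continue
        # pigeonhole sums
        for node in range(K):
            kids = [b for b in non_trunk if par[b] == node]
            if kids and np.any(P[kids].sum(axis=0) > P[node] + tau):
                ok = False
                break
        if not ok:
            continue

        def depth_of(b, par=par):
            d = 0
            while par[b] is not None:
                b = par[b]
                d += 1
            return d

        valid.append((sum(depth_of(b) for b in non_trunk), par))

    if not valid:
        raise PhylogenyError("no tree satisfies the pigeonhole constraints")
    valid.sort(key=lambda t: -t[0])

    def to_ids(par):
        return {merged_ids[k]: (None if v is None else merged_ids[v])
                for k, v in par.items()}

    primary = to_ids(valid[0][1])
    tree = PhyloTree(
        samples=list(samples),
        clusters=[merged_ids[k] for k in range(K)],
        ccf={merged_ids[k]: P[k] for k in range(K)},
        sizes={merged_ids[k]: merged_sizes[k] for k in range(K)},
        parent=primary,
        alternatives=[to_ids(par) for _, par in valid[1:]],
        tau=tau,
    )
    tree.merge_map = merge_map  # original cluster id -> merged id
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# indel spectrum shifts
# ---------------------------------------------------------------------------

def deletion_enrichment(relapse_indels: pd.DataFrame,
                        trunk_indels: pd.DataFrame,
                        long_cutoff: int = 5) -> dict:
    """Test whether relapse-private indels are enriched for deletions, and
    for longer deletions, relative to the trunk.

    Each frame needs columns ``var_class`` (insertion/deletion) and
    ``length``.  Returns two 2x2 Fisher tests: deletion vs insertion, and
    deletion length >= ``long_cutoff`` bp vs shorter.  Odds ratios use a
    Haldane 0.5 correction when a cell is empty (flagged).
    """
    if len(relapse_indels) == 0 or len(trunk_indels) == 0:
        raise ValueError("empty indel set")

    def table_or(table):
        table = np.asarray(table, dtype=float)
        _, p = fisher_exact(table, alternative="two-sided")
        corrected = (table == 0).any()
        t = table + 0.5 if corrected else table
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        return float(odds), float(p), bool(corrected)

    rel_del = int((relapse_indels["var_class"] == "deletion").sum())
    rel_ins = int((relapse_indels["var_class"] == "insertion").sum())
    tr_del = int((trunk_indels["var_class"] == "deletion").sum())
    tr_ins = int((trunk_indels["var_class"] == "insertion").sum())
    or1, p1, c1 = table_or([[rel_del, rel_ins], [tr_del, tr_ins]])

    rd = relapse_indels[relapse_indels["var_class"] == "deletion"]["length"]
    td = trunk_indels[trunk_indels["var_class"] == "deletion"]["length"]
    tab2 = [[int((rd >= long_cutoff).sum()), int((rd < long_cutoff).sum())],
            [int((td >= long_cutoff).sum()), int((td < long_cutoff).sum())]]
    or2, p2, c2 = table_or(tab2)

    return {
        "deletion_vs_insertion": {"odds_ratio": or1, "p": p1,
                                  "haldane_corrected": c1,
                                  "table": [[rel_del, rel_ins], [tr_del, tr_ins]]},
        "long_deletions": {"odds_ratio": or2, "p": p2,
                           "haldane_corrected": c2, "table": tab2},
    }
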