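"""Rule-based driver annotation, copy-number driver calls, enrichment
tests and early/late timing of driver mutations.

Point mutations in known cancer genes are classified into four
oncogenic categories, applied in order of precedence:

1. a canonical oncogenic mutation at a recurrent hotspot;
2. a lower-frequency recurrent mutation in a known oncogene with three
   or more previously reported somatic non-synonymous substitutions or
   in-frame deletions at the locus;
3. a likely damaging event in a tumour suppressor — truncating
   (nonsense), frameshift or essential-splice variants, or any variant
   at a hotspot with two or more prior somatic reports;
4. a silent mutation at a known recurrent splice-site hotspot.

Copy-number drivers: in whole-genome mode a segment is amplified when
its total copy number exceeds twice the genome-average ploidy and
homozygously deleted when it is zero; in targeted mode amplification
requires gene-level mean logR > 1.  Gene-level enrichment between
cohorts uses two-sided Fisher exact tests with Benjamini-Hochberg
correction, significant at q < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .phylogeny import presence_call

__all__ = [
    "CancerGeneRecord", "DriverCall", "annotate_driver",
    "call_copy_number_drivers", "enrichment_test", "driver_timing",
]

CONSEQUENCE_CLASSES = (
    "missense", "nonsense", "frameshift", "essential_splice",
    "inframe_deletion", "silent", "synonymous",
)
_TRUNCATING = {"nonsense", "frameshift", "essential_splice"}
_NONSYN_SUB = {"missense", "inframe_deletion"}


@dataclass
class CancerGeneRecord:
    """Curated knowledge about one cancer gene.

    ``hotspots`` maps position -> number of previously reported somatic
    mutations at that locus; ``canonical_hotspots`` marks canonical
    oncogenic hotspot positions; ``splice_hotspots`` marks recurrent
    splice-site hotspot positions at which even silent changes matter.
    """

    gene: str
    role: str  # oncogene | TSG | both
    hotspots: dict[int, int] = field(default_factory=dict)
    canonical_hotspots: set[int] = field(default_factory=set)
    splice_hotspots: set[int] = field(default_factory=set)

    def __post_init__(self):
        if self.role not in ("oncogene", "TSG", "both"):
            raise ValueError(f"unknown gene role {self.role!r}")
        if any(v < 0 for v in self.hotspots.values()):
            raise ValueError("hotspot counts must be non-negative")


@dataclass
class DriverCall:
    mutation_id: str
    gene: str
    category: int | str  # 1..4, "amplification" or "homozygous-deletion"
    evidence: str
    timing: str | None = None  # early | late | both-different


def annotate_driver(mutation: dict, record: CancerGeneRecord | None
                    ) -> DriverCall | None:
    """Categorise one annotated mutation against a cancer-gene record.

    ``mutation`` needs keys mutation_id, gene, pos and consequence.
    Returns None for genes outside the cancer-gene list or mutations
    matching no rule.  Rules apply in order of precedence; a mutation
    receives at most one category.
    """
    cons = mutation["consequence"]
    if cons not in CONSEQUENCE_CLASSES:
        raise ValueError(f"unknown consequence class {cons!r}")
    if record is None or record.gene != mutation.get("gene"):
        return None
    pos = int(mutation["pos"])
    silent = cons in ("silent", "synonymous")
    prior = record.hotspots.get(pos, 0)

    if pos in record.canonical_hotspots and not silent:
        return DriverCall(mutation["mutation_id"], record.gene, 1,
                          "canonical oncogenic hotspot")
    if record.role in ("oncogene", "both") and cons in _NONSYN_SUB and prior >= 3:
        return DriverCall(mutation["mutation_id"], record.gene, 2,
                          f"oncogene locus with {prior} prior somatic reports")
    if record.role in ("TSG", "both"):
        if cons in _TRUNCATING:
            return DriverCall(mutation["mutation_id"], record.gene, 3,
                              f"truncating ({cons}) in tumour suppressor")
        if not silent and prior >= 2:
            return DriverCall(mutation["mutation_id"], record.gene, 3,
                              f"tumour-suppressor hotspot with {prior} prior reports")
    if silent and pos in record.splice_hotspots:
        return DriverCall(mutation["mutation_id"], record.gene, 4,
                          "silent change at recurrent splice-site hotspot")
    return None


def call_copy_number_drivers(segments=None, ploidy: float | None = None,
                             mode: str = "wgs", genes: pd.DataFrame | None = None,
                             gene_logr: pd.DataFrame | None = None,
                             logr_threshold: float = 1.0) -> list[DriverCall]:
    """Copy-number driver calls.

    wgs mode: ``segments`` is a per-sample segment frame (chrom, start,
    end, total_cn) and ``genes`` a frame with gene, chrom, start, end;
    a gene is amplified when an overlapping segment's total copy number
    exceeds 2 x ploidy, homozygously deleted when it is zero.

    targeted mode: ``gene_logr`` is a frame with gene, mean_logr and
    optionally ci_low/ci_high and per-sample heterogeneity; genes with
    mean logR > 1 are amplified.  Heterogeneous amplifications across
    related samples are flagged for manual review, not auto-called.
    """
    calls: list[DriverCall] = []
    if mode == "wgs":
        if ploidy is None or ploidy <= 0:
            raise ValueError("wgs mode requires a positive genome-average ploidy")
        if segments is None or genes is None:
            raise ValueError("wgs mode requires segments and gene coordinates")
        seg = segments.df if hasattr(segments, "df") else segments
        for _, g in genes.iterrows():
            hits = seg[(seg["chrom"].astype(str) == str(g["chrom"]))
                       & (seg["start"] < g["end"]) & (g["start"] < seg["end"])]
            if len(hits) == 0:
                continue
            top = int(hits["total_cn"].max())
            low = int(hits["total_cn"].min())
            if top > 2 * ploidy:
                calls.append(DriverCall(f"cn:{g['gene']}", g["gene"], "amplification",
                                        f"total CN {top} > 2 x ploidy {ploidy:g}"))
            if low == 0:
                calls.append(DriverCall(f"cn:{g['gene']}", g["gene"],
                                        "homozygous-deletion", "total CN 0"))
        return calls
    if mode == "targeted":
        if gene_logr is None:
            raise ValueError("targeted mode requires gene-level mean logR")
        for _, g in gene_logr.iterrows():
            if g["mean_logr"] > logr_threshold:
                evidence = f"mean logR {g['mean_logr']:.2f} > {logr_threshold:g}"
                if "ci_low" in g.index and not pd.isna(g.get("ci_low")):
                    evidence += f" (95% CI {g['ci_low']:.2f}-{g['ci_high']:.2f})"
                if bool(g.get("heterogeneous", False)):
                    evidence += "; heterogeneous across samples - flagged for review"
                calls.append(DriverCall(f"cn:{g['gene']}", g["gene"],
                                        "amplification", evidence))
        return calls
    raise ValueError(f"unknown mode {mode!r}")


def enrichment_test(counts_relapse: dict, counts_primary: dict,
                    q_threshold: float = 0.1) -> pd.DataFrame:
    """Per-gene Fisher enrichment between relapse and primary cohorts.

    Each dict maps gene -> (mutated, total).  Returns a frame with the
    two-sided Fisher p, odds ratio, BH q and a q < 0.1 significance flag.
    """
    genes = sorted(set(counts_relapse) | set(counts_primary))
    rows = []
    for gene in genes:
        mr, tr = counts_relapse.get(gene, (0, 0))
        mp, tp = counts_primary.get(gene, (0, 0))
        if mr > tr or mp > tp:
            raise ValueError(f"{gene}: mutated count exceeds cohort size")
        if tr == 0 or tp == 0:
            raise ValueError(f"{gene}: empty cohort")
        table = [[mr, tr - mr], [mp, tp - mp]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append({"gene": gene, "mutated_relapse": mr, "total_relapse": tr,
                     "mutated_primary": mp, "total_primary": tp,
                     "odds_ratio": float(odds), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < q_threshold
    return out


def driver_timing(primary_variants: set | None, recurrence_variants: set,
                  primary_coverage: dict | None = None,
                  error_rate: float = 1.0 / 200.0) -> dict:
    """Label driver mutations of one gene in one patient as early, late
    or both-different.

    ``primary_variants`` / ``recurrence_variants`` are sets of variant
    keys (e.g. chrom:pos:ref:alt) carrying a driver in each setting;
    ``primary_coverage`` maps recurrence-only variant keys to (X, n)
    read counts observed in the primary, letting a conservative presence
    test distinguish genuine late acquisition from coverage dropout.

    Returns {"label": ..., "reason": ...} where label is early, late,
    both-different or None (withheld).
    """
    if primary_variants is None:
        return {"label": None, "reason": "no matched primary sample"}
    shared = primary_variants & recurrence_variants
    if shared:
        return {"label": "early",
                "reason": f"{len(shared)} identical variant(s) in primary and recurrence"}
    if primary_variants and recurrence_variants:
        return {"label": "both-different",
                "reason": "different driver mutations in primary and recurrence"}
    if recurrence_variants:
        if primary_coverage is not None:
            for key in recurrence_variants:
                X, n = primary_coverage.get(key, (0, 0))
                call = presence_call(X, n, error_rate)
                if call == "untyped":
                    return {"label": None,
                            "reason": f"{key} untyped in primary (n=0): cannot "
                                      "exclude coverage dropout"}
                if call == "present":
                    return {"label": "early",
                            "reason": f"{key} detectable in primary by presence test"}
        return {"label": "late", "reason": "detected in the recurrence only; "
                                           "primary typed and negative"}
    return {"label": None, "reason": "no driver variants supplied"}
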