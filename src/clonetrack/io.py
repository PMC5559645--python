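"""Readers and writers for the tabular formats the pipeline consumes.

Conventions
-----------
* Mutation positions are 1-based (VCF convention).
* Copy-number segments are 0-based half-open intervals (BED convention).
  The conversion between the two lives in :func:`position_in_segment`
  and nowhere else.
* Mutation tables are wide: one row per variant with per-sample variant
  read (``X:<sample>``) and depth (``n:<sample>``) columns.
* A missing depth (``n = 0``) means the site is untyped in that sample,
  not that the mutation is absent; absence requires the binomial
  presence test in :mod:`clonetrack.phylogeny`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, CHANNEL_INDEX
from .exceptions import ValidationError

MUTATION_CLASSES = ("substitution", "insertion", "deletion", "SV")

_MUT_FIXED_COLS = ["mutation_id", "chrom", "pos", "ref", "alt", "var_class",
                   "gene", "consequence", "context"]
_SEG_COLS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn", "frac"]


def position_in_segment(pos: int, start: int, end: int) -> bool:
    """Does 1-based position ``pos`` fall in 0-based half-open [start, end)?"""
    return start <= pos - 1 < end


def to_zero_based(pos: int) -> int:
    return pos - 1


def to_one_based(offset: int) -> int:
    return offset + 1


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

@dataclass
class MutationTable:
    """Somatic variants with per-sample read support.

    ``df`` holds one row per variant; per-sample variant reads and depths
    live in ``X:<sample>`` / ``n:<sample>`` columns, with sample order
    recorded in ``samples``.
    """

    df: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        for col in _MUT_FIXED_COLS:
            if col not in df.columns:
                raise ValidationError(f"mutation table missing column {col!r}")
        for s in self.samples:
            for pre in ("X", "n"):
                if f"{pre}:{s}" not in df.columns:
                    raise ValidationError(f"missing column {pre}:{s}")
        if len(df) == 0:
            return
        if (df["pos"] < 1).any():
            row = int(df.index[df["pos"] < 1][0])
            raise ValidationError(f"row {row}: position < 1")
        bad_class = ~df["var_class"].isin(MUTATION_CLASSES)
        if bad_class.any():
            row = int(df.index[bad_class][0])
            raise ValidationError(f"row {row}: unknown class {df.loc[row, 'var_class']!r}")
        for s in self.samples:
            X = df[f"X:{s}"].to_numpy()
            n = df[f"n:{s}"].to_numpy()
            if (X < 0).any() or (n < 0).any():
                raise ValidationError(f"negative read count in sample {s}")
            over = X > n
            if over.any():
                row = int(df.index[over][0])
                raise ValidationError(
                    f"row {row}: variant reads X={X[over][0]} exceed depth "
                    f"n={n[over][0]} in sample {s}")
        # class must be consistent with allele lengths for non-SV records
        sub = df["var_class"] == "substitution"
        if sub.any():
            ok = (df.loc[sub, "ref"].str.len() == 1) & (df.loc[sub, "alt"].str.len() == 1)
            if not ok.all():
                row = int(ok.index[~ok][0])
                raise ValidationError(f"row {row}: substitution with multi-base alleles")
        ins = df["var_class"] == "insertion"
        if ins.any():
            ok = df.loc[ins, "alt"].str.len() > df.loc[ins, "ref"].str.len()
            if not ok.all():
                row = int(ok.index[~ok][0])
                raise ValidationError(f"row {row}: insertion with alt not longer than ref")
        dele = df["var_class"] == "deletion"
        if dele.any():
            ok = df.loc[dele, "ref"].str.len() > df.loc[dele, "alt"].str.len()
            if not ok.all():
                row = int(ok.index[~ok][0])
                raise ValidationError(f"row {row}: deletion with ref not longer than alt")

    def __len__(self) -> int:
        return len(self.df)

    def X(self, sample: str) -> np.ndarray:
        return self.df[f"X:{sample}"].to_numpy(dtype=int)

    def n(self, sample: str) -> np.ndarray:
        return self.df[f"n:{sample}"].to_numpy(dtype=int)

    def X_matrix(self) -> np.ndarray:
        return np.column_stack([self.X(s) for s in self.samples])

    def n_matrix(self) -> np.ndarray:
        return np.column_stack([self.n(s) for s in self.samples])


def _infer_class(ref: str, alt: str) -> str:
    if alt.startswith("<") or alt in (".", "") or ref.startswith("<"):
        return "SV"
    if len(ref) == 1 and len(alt) == 1:
        return "substitution"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


def read_mutation_table(path, dialect: str = "tsv") -> MutationTable:
    """Load a mutation table from TSV or from a VCF subset.

    The VCF dialect uses CHROM/POS/REF/ALT plus per-sample AD (allele
    depths) and DP format fields; only the first ALT allele is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = sorted({c.split(":", 1)[1] for c in df.columns if c.startswith("X:")},
                         key=lambda s: list(df.columns).index(f"X:{s}"))
        for col in ("gene", "consequence", "context"):
            if col not in df.columns:
                df[col] = ""
            df[col] = df[col].fillna("")
        return MutationTable(df.reset_index(drop=True), samples)
    if dialect == "vcf-subset":
        from cyvcf2 import VCF
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows = []
        for i, var in enumerate(vcf):
            ad = var.format("AD")
            dp = var.format("DP")
            if ad is None or dp is None:
                raise ValidationError(f"record {i}: AD/DP format fields required")
            alt = var.ALT[0] if var.ALT else "."
            row = {
                "mutation_id": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alt}",
                "chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": alt,
                "var_class": _infer_class(var.REF, alt),
                "gene": "", "consequence": "", "context": "",
            }
            for j, s in enumerate(samples):
                row[f"X:{s}"] = max(int(ad[j][1]), 0)
                row[f"n:{s}"] = max(int(dp[j][0] if np.ndim(dp[j]) else dp[j]), 0)
            rows.append(row)
        cols = _MUT_FIXED_COLS + [f"{p}:{s}" for s in samples for p in ("X", "n")]
        df = pd.DataFrame(rows, columns=cols)
        return MutationTable(df, samples)
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_mutation_table(table: MutationTable, path) -> None:
    cols = _MUT_FIXED_COLS + [f"{p}:{s}" for s in table.samples for p in ("X", "n")]
    table.df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

@dataclass
class SegmentTable:
    """Allele-specific copy-number segments, one row per (sample, interval)."""

    df: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        for col in _SEG_COLS:
            if col not in df.columns:
                raise ValidationError(f"segment table missing column {col!r}")
        if len(df) == 0:
            return
        if (df["start"] >= df["end"]).any():
            raise ValidationError("segment with start >= end")
        if (df["total_cn"] < 0).any():
            raise ValidationError("negative total copy number")
        bad = df["minor_cn"] > df["total_cn"] - df["minor_cn"]
        if bad.any():
            raise ValidationError("minor copy number exceeds major")
        if ((df["frac"] <= 0) | (df["frac"] > 1)).any():
            raise ValidationError("subclonal fraction outside (0, 1]")
        for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
            g = grp.sort_values("start")
            overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
            if overlap.any():
                k = int(np.flatnonzero(overlap)[0])
                a = g.iloc[k]
                b = g.iloc[k + 1]
                raise ValidationError(
                    f"overlapping segments in sample {sample}: "
                    f"{chrom}:{a.start}-{a.end} and {chrom}:{b.start}-{b.end}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample"]))

    def lookup(self, sample: str, chrom, pos: int):
        """Segment row covering 1-based ``pos`` in ``sample``, or None."""
        g = self.df[(self.df["sample"] == sample) & (self.df["chrom"] == str(chrom))]
        hit = g[(g["start"] <= pos - 1) & (pos - 1 < g["end"])]
        if len(hit) == 0:
            return None
        return hit.iloc[0]


def read_segments(path) -> SegmentTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if "frac" not in df.columns:
        df["frac"] = 1.0
    df["frac"] = df["frac"].fillna(1.0)
    return SegmentTable(df.reset_index(drop=True))


def write_segments(segments: SegmentTable, path) -> None:
    segments.df[_SEG_COLS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature catalogues
# ---------------------------------------------------------------------------

@dataclass
class SignatureCatalog:
    """96-channel signature probability catalogue (channels x signatures).

    Rows follow the canonical COSMIC channel ordering; each column sums
    to one.
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if list(self.df.index) != list(CHANNELS):
            if set(self.df.index) != set(CHANNELS):
                raise ValidationError(
                    f"catalogue must have the 96 canonical channels, got {len(self.df)} rows")
            self.df = self.df.loc[list(CHANNELS)]
        if (self.df.to_numpy() < 0).any():
            raise ValidationError("negative signature probability")
        sums = self.df.sum(axis=0)
        off = (sums - 1.0).abs() > 1e-3
        if off.any():
            name = sums.index[off][0]
            raise ValidationError(
                f"signature column {name!r} sums to {sums[name]:.4f}, expected 1")
        # tidy tiny numerical drift so downstream mixtures are exact simplex points
        self.df = self.df / self.df.sum(axis=0)

    @property
    def names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def K(self) -> int:
        return self.df.shape[1]

    def matrix(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


def read_signature_catalog(path) -> SignatureCatalog:
    """Read a COSMIC-v2-style TSV catalogue.

    Accepts either a ``channel`` column with labels like ``A[C>A]A`` or the
    COSMIC pair of ``Substitution Type`` / ``Trinucleotide`` columns.
    Channel rows may appear in any order; they are restored to canonical
    order by label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if "channel" in df.columns:
        df = df.set_index("channel")
    elif "Substitution Type" in df.columns and "Trinucleotide" in df.columns:
        sub = df["Substitution Type"]
        tri = df["Trinucleotide"]
        labels = [f"{t[0]}[{s}]{t[2]}" for s, t in zip(sub, tri)]
        df = df.drop(columns=[c for c in ("Substitution Type", "Trinucleotide",
                                          "Somatic Mutation Type") if c in df.columns])
        df.index = labels
    else:
        raise ValidationError("catalogue needs a 'channel' column or COSMIC headers")
    unknown = [c for c in df.index if c not in CHANNEL_INDEX]
    if unknown or len(df) != 96:
        raise ValidationError(f"catalogue must have the 96 canonical channels, got {len(df)} rows")
    return SignatureCatalog(df.astype(float))


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    out = catalog.df.copy()
    out.insert(0, "channel", out.index)
    out.to_csv(path, sep="\t", index=False)
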