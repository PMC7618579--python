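"""Reading, validation, harmonisation and filtering of GWAS summary statistics.

A :class:`SummaryStatSet` holds one trait's per-variant association records
(effect size ``BETA`` on the log-odds scale for case-control traits or in
per-SD units for quantitative traits, its standard error ``SE``, two-sided
p-value ``P``, effect-allele frequency ``EAF`` and optional QC fields) in a
pandas DataFrame keyed by ``(CHR, BP, REF, ALT)``.  All sets are aligned to a
:class:`VariantPanel` — a reference SNP panel giving the canonical allele
order and reference-population minor-allele frequency — so that effect sizes
from different studies are directly comparable.

Coordinates are 1-based and intervals inclusive throughout (GWAS/VCF
convention).  Strand-flip rescue is deliberately not attempted: records whose
alleles match the panel in neither orientation are dropped with a reason
code, on the assumption that inputs have been verified positive-strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KEY_COLS",
    "MHC_INTERVAL",
    "GENOME_WIDE_SIG",
    "GenomicInterval",
    "QCThresholds",
    "ReadReport",
    "SummaryStatSet",
    "VariantPanel",
    "read_sumstats",
    "write_sumstats",
    "recompute_effects",
    "align_to_panel",
    "qc_filter",
    "exclude_interval",
    "join_sets",
    "read_gene_table",
]

#: key identifying a variant after panel alignment
KEY_COLS = ["CHR", "BP", "REF", "ALT"]

#: canonical column order for the on-disk TSV dialect
CANONICAL_COLS = [
    "CHR", "BP", "REF", "ALT", "BETA", "SE", "P", "EAF",
    "INFO", "HWE_P", "N", "N_CASES", "N_CONTROLS",
]

#: genome-wide significance threshold for a single GWAS
GENOME_WIDE_SIG = 5e-8

#: smallest p retained: p = 0 inputs are clipped here so -log10 p stays finite
_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


#: extended MHC interval excluded from genome-wide shared-architecture
#: analyses because of its long-range LD
MHC_INTERVAL = GenomicInterval("6", 24_000_000, 45_000_000)


@dataclass(frozen=True)
class QCThresholds:
    """Variant-level QC thresholds; filters on absent columns are skipped.

    Defaults: imputation info < 0.4, HWE p < 1e-6, reference MAF < 0.001 and
    |beta|/se > 10 remove a record.  All inequalities are strict.
    """

    min_info: float = 0.4
    min_hwe_p: float = 1e-6
    min_maf: float = 0.001
    max_beta_se_ratio: float = 10.0

    def __post_init__(self) -> None:
        for name in ("min_info", "min_hwe_p", "min_maf", "max_beta_se_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QC threshold {name} must be positive")


@dataclass
class ReadReport:
    """Accounting for rows dropped during read/validation."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


class SummaryStatSet:
    """Per-variant association records for one trait.

    Thin wrapper over a DataFrame with the canonical columns; enforces key
    uniqueness on (CHR, BP, REF, ALT) and basic range invariants.
    """

    def __init__(self, df: pd.DataFrame, trait_name: str = "trait",
                 trait_type: str = "case-control", validate: bool = True):
        if trait_type not in ("case-control", "quantitative"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        self.df = df.reset_index(drop=True)
        self.trait_name = trait_name
        self.trait_type = trait_type
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        missing = [c for c in ("CHR", "BP", "REF", "ALT") if c not in df.columns]
        if missing:
            raise ValueError(f"summary-statistic set lacks key columns {missing}")
        if (df["BP"] < 0).any():
            raise ValueError("negative positions")
        if df.duplicated(subset=KEY_COLS).any():
            raise ValueError("duplicate (CHR,BP,REF,ALT) keys")
        if "P" in df.columns:
            p = df["P"].dropna()
            if ((p <= 0) | (p > 1)).any():
                raise ValueError("p-values outside (0,1]")
        if "SE" in df.columns:
            se = df["SE"].dropna()
            if (se <= 0).any():
                raise ValueError("non-positive standard errors")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self, df: pd.DataFrame | None = None) -> "SummaryStatSet":
        return SummaryStatSet(self.df.copy() if df is None else df,
                              self.trait_name, self.trait_type, validate=False)

    def key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.df[KEY_COLS])


class VariantPanel:
    """Reference SNP panel: canonical allele order plus reference MAF.

    Emulates a common-variant panel (e.g. 1000 Genomes European SNPs with
    MAF > 0.005): columns CHR, BP, REF, ALT, MAF with MAF in (0, 0.5].
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            need = {"CHR", "BP", "REF", "ALT", "MAF"}
            if not need.issubset(self.df.columns):
                raise ValueError(f"panel needs columns {sorted(need)}")
            maf = self.df["MAF"]
            if ((maf <= 0) | (maf > 0.5)).any():
                raise ValueError("panel MAF outside (0, 0.5]")
            if self.df.duplicated(subset=KEY_COLS).any():
                raise ValueError("duplicate panel keys")

    def __len__(self) -> int:
        return len(self.df)


def _numeric(col: pd.Series) -> pd.Series:
    """Lenient numeric coercion (NaN for unparseable) that is correctly
    rounded, so a write/read round-trip is bit-exact."""
    num = pd.to_numeric(col, errors="coerce")
    mask = num.notna().to_numpy()
    if mask.any():
        exact = col[mask].astype(np.float64)
        num = num.astype(float)
        num.iloc[np.flatnonzero(mask)] = exact.to_numpy()
    return num


def _coerce_chrom(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.replace("^chr", "", regex=True)
    # normalise numeric-looking labels ("6.0" from float columns) to "6"
    return s.str.replace(r"\.0$", "", regex=True)


def read_sumstats(path, column_map: dict[str, str] | None = None, *,
                  trait_name: str = "trait", trait_type: str = "case-control",
                  swap_alleles: bool = False, sep: str = "\t",
                  ) -> tuple[SummaryStatSet, ReadReport]:
    """Read a delimited summary-statistic table into a validated set.

    ``column_map`` maps source column names to canonical fields (CHR, BP,
    REF, ALT, BETA, SE, P, EAF, OR, INFO, HWE_P, N, N_CASES, N_CONTROLS); it
    may be omitted when the file already uses canonical names.  Rows failing
    type coercion or range checks are dropped and counted in the returned
    :class:`ReadReport`.  ``swap_alleles`` exchanges REF and ALT on read, for
    sources whose effect/other columns are known to be mislabelled.  If the
    table carries OR but no BETA, effects are recomputed on read via
    :func:`recompute_effects`.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"empty summary-statistic file: {path}")
    if column_map:
        df = df.rename(columns=column_map)
    mandatory = ["CHR", "BP", "REF", "ALT"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise KeyError(f"missing mandatory columns {missing} after mapping")
    if not ({"BETA", "SE"}.issubset(df.columns) or {"OR", "P"}.issubset(df.columns)):
        raise KeyError("need (BETA,SE) or (OR,P) columns")

    report = ReadReport(n_input=len(df))
    df["CHR"] = _coerce_chrom(df["CHR"])

    numeric = [c for c in ("BP", "BETA", "SE", "P", "EAF", "OR", "INFO",
                           "HWE_P", "N", "N_CASES", "N_CONTROLS") if c in df.columns]
    for c in numeric:
        df[c] = _numeric(df[c])

    # required-value masks; optional fields may stay NaN
    ok = df["BP"].notna() & df["REF"].notna() & df["ALT"].notna()
    ok &= df["REF"].astype(str) != df["ALT"].astype(str)
    if "P" in df.columns:
        ok_p = df["P"].notna() & (df["P"] > 0) & (df["P"] <= 1)
        # p=0 would be clipped later, but NA/negative p is unusable when
        # effects must be recomputed from (OR, P)
        if "BETA" not in df.columns or "SE" not in df.columns:
            ok &= ok_p
        else:
            ok &= df["P"].isna() | (df["P"] > 0) & (df["P"] <= 1) | df["BETA"].notna()
    if "BETA" in df.columns and "SE" in df.columns:
        ok &= df["BETA"].notna() & df["SE"].notna() & (df["SE"] > 0)
    bad = int((~ok).sum())
    if bad:
        report.dropped["coercion_or_range"] = bad
    df = df[ok].copy()

    dup = df.duplicated(subset=mandatory, keep="first")
    if dup.any():
        report.dropped["duplicate_key"] = int(dup.sum())
        df = df[~dup]

    if swap_alleles:
        df[["REF", "ALT"]] = df[["ALT", "REF"]].to_numpy()
        if "EAF" in df.columns:
            df["EAF"] = 1.0 - df["EAF"]

    df["BP"] = df["BP"].astype(np.int64)
    s = SummaryStatSet(df, trait_name, trait_type, validate=False)
    if "BETA" not in df.columns or df["BETA"].isna().any():
        s, rec_report = recompute_effects(s)
        for k, v in rec_report.dropped.items():
            report.dropped[k] = report.dropped.get(k, 0) + v
    report.n_kept = len(s)
    return s, report


def write_sumstats(s: SummaryStatSet, path) -> None:
    """Write the canonical tab-separated dialect (gzip-transparent by suffix).

    Floats are written with 17 significant digits so a write/read round-trip
    reproduces every field to full double precision.
    """
    cols = [c for c in CANONICAL_COLS if c in s.df.columns]
    extra = [c for c in s.df.columns if c not in cols]
    s.df[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.17g")


def recompute_effects(s: SummaryStatSet) -> tuple[SummaryStatSet, ReadReport]:
    """Fill missing (BETA, SE) from (OR, P): beta = ln OR, se = |beta|/|z|.

    |z| = Phi^-1(1 - p/2).  p-values of 0 (or below the smallest positive
    double) are clipped to the representable floor before inversion.  Records
    with OR = 1 (beta 0) and no stated SE are dropped — their SE is
    undefined — as are records with p outside (0,1].
    """
    df = s.df.copy()
    report = ReadReport(n_input=len(df))
    if "BETA" not in df.columns:
        df["BETA"] = np.nan
    if "SE" not in df.columns:
        df["SE"] = np.nan

    need = df["BETA"].isna() | df["SE"].isna()
    if need.any():
        if "OR" not in df.columns or "P" not in df.columns:
            raise ValueError("records lack (BETA,SE) and no (OR,P) to recompute from")
        odds = df.loc[need, "OR"]
        p = df.loc[need, "P"]
        # p = 0 is clipped (keeps -log10 finite downstream); p < 0 or > 1 is
        # unusable
        bad_p = p.isna() | (p < 0) | (p > 1)
        bad_or = odds.isna() | (odds <= 0)
        beta = np.log(odds.to_numpy(float))
        p_clip = np.clip(p.to_numpy(float), _P_FLOOR, 1.0)
        z = stats.norm.isf(p_clip / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.abs(beta) / np.abs(z)
        zero_beta = (beta == 0.0) & df.loc[need, "SE"].isna().to_numpy()
        df.loc[need, "BETA"] = beta
        df.loc[need, "SE"] = np.where(df.loc[need, "SE"].notna(), df.loc[need, "SE"], se)
        drop = bad_p | bad_or | pd.Series(zero_beta, index=odds.index)
        for reason, mask in (("p_out_of_range", bad_p), ("bad_or", bad_or & ~bad_p),
                             ("zero_effect_no_se", pd.Series(zero_beta, index=odds.index) & ~bad_p & ~bad_or)):
            n = int(mask.sum())
            if n:
                report.dropped[reason] = n
        df = df.drop(index=drop[drop].index)

    bad_se = df["SE"].isna() | (df["SE"] <= 0) | ~np.isfinite(df["SE"])
    if bad_se.any():
        report.dropped["invalid_se"] = int(bad_se.sum())
        df = df[~bad_se]
    if "P" in df.columns:
        df["P"] = df["P"].clip(lower=_P_FLOOR)
    report.n_kept = len(df)
    return s.copy(df.reset_index(drop=True)), report


def flip_record_orientation(df: pd.DataFrame, mask) -> pd.DataFrame:
    """Flip allele orientation for rows in ``mask``: swap alleles, negate
    BETA, replace EAF by 1 - EAF.  Involutive."""
    df = df.copy()
    df.loc[mask, ["REF", "ALT"]] = df.loc[mask, ["ALT", "REF"]].to_numpy()
    if "BETA" in df.columns:
        df.loc[mask, "BETA"] = -df.loc[mask, "BETA"]
    if "EAF" in df.columns:
        df.loc[mask, "EAF"] = 1.0 - df.loc[mask, "EAF"]
    return df


def align_to_panel(s: SummaryStatSet, panel: VariantPanel,
                   ) -> tuple[SummaryStatSet, ReadReport]:
    """Align a set to the panel's allele order.

    A record keyed (other, effect) = (ref, alt) is kept unchanged; one keyed
    (effect, other) = (ref, alt) is flipped (beta negated, EAF complemented,
    alleles swapped).  Records matching neither orientation — including
    strand complements — and records absent from the panel are dropped.
    The panel MAF is attached as column ``PANEL_MAF``.  Idempotent.
    """
    report = ReadReport(n_input=len(s))
    pdf = panel.df[KEY_COLS + ["MAF"]]
    df = s.df.copy()
    if "PANEL_MAF" in df.columns:   # re-alignment: refresh the panel MAF
        df = df.drop(columns="PANEL_MAF")
    df["_row"] = np.arange(len(df))

    fwd = df.merge(pdf, on=KEY_COLS, how="inner")
    rev_key = df.rename(columns={"REF": "ALT", "ALT": "REF"})
    rev = rev_key.merge(pdf, on=KEY_COLS, how="inner")
    rev = rev[~rev["_row"].isin(fwd["_row"])].copy()
    # after the swapped-key merge, REF/ALT already hold the panel order;
    # flip the orientation-dependent statistics only
    if "BETA" in rev.columns:
        rev["BETA"] = -rev["BETA"]
    if "EAF" in rev.columns:
        rev["EAF"] = 1.0 - rev["EAF"]

    out = pd.concat([fwd, rev], ignore_index=True).sort_values("_row")
    n_drop = len(df) - len(out)
    if n_drop:
        report.dropped["no_panel_match"] = n_drop
    out = out.drop(columns=["_row"]).rename(columns={"MAF": "PANEL_MAF"})
    report.n_kept = len(out)
    return s.copy(out.reset_index(drop=True)), report


def qc_filter(s: SummaryStatSet, thresholds: QCThresholds = QCThresholds(),
              ) -> tuple[SummaryStatSet, dict[str, int]]:
    """Apply variant-level QC; returns survivors plus per-filter removal counts.

    Filters (strict inequalities): INFO < 0.4; HWE p < 1e-6; reference MAF
    (PANEL_MAF, else EAF folded to minor) < 0.001; |BETA|/SE > 10.  A filter
    whose column is absent, or NaN for a record, is skipped for that record.
    Counts are attributed to the first failing filter in the order above;
    counts plus survivors sum to the input size.
    """
    df = s.df
    n = len(df)
    removed_by = np.zeros(n, dtype=np.int8)  # 0 = keep; 1..4 = filter index

    def _mark(mask, code):
        removed_by[(removed_by == 0) & mask.to_numpy()] = code

    if "INFO" in df.columns:
        _mark(df["INFO"].notna() & (df["INFO"] < thresholds.min_info), 1)
    if "HWE_P" in df.columns:
        _mark(df["HWE_P"].notna() & (df["HWE_P"] < thresholds.min_hwe_p), 2)
    maf = None
    if "PANEL_MAF" in df.columns:
        maf = df["PANEL_MAF"]
    elif "EAF" in df.columns:
        maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
    if maf is not None:
        _mark(pd.Series(maf).notna() & (pd.Series(maf) < thresholds.min_maf), 3)
    if "BETA" in df.columns and "SE" in df.columns:
        ratio = (df["BETA"].abs() / df["SE"])
        _mark(ratio.notna() & (ratio > thresholds.max_beta_se_ratio), 4)

    names = {1: "info", 2: "hwe", 3: "maf", 4: "beta_se_ratio"}
    counts = {v: int((removed_by == k).sum()) for k, v in names.items()}
    out = df[removed_by == 0].reset_index(drop=True)
    return s.copy(out), counts


def exclude_interval(s: SummaryStatSet, iv: GenomicInterval = MHC_INTERVAL,
                     ) -> SummaryStatSet:
    """Drop records inside a genomic interval (default: the extended MHC,
    chr6:24,000,000-45,000,000, inclusive at both bounds)."""
    df = s.df
    inside = (df["CHR"].astype(str) == iv.chrom) & (df["BP"] >= iv.start) & (df["BP"] <= iv.end)
    return s.copy(df[~inside].reset_index(drop=True))


def join_sets(left: SummaryStatSet, right: SummaryStatSet, mode: str = "left",
              suffixes: tuple[str, str] = ("_x", "_y")) -> pd.DataFrame:
    """Join two panel-aligned sets on (CHR, BP, REF, ALT).

    ``mode='left'`` keeps every variant of ``left``, attaching the right-hand
    statistics where present (NaN otherwise); ``mode='inner'`` keeps the
    intersection.  Statistic columns carry the given suffixes.
    """
    if mode not in ("left", "inner"):
        raise ValueError(f"unknown join mode {mode!r}")
    for s in (left, right):
        if s.df.duplicated(subset=KEY_COLS).any():
            raise ValueError("duplicate keys in join input")
    out = left.df.merge(right.df, on=KEY_COLS, how=mode, suffixes=suffixes)
    if mode == "inner" and out.empty:
        import warnings
        warnings.warn("inner join of disjoint summary-statistic sets is empty")
    return out


def read_gene_table(path, zero_based: bool = False) -> pd.DataFrame:
    """Read a BED-like gene table (chrom, start, end, name) as 1-based
    inclusive coordinates; ``zero_based`` converts from BED half-open."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["CHR", "START", "END", "GENE"], dtype=str)
    df["CHR"] = _coerce_chrom(df["CHR"])
    df["START"] = pd.to_numeric(df["START"]).astype(np.int64)
    df["END"] = pd.to_numeric(df["END"]).astype(np.int64)
    if zero_based:
        df["START"] = df["START"] + 1
    if (df["START"] > df["END"]).any():
        raise ValueError("gene with start > end")
    return df
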