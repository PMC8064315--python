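"""Expression preprocessing and Reaction Activity Scores (RAS).

The pipeline turns an RNA-seq TPM table into per-reaction activity
scores in three steps:

1. ``zero_adjust`` — rescue technical zeros.  RNA-seq suffers from
   zero inflation; a single zero TPM on an essential enzyme closes an
   entire pathway.  For each gene with TPM 0 that a microarray dataset
   did measure, the ratio R = intensity / (genome-wide microarray
   median) is carried over: TPM* = R x (genome-wide RNA-seq median).
2. ``match_genes`` — resolve the model's gene symbols against the
   dataset, first directly, then through an alias table; genes still
   unmatched get the maximum matched TPM so that an unmeasured gene is
   never artificially limiting.
3. ``compute_ras`` — evaluate each reaction's GPR rule quantitatively
   (isozymes add, complex subunits take the minimum); single-gene
   reactions score their gene's TPM*; geneless reactions get no score
   and keep their default bounds downstream.

"Genome-wide median" is taken over all genes present in each dataset,
not only the metabolic ones.  Duplicate gene rows in input tables are
summed (transcript rows collapsing to gene level) and logged.  A RAS of
zero is a legal score — the zero-rescue step exists precisely because
zeros close reactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gpr import EmptyGPR, evaluate_gpr, gpr_genes
from .model import GEMModel

logger = logging.getLogger(__name__)


def _read_two_column_tsv(path: str | Path, value_name: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (symbol, {value_name})")
    sym, val = df.columns[:2]
    series = df.set_index(sym)[val].astype(float)
    if series.index.has_duplicates:
        ndup = series.index.duplicated().sum()
        logger.info("%s: summing %d duplicate gene rows", path, ndup)
        series = series.groupby(level=0).sum()
    return series


def _as_series(values: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(values, dtype=float)
    if s.index.has_duplicates:
        s = s.groupby(level=0).sum()
    return s


@dataclass
class ExpressionProfile:
    """RNA-seq expression: gene symbol -> TPM (>= 0)."""

    values: pd.Series
    label: str = ""

    def __post_init__(self) -> None:
        self.values = _as_series(self.values)
        if (self.values < 0).any():
            bad = self.values[self.values < 0].index[0]
            raise ValueError(f"negative TPM for gene {bad!r}")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "ExpressionProfile":
        return cls(_read_two_column_tsv(path, "tpm"), label=label or Path(path).stem)


@dataclass
class MicroarrayProfile:
    """Microarray intensities: gene symbol -> intensity (>= 0)."""

    values: pd.Series

    def __post_init__(self) -> None:
        self.values = _as_series(self.values)
        if self.values.empty:
            raise ValueError("microarray profile is empty")
        if (self.values < 0).any():
            raise ValueError("negative microarray intensity")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MicroarrayProfile":
        return cls(_read_two_column_tsv(path, "intensity"))


@dataclass
class AdjustedProfile:
    """Zero-adjusted TPM* values, with bookkeeping of what changed."""

    values: pd.Series
    label: str = ""
    adjusted_genes: set[str] = field(default_factory=set)
    unmatched_genes: set[str] = field(default_factory=set)
    unrescued_zeros: set[str] = field(default_factory=set)


@dataclass
class MatchReport:
    n_direct: int
    n_alias: int
    n_unmatched: int
    alias_matched: dict[str, str] = field(default_factory=dict)
    unmatched: set[str] = field(default_factory=set)
    assigned_value: float = 0.0


@dataclass
class RASTable:
    """Per-reaction activity scores; geneless reactions are absent."""

    scores: pd.Series
    label: str = ""

    def __post_init__(self) -> None:
        self.scores = _as_series(self.scores)
        if (self.scores < 0).any():
            raise ValueError("negative RAS")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"reaction_id": self.scores.index,
                           "ras": self.scores.values})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "RASTable":
        return cls(_read_two_column_tsv(path, "ras"), label=label)


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping dataset alias -> model gene symbol."""
    df = pd.read_csv(path, sep="\t")
    a, b = df.columns[:2]
    return dict(zip(df[a].astype(str), df[b].astype(str)))


def zero_adjust(rnaseq: ExpressionProfile,
                microarray: MicroarrayProfile) -> AdjustedProfile:
    """Rescue zero TPMs using microarray intensity ratios.

    For each gene g with TPM 0 and a microarray measurement::

        R_g    = intensity_g / median(all microarray intensities)
        TPM*_g = R_g * median(all RNA-seq TPMs)

    Genes with positive TPM are unchanged; zeros without microarray
    coverage stay 0 and are reported in ``unrescued_zeros``.
    """
    if rnaseq.values.empty:
        raise ValueError("RNA-seq profile is empty")
    ma_median = float(microarray.values.median())
    if ma_median <= 0:
        raise ValueError("microarray genome-wide median must be > 0")
    rna_median = float(rnaseq.values.median())
    adjusted = rnaseq.values.copy()
    zeros = adjusted.index[adjusted == 0]
    rescued, unrescued = set(), set()
    for gene in zeros:
        if gene in microarray.values.index:
            ratio = float(microarray.values[gene]) / ma_median
            adjusted[gene] = ratio * rna_median
            rescued.add(gene)
        else:
            unrescued.add(gene)
    if unrescued:
        logger.info("%d zero-TPM genes had no microarray value", len(unrescued))
    return AdjustedProfile(values=adjusted, label=rnaseq.label,
                           adjusted_genes=rescued, unrescued_zeros=unrescued)


def match_genes(model_genes: set[str],
                profile: ExpressionProfile | AdjustedProfile,
                aliases: Mapping[str, str] | None = None
                ) -> tuple[AdjustedProfile, MatchReport]:
    """Resolve model gene symbols against the expression dataset.

    Matching order: direct symbol, then alias lookup (alias table maps
    dataset symbol -> model symbol), then max-TPM assignment for genes
    that remain unmatched — an unmeasured gene must never be the
    limiting factor of a reaction.
    """
    if profile.values.empty:
        raise ValueError("expression profile is empty")
    aliases = dict(aliases or {})
    # invert: model symbol -> dataset symbols claiming to alias it
    to_dataset: dict[str, list[str]] = {}
    for ds_sym, model_sym in aliases.items():
        to_dataset.setdefault(model_sym, []).append(ds_sym)

    values: dict[str, float] = {}
    alias_matched: dict[str, str] = {}
    unmatched: set[str] = set()
    n_direct = 0
    data = profile.values
    for gene in sorted(model_genes):
        if gene in data.index:
            values[gene] = float(data[gene])
            n_direct += 1
            continue
        hit = next((ds for ds in to_dataset.get(gene, []) if ds in data.index),
                   None)
        if hit is not None:
            values[gene] = float(data[hit])
            alias_matched[gene] = hit
        else:
            unmatched.add(gene)
    matched_max = 0.0
    if unmatched:
        matched_vals = pd.Series(values, dtype=float)
        matched_max = float(matched_vals.max()) if not matched_vals.empty \
            else float(data.max())
        for gene in unmatched:
            values[gene] = matched_max
    prior_adjusted = getattr(profile, "adjusted_genes", set())
    prior_unrescued = getattr(profile, "unrescued_zeros", set())
    out = AdjustedProfile(values=pd.Series(values, dtype=float),
                          label=getattr(profile, "label", ""),
                          adjusted_genes=set(prior_adjusted) & set(values),
                          unmatched_genes=set(unmatched),
                          unrescued_zeros=set(prior_unrescued) & set(values))
    report = MatchReport(n_direct=n_direct, n_alias=len(alias_matched),
                         n_unmatched=len(unmatched),
                         alias_matched=alias_matched, unmatched=unmatched,
                         assigned_value=matched_max if unmatched else 0.0)
    return out, report


def compute_ras(model: GEMModel,
                profile: AdjustedProfile | ExpressionProfile) -> RASTable:
    """Evaluate every gene-associated reaction's GPR into a RAS.

    Raises
    ------
    KeyError
        Naming both gene and reaction, if a GPR symbol is missing from
        the profile (run :func:`match_genes` first).
    """
    values = profile.values
    scores: dict[str, float] = {}
    for rid, expr in model.gprs.items():
        if isinstance(expr, EmptyGPR):
            continue
        missing = gpr_genes(expr) - set(values.index)
        if missing:
            gene = sorted(missing)[0]
            raise KeyError(
                f"gene {gene!r} (reaction {rid!r}) missing from expression profile")
        scores[rid] = evaluate_gpr(expr, values)
    return RASTable(scores=pd.Series(scores, dtype=float),
                    label=getattr(profile, "label", ""))


def compare_profiles(a, b, outlier_log10: float = 2.0) -> dict:
    """Per-item ratios b/a between two RAS tables or profiles.

    Ratios are defined where a > 0.  The summary reports the standard
    deviation of the ratios and the count of items with
    ``|log10 ratio| > outlier_log10`` (dispersion diagnostics of the
    kind used to compare RAS vs TPM* variability between cell lines).
    """
    sa = a.scores if isinstance(a, RASTable) else a.values
    sb = b.scores if isinstance(b, RASTable) else b.values
    shared = sa.index.intersection(sb.index)
    if shared.empty:
        raise ValueError("profiles share no identifiers")
    sa, sb = sa[shared], sb[shared]
    defined = sa > 0
    ratio = (sb[defined] / sa[defined]).astype(float)
    log10 = pd.Series(np.log10(ratio.where(ratio > 0)), index=ratio.index)
    table = pd.DataFrame({"a": sa, "b": sb})
    table["ratio"] = ratio
    table["log10_ratio"] = log10
    outliers = int((log10.abs() > outlier_log10).sum())
    return {
        "table": table,
        "n_shared": int(len(shared)),
        "ratio_sd": float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0,
        "n_outliers": outliers,
        "outlier_log10": outlier_log10,
    }
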