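"""Depth-aware genotype quality control for GBS call matrices.

Implements the filtering scheme typical of low-coverage GBS data: homozygous
calls are only trusted at a minimum total depth (four reads by default,
since a true heterozygote sampled three times shows a single allele with
probability 1/4 per read pattern), heterozygous calls require reads from
both alleles, and markers/individuals are dropped on missingness, minor
allele frequency and allele-count rules.  A simple reliability index —
the sum of standardized call rate and standardized mean depth — ranks
markers for the parentage panel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, CallMatrix

__all__ = [
    "FilterConfig",
    "mask_low_confidence_calls",
    "compute_marker_stats",
    "filter_markers",
    "filter_individuals",
    "marker_reliability_index",
    "select_paternity_panel",
]


@dataclass
class FilterConfig:
    """Thresholds for call masking, marker/individual filters and the panel.

    Defaults follow common GBS practice for SNP discovery: keep markers with
    missingness < 0.70 and MAF > 0.01, drop individuals with > 0.95 missing.
    The parentage panel is stricter (missingness <= 0.50, MAF >= 0.02) and
    keeps the ``panel_size`` highest-index markers.
    """

    min_hom_depth: int = 4
    min_het_reads_each: int = 1
    max_marker_missing: float = 0.70
    min_maf: float = 0.01
    max_individual_missing: float = 0.95
    panel_max_missing: float = 0.50
    panel_min_maf: float = 0.02
    panel_size: int = 2500

    def __post_init__(self) -> None:
        for name in ("max_marker_missing", "min_maf",
                     "max_individual_missing", "panel_max_missing",
                     "panel_min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def mask_low_confidence_calls(raw: CallMatrix,
                              cfg: FilterConfig | None = None) -> CallMatrix:
    """Set depth-unsupported calls to missing.

    A homozygous call with total depth below ``min_hom_depth`` becomes
    missing; a heterozygous call is kept only when each allele is covered
    by at least ``min_het_reads_each`` reads.  No call is ever changed to a
    different non-missing state.
    """
    cfg = cfg or FilterConfig()
    if raw.allele_depths is None:
        raise ValueError(
            "allele depths are required for call masking: the depth rules "
            "are undefined without per-call read counts"
        )
    out = raw.copy()
    g = out.genotypes
    ref = out.allele_depths[:, :, 0]
    alt = out.allele_depths[:, :, 1]
    total = ref + alt
    hom = (g == 0) | (g == 2)
    g[hom & (total < cfg.min_hom_depth)] = MISSING
    het = g == HET
    weak_het = het & ((ref < cfg.min_het_reads_each) |
                      (alt < cfg.min_het_reads_each))
    g[weak_het] = MISSING
    return out


def compute_marker_stats(matrix: CallMatrix) -> pd.DataFrame:
    """Per-marker call rate, MAF, mean depth and observed allele count."""
    g = matrix.genotypes
    called = g != MISSING
    percent_present = called.mean(axis=0)
    maf = matrix.minor_allele_frequencies()
    mean_depth = matrix.mean_depths()
    has_ref = ((g == 0) | (g == 1)).any(axis=0)
    has_alt = ((g == 2) | (g == 1)).any(axis=0)
    n_alleles = has_ref.astype(int) + has_alt.astype(int)
    if "multiallelic" in matrix.markers.columns:
        n_alleles = np.where(matrix.markers["multiallelic"].to_numpy(),
                             3, n_alleles)
    return pd.DataFrame(
        {
            "percent_present": percent_present,
            "maf": maf,
            "mean_depth": mean_depth,
            "n_alleles": n_alleles,
        },
        index=matrix.markers.index,
    )


def filter_markers(
    matrix: CallMatrix, cfg: FilterConfig | None = None
) -> tuple[CallMatrix, pd.DataFrame]:
    """Drop markers failing missingness, MAF or biallelicity rules.

    Keeps markers with missing fraction strictly below ``max_marker_missing``
    and MAF strictly above ``min_maf``; markers with more than two observed
    alleles (flagged multiallelic on input) are discarded.  Returns the
    filtered matrix and the stats of the retained markers.
    """
    cfg = cfg or FilterConfig()
    stats = compute_marker_stats(matrix)
    missing_frac = 1.0 - stats["percent_present"].to_numpy()
    maf = stats["maf"].to_numpy()
    fail_missing = missing_frac >= cfg.max_marker_missing
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf > cfg.min_maf)  # NaN MAF (all-missing) also fails
    fail_allelic = stats["n_alleles"].to_numpy() > 2
    keep = ~(fail_missing | fail_maf | fail_allelic)
    if not keep.any():
        raise ValueError(
            "no markers survive filtering "
            f"(missing>=thr: {int(fail_missing.sum())}, "
            f"maf<=thr: {int(fail_maf.sum())}, "
            f"multiallelic: {int(fail_allelic.sum())})"
        )
    kept_ids = matrix.markers.index[keep]
    return matrix.subset(markers=kept_ids), stats.loc[kept_ids]


def filter_individuals(matrix: CallMatrix,
                       cfg: FilterConfig | None = None) -> CallMatrix:
    """Drop individuals with missing fraction strictly above the threshold."""
    cfg = cfg or FilterConfig()
    missing = matrix.individual_missing_fraction()
    keep = missing <= cfg.max_individual_missing
    if keep.all():
        return matrix
    kept = [name for name, k in zip(matrix.individuals, keep) if k]
    return matrix.subset(individuals=kept)


def marker_reliability_index(stats: pd.DataFrame) -> pd.DataFrame:
    """Score markers by standardized call rate plus standardized mean depth.

    Each component is z-scored across markers; a component with zero
    variance contributes 0.  The index is monotone increasing in both call
    rate and depth.
    """
    if stats.empty:
        raise ValueError("marker stats are empty")

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            return np.zeros_like(x, dtype=float)
        return (x - x.mean()) / sd

    out = stats.copy()
    out["index_score"] = zscore(stats["percent_present"].to_numpy()) + zscore(
        stats["mean_depth"].to_numpy()
    )
    return out


def select_paternity_panel(stats: pd.DataFrame,
                           cfg: FilterConfig | None = None) -> pd.Index:
    """Pick the parentage marker panel: the ``panel_size`` markers with the
    highest reliability index among those with missingness <= 0.50 and
    MAF >= 0.02.  Ties are broken by marker id so the panel is deterministic.
    """
    cfg = cfg or FilterConfig()
    if "index_score" not in stats.columns:
        stats = marker_reliability_index(stats)
    ok = (1.0 - stats["percent_present"] <= cfg.panel_max_missing) & (
        stats["maf"] >= cfg.panel_min_maf
    )
    survivors = stats.loc[ok]
    # stable sort on a pre-sorted-by-id frame gives lexicographic tie-break
    ranked = (
        survivors.sort_index()
        .sort_values("index_score", ascending=False, kind="stable")
    )
    if len(ranked) < cfg.panel_size:
        warnings.warn(
            f"only {len(ranked)} markers qualify for a panel of "
            f"{cfg.panel_size}; returning all of them",
            stacklevel=2,
        )
        return ranked.index
    return ranked.index[: cfg.panel_size]
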