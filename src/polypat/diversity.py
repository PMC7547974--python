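"""Mating diversity summaries from a female x male progeny-count matrix.

The polycross produces half-sib seed lots; once paternity is assigned,
every offspring becomes a count in an ordered (mother, father) cell of the
full-diallel progeny matrix.  Shannon's index over family frequencies
measures how evenly the realized crosses cover the diallel: a balanced set
of k families reaches the maximum H = ln k, so exp(H) is the "effective"
number of balanced crosses a direct-crossing program would need to match
the polycross's diversity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FamilyStats",
    "build_progeny_matrix",
    "shannon_index",
    "family_summary",
    "fecundity_correlation",
    "min_crosses_for_diversity",
]


@dataclass
class FamilyStats:
    """Counts and diversity of realized families in a progeny matrix."""

    shannon_h: float
    n_ordered_families: int
    n_unordered_families: int
    n_successful_fathers: int
    father_progeny_min: float
    father_progeny_median: float
    father_progeny_mean: float
    father_progeny_max: float
    total_progeny: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_progeny_matrix(assignments: pd.DataFrame,
                         parents: list[str]) -> pd.DataFrame:
    """P x P ordered progeny counts (rows = female parent, columns = male).

    One count per assigned offspring (``father`` non-null); unassigned
    offspring are excluded and unobserved combinations stay 0.  Diagonal
    cells hold self-progeny.
    """
    matrix = pd.DataFrame(
        0, index=pd.Index(parents, name="female"),
        columns=pd.Index(parents, name="male"), dtype=int,
    )
    assigned = assignments[assignments["father"].notna()]
    known = set(parents)
    offenders = sorted(
        set(assigned["mother"]).union(assigned["father"]) - known
    )
    if offenders:
        raise ValueError(f"assigned parents not in parent list: {offenders}")
    counts = assigned.groupby(["mother", "father"]).size()
    for (mo, fa), n in counts.items():
        matrix.loc[mo, fa] = int(n)
    return matrix


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over families with count > 0."""
    c = np.asarray(counts, dtype=float).ravel()
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("total family count must be positive")
    p = c / total
    return float(-(p * np.log(p)).sum())


def family_summary(matrix: pd.DataFrame) -> FamilyStats:
    """Family counts, per-father totals and Shannon H for a progeny matrix.

    Ordered families are nonzero cells (reciprocals distinct, selfs
    included); unordered families pool cell (A, B) with (B, A), a self
    family counting on its own.
    """
    counts = matrix.to_numpy()
    if (counts < 0).any():
        raise ValueError("negative progeny counts")
    nonzero = counts > 0
    n_ordered = int(nonzero.sum())
    pooled = counts + counts.T
    iu = np.triu_indices(len(counts), k=0)
    n_unordered = int((pooled[iu] > 0).sum())
    father_totals = counts.sum(axis=0).astype(float)
    successful = father_totals[father_totals > 0]
    total = int(counts.sum())
    h = shannon_index(counts) if total > 0 else 0.0
    return FamilyStats(
        shannon_h=h,
        n_ordered_families=n_ordered,
        n_unordered_families=n_unordered,
        n_successful_fathers=int(len(successful)),
        father_progeny_min=float(successful.min()) if len(successful) else 0.0,
        father_progeny_median=float(np.median(successful))
        if len(successful) else 0.0,
        father_progeny_mean=float(successful.mean()) if len(successful)
        else 0.0,
        father_progeny_max=float(successful.max()) if len(successful) else 0.0,
        total_progeny=total,
    )


def fecundity_correlation(inflorescences: pd.Series,
                          matrix: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of inflorescence count with ln(progeny count),
    over fathers that sired at least one offspring.  Returns (r, p-value).
    """
    father_totals = matrix.sum(axis=0)
    successful = father_totals[father_totals > 0]
    common = successful.index.intersection(inflorescences.index)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 successful fathers with inflorescence data, "
            f"have {len(common)}"
        )
    x = inflorescences.loc[common].to_numpy(dtype=float)
    y = np.log(successful.loc[common].to_numpy(dtype=float))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has no variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def min_crosses_for_diversity(h_target: float) -> int:
    """Smallest number k of equally represented crosses with ln k >= H.

    This is the balanced-family equivalent of a Shannon index: a program
    making k equal-size families attains exactly H = ln k.
    """
    if h_target < 0:
        raise ValueError("H must be non-negative")
    if h_target == 0:
        return 1
    k = math.ceil(math.exp(h_target))
    # guard against float noise around exact powers (exp(ln k) slightly high)
    while k > 1 and math.log(k - 1) >= h_target:
        k -= 1
    return k
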