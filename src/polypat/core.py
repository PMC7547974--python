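"""Shared containers for genotype data.

Genotype calls are stored as small integers: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing.  Allele read
depths, when present, are per-call (ref, alt) read counts.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: Column order required of the marker table.
MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class CallMatrix:
    """Individuals x markers genotype calls with optional allele depths.

    Parameters
    ----------
    individuals
        Sample identifiers, one per row of ``genotypes``.
    markers
        DataFrame indexed by marker id with columns ``chrom`` (str),
        ``pos`` (1-based int), ``ref``, ``alt`` and optionally a boolean
        ``multiallelic`` flag set by the VCF reader.
    genotypes
        ``(n_individuals, n_markers)`` int8 array of call codes.
    allele_depths
        ``(n_individuals, n_markers, 2)`` int array of (ref, alt) read
        counts, or ``None`` when depth information is unavailable.
    """

    individuals: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray
    allele_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_ind, n_mark = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValueError(
                f"{len(self.individuals)} individuals but genotype matrix has "
                f"{n_ind} rows"
            )
        if len(self.markers) != n_mark:
            raise ValueError(
                f"{len(self.markers)} markers but genotype matrix has "
                f"{n_mark} columns"
            )
        if self.allele_depths is not None:
            if self.allele_depths.shape != (n_ind, n_mark, 2):
                raise ValueError("allele_depths shape mismatch")
            if (self.allele_depths < 0).any():
                raise ValueError("negative allele depths")
        missing = set(MARKER_COLUMNS) - set(self.markers.columns)
        if missing:
            raise ValueError(f"marker table lacks columns: {sorted(missing)}")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    def marker_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def individual_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def minor_allele_frequencies(self) -> np.ndarray:
        """Allele-counting MAF per marker over non-missing calls.

        Markers with no non-missing call get NaN.
        """
        g = self.genotypes
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        total = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_alt = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        return np.minimum(f_alt, 1.0 - f_alt)

    def mean_depths(self) -> np.ndarray:
        """Mean total read depth per marker (zeros when depths absent)."""
        if self.allele_depths is None:
            return np.zeros(self.n_markers)
        return self.allele_depths.sum(axis=2).mean(axis=0)

    # ------------------------------------------------------------------
    def subset(
        self,
        individuals: np.ndarray | list | None = None,
        markers: np.ndarray | list | None = None,
    ) -> "CallMatrix":
        """Return a new matrix restricted to the given individual / marker
        identifiers (order follows the arguments)."""
        ind_idx = np.arange(self.n_individuals)
        if individuals is not None:
            lookup = {name: i for i, name in enumerate(self.individuals)}
            ind_idx = np.array([lookup[name] for name in individuals], dtype=int)
        mark_idx = np.arange(self.n_markers)
        if markers is not None:
            mark_idx = self.markers.index.get_indexer(pd.Index(markers))
            if (mark_idx < 0).any():
                bad = list(pd.Index(markers)[mark_idx < 0][:5])
                raise KeyError(f"unknown markers: {bad}")
        depths = None
        if self.allele_depths is not None:
            depths = self.allele_depths[np.ix_(ind_idx, mark_idx)]
        return CallMatrix(
            individuals=[self.individuals[i] for i in ind_idx],
            markers=self.markers.iloc[mark_idx].copy(),
            genotypes=self.genotypes[np.ix_(ind_idx, mark_idx)].copy(),
            allele_depths=depths,
        )

    def copy(self) -> "CallMatrix":
        return CallMatrix(
            individuals=list(self.individuals),
            markers=self.markers.copy(),
            genotypes=self.genotypes.copy(),
            allele_depths=None
            if self.allele_depths is None
            else self.allele_depths.copy(),
        )


@dataclass
class GeneticMap:
    """Per-chromosome marker positions in centimorgans.

    ``positions[chrom]`` is a strictly increasing float array; marker ids
    are stored in chromosome-major order matching genotype column order.
    """

    chroms: list[str]
    positions: dict[str, np.ndarray]
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom in self.chroms:
            pos = self.positions[chrom]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if not self.marker_ids:
            self.marker_ids = [
                f"{chrom}_{i:05d}"
                for chrom in self.chroms
                for i in range(len(self.positions[chrom]))
            ]

    @property
    def n_markers(self) -> int:
        return sum(len(self.positions[c]) for c in self.chroms)

    def chrom_slices(self) -> dict[str, slice]:
        """Slice of the flat marker axis covered by each chromosome."""
        out: dict[str, slice] = {}
        start = 0
        for chrom in self.chroms:
            n = len(self.positions[chrom])
            out[chrom] = slice(start, start + n)
            start += n
        return out

    def marker_table(self, cm_to_bp: float = 1e6) -> pd.DataFrame:
        """Marker table with 1-based bp positions (``pos = round(cM*scale)+1``)."""
        rows = []
        for chrom in self.chroms:
            for cm in self.positions[chrom]:
                rows.append((chrom, int(round(cm * cm_to_bp)) + 1, cm))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "cm"])
        df.index = pd.Index(self.marker_ids, name="marker")
        df["ref"] = "A"
        df["alt"] = "T"
        return df[["chrom", "pos", "ref", "alt", "cm"]]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a global seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
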