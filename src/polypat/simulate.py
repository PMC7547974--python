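"""Polycross simulation under two-locus gametophytic self-incompatibility.

Grasses carry a gametophytic SI system governed by two unlinked multiallelic
loci, S and Z.  A pollen grain expressing haploid alleles (s, z) is rejected
by a pistil if and only if s matches one of the pistil's two S alleles AND z
matches one of its two Z alleles; any single mismatch makes the cross
compatible.  This module simulates a founder population, meiosis with
recombination (Haldane map function), an open polycross in which pollen
success is shaped by SI plus per-parent fecundity, and a low-coverage
genotyping-by-sequencing (GBS) observation layer with depth-dependent calls.

Two founder-haplotype models are provided.  ``independent`` draws every
marker allele independently from its frequency (no linkage disequilibrium).
``bottleneck`` builds each founder haplotype as a recombinant mosaic of a
small pool of ancestral haplotypes, emulating a breeding population descended
from a handful of plants; this creates LD that decays with map distance and
couples markers near the S and Z loci to the segregating SI alleles, which is
what allows association scans to localize them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CallMatrix, GeneticMap

__all__ = [
    "SIModel",
    "FounderSet",
    "MatingDesign",
    "ProgenySet",
    "simulate_founders",
    "is_compatible",
    "make_gamete",
    "make_gametes",
    "simulate_polycross",
    "simulate_gbs",
]


@dataclass(frozen=True)
class SIModel:
    """Two-locus gametophytic SI system.

    ``k_s`` / ``k_z`` count the distinct S / Z alleles segregating in the
    founders; ``s_locus`` and ``z_locus`` are (chromosome, position-cM)
    pairs placing the two loci on the genetic map.
    """

    k_s: int = 4
    k_z: int = 4
    s_locus: tuple[str, float] = ("Chr01", 75.0)
    z_locus: tuple[str, float] = ("Chr02", 75.0)

    def __post_init__(self) -> None:
        if self.k_s < 1 or self.k_z < 1:
            raise ValueError("k_s and k_z must be >= 1")
        if self.s_locus == self.z_locus:
            raise ValueError("S and Z loci must be distinct positions")

    def validate_map(self, gmap: GeneticMap) -> None:
        for name, (chrom, cm) in (("S", self.s_locus), ("Z", self.z_locus)):
            if chrom not in gmap.positions:
                raise ValueError(f"{name} locus chromosome {chrom} not in map")
            pos = gmap.positions[chrom]
            if not (pos[0] <= cm <= pos[-1]):
                raise ValueError(
                    f"{name} locus at {cm} cM outside mapped interval "
                    f"[{pos[0]}, {pos[-1]}] on {chrom}"
                )


@dataclass
class FounderSet:
    """Founder parents: phased marker haplotypes plus SI genotypes.

    ``haplotypes`` is ``(n_parents, 2, n_markers)`` with 0 = reference
    allele, 1 = alternate.  ``si_s``/``si_z`` are ``(n_parents, 2)`` allele
    indices carried on haplotype 0 and 1, so SI alleles are physically
    linked to the marker haplotypes.
    """

    ids: list[str]
    gmap: GeneticMap
    haplotypes: np.ndarray
    si_s: np.ndarray
    si_z: np.ndarray
    si_model: SIModel
    allele_freqs: np.ndarray  # true alternate-allele frequency per marker

    def __post_init__(self) -> None:
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValueError("each parent must have exactly 2 haplotypes")
        if m != self.gmap.n_markers:
            raise ValueError("haplotype/marker-count mismatch")
        if self.si_s.shape != (n, 2) or self.si_z.shape != (n, 2):
            raise ValueError("SI genotype shape mismatch")
        if self.si_s.max(initial=0) >= self.si_model.k_s:
            raise ValueError("S allele index out of range")
        if self.si_z.max(initial=0) >= self.si_model.k_z:
            raise ValueError("Z allele index out of range")
        self.si_model.validate_map(self.gmap)

    @property
    def n_parents(self) -> int:
        return self.haplotypes.shape[0]

    def genotype_dosages(self) -> np.ndarray:
        """(n_parents, n_markers) alternate-allele dosages in {0,1,2}."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def si_genotype_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s1": self.si_s[:, 0],
                "s2": self.si_s[:, 1],
                "z1": self.si_z[:, 0],
                "z2": self.si_z[:, 1],
            },
            index=pd.Index(self.ids, name="parent"),
        )


@dataclass
class MatingDesign:
    """Polycross design: per-parent fecundity weights and seeds per mother.

    ``fecundity`` acts as a proxy for inflorescence count: a parent's chance
    of being drawn as pollen donor is proportional to its weight.
    """

    fecundity: np.ndarray
    progeny_per_mother: int = 45
    max_pollen_attempts: int = 200
    selfing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.fecundity = np.asarray(self.fecundity, dtype=float)
        if (self.fecundity <= 0).any():
            raise ValueError("fecundity weights must be positive")
        if self.progeny_per_mother < 0:
            raise ValueError("progeny_per_mother must be >= 0")
        if not 0.0 <= self.selfing_rate < 1.0:
            raise ValueError("selfing_rate must lie in [0, 1)")


@dataclass
class ProgenySet:
    """True (noise-free) progeny genotypes plus the generating pedigree.

    ``pedigree`` records, per offspring, the mother, the accepted father and
    the transmitted S/Z alleles of both gametes, so SI bookkeeping can be
    audited after the fact.
    """

    ids: list[str]
    genotypes: np.ndarray  # (n_offspring, n_markers) dosages 0/1/2
    pedigree: pd.DataFrame
    skipped: pd.Series  # per-mother count of seeds with no compatible pollen

    @property
    def n_offspring(self) -> int:
        return self.genotypes.shape[0]


# ----------------------------------------------------------------------
# founders
# ----------------------------------------------------------------------


def _default_map(n_chromosomes: int, markers_per_chromosome: int,
                 chrom_length_cm: float) -> GeneticMap:
    chroms = [f"Chr{i + 1:02d}" for i in range(n_chromosomes)]
    positions = {
        c: np.linspace(0.0, chrom_length_cm, markers_per_chromosome)
        for c in chroms
    }
    return GeneticMap(chroms=chroms, positions=positions)


def _draw_het_pair(rng: np.random.Generator, k: int) -> np.ndarray:
    return rng.choice(k, size=2, replace=False)


def simulate_founders(
    n_parents: int = 89,
    n_chromosomes: int = 21,
    markers_per_chromosome: int = 120,
    maf_range: tuple[float, float] = (0.05, 0.5),
    si_model: SIModel | None = None,
    seed: int = 0,
    chrom_length_cm: float = 150.0,
    n_ancestral_haplotypes: int | None = None,
    copying_generations: float = 4.0,
    si_divergence_scale_cm: float = 4.0,
    enforce_si_heterozygosity: bool = True,
) -> FounderSet:
    """Simulate a founder population for the polycross.

    With ``n_ancestral_haplotypes=None`` marker alleles are drawn
    independently per frequency (no LD).  With an integer value ``A`` each
    founder haplotype is a mosaic copied from ``A`` ancestral haplotypes,
    with ancestry switching between adjacent loci at probability
    ``1 - exp(-copying_generations * d / 100)`` for map distance ``d`` cM;
    ancestral haplotypes also carry the S and Z alleles, creating LD between
    SI loci and nearby markers.

    SI loci sit under strong balancing selection, so their allelic lineages
    are ancient and the flanking haplotypes of different functional alleles
    are deeply diverged.  The bottleneck mode emulates this: each S (and Z)
    allele owns a lineage haplotype profile, and an ancestral haplotype
    carrying that allele copies the profile at markers near the locus with
    probability ``exp(-d / si_divergence_scale_cm)`` for distance ``d`` cM,
    so nearby markers tag the SI lineage and the tagging decays outward.

    Founders are forced heterozygous at S and at Z whenever the respective
    allele count is >= 2, because a strictly self-incompatible plant cannot
    be produced by a pollen grain matching both pistil alleles and is
    therefore never SI-homozygous.
    """
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    si_model = si_model or SIModel()
    if enforce_si_heterozygosity and (si_model.k_s == 1 or si_model.k_z == 1):
        raise ValueError(
            "cannot enforce SI heterozygosity with a single S or Z allele: "
            "a one-allele locus admits only homozygous genotypes"
        )
    rng = np.random.default_rng(seed)
    gmap = _default_map(n_chromosomes, markers_per_chromosome, chrom_length_cm)
    si_model.validate_map(gmap)
    m = gmap.n_markers
    freqs = rng.uniform(lo, hi, size=m)  # alternate allele is the minor one

    if n_ancestral_haplotypes is None:
        haplos = (rng.random((n_parents, 2, m)) < freqs).astype(np.int8)
        si_s = np.empty((n_parents, 2), dtype=np.int64)
        si_z = np.empty((n_parents, 2), dtype=np.int64)
        for i in range(n_parents):
            if enforce_si_heterozygosity:
                si_s[i] = _draw_het_pair(rng, si_model.k_s)
                si_z[i] = _draw_het_pair(rng, si_model.k_z)
            else:
                si_s[i] = rng.integers(si_model.k_s, size=2)
                si_z[i] = rng.integers(si_model.k_z, size=2)
    else:
        haplos, si_s, si_z = _bottleneck_founders(
            rng,
            gmap,
            freqs,
            si_model,
            n_parents,
            n_ancestral_haplotypes,
            copying_generations,
            si_divergence_scale_cm,
            enforce_si_heterozygosity,
        )

    ids = [f"P{i + 1:03d}" for i in range(n_parents)]
    return FounderSet(
        ids=ids,
        gmap=gmap,
        haplotypes=haplos,
        si_s=si_s,
        si_z=si_z,
        si_model=si_model,
        allele_freqs=freqs,
    )


def _bottleneck_founders(
    rng: np.random.Generator,
    gmap: GeneticMap,
    freqs: np.ndarray,
    si_model: SIModel,
    n_parents: int,
    n_ancestral: int,
    generations: float,
    divergence_scale: float,
    enforce_het: bool,
):
    """Founder haplotypes as ancestry mosaics over a small haplotype pool."""
    m = gmap.n_markers
    pool = (rng.random((n_ancestral, m)) < freqs).astype(np.int8)
    # distribute SI alleles over the pool so every allele is represented
    pool_s = np.resize(np.arange(si_model.k_s), n_ancestral)
    pool_z = np.resize(np.arange(si_model.k_z), n_ancestral)
    rng.shuffle(pool_s)
    rng.shuffle(pool_z)
    if divergence_scale and divergence_scale > 0:
        _apply_lineage_divergence(rng, gmap, freqs, pool, pool_s,
                                  si_model.k_s, si_model.s_locus,
                                  divergence_scale)
        _apply_lineage_divergence(rng, gmap, freqs, pool, pool_z,
                                  si_model.k_z, si_model.z_locus,
                                  divergence_scale)

    layout = _chromosome_layout(gmap, si_model)

    def draw_haplotypes(n: int):
        hap = np.empty((n, m), dtype=np.int8)
        s_allele = np.empty(n, dtype=np.int64)
        z_allele = np.empty(n, dtype=np.int64)
        for chrom in layout:
            anc = _ancestry_mosaic(rng, chrom["distances"], n_ancestral, n,
                                   generations)
            alleles = pool[anc, chrom["merged_to_flat"][None, :]]
            hap[:, chrom["slice"]] = alleles[:, chrom["is_marker"]]
            if chrom["s_index"] is not None:
                s_allele[:] = pool_s[anc[:, chrom["s_index"]]]
            if chrom["z_index"] is not None:
                z_allele[:] = pool_z[anc[:, chrom["z_index"]]]
        return hap, s_allele, z_allele

    haplos = np.empty((n_parents, 2, m), dtype=np.int8)
    si_s = np.empty((n_parents, 2), dtype=np.int64)
    si_z = np.empty((n_parents, 2), dtype=np.int64)
    h0, s0, z0 = draw_haplotypes(n_parents)
    haplos[:, 0] = h0
    si_s[:, 0] = s0
    si_z[:, 0] = z0
    # second haplotype: redraw per parent until SI-heterozygous if required
    pending = np.arange(n_parents)
    for _ in range(200):
        h1, s1, z1 = draw_haplotypes(len(pending))
        haplos[pending, 1] = h1
        si_s[pending, 1] = s1
        si_z[pending, 1] = z1
        if not enforce_het:
            pending = pending[:0]
            break
        bad = (si_s[pending, 0] == si_s[pending, 1]) | (
            si_z[pending, 0] == si_z[pending, 1]
        )
        pending = pending[bad]
        if len(pending) == 0:
            break
    if len(pending):  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("failed to draw SI-heterozygous founders")
    return haplos, si_s, si_z


def _apply_lineage_divergence(
    rng: np.random.Generator,
    gmap: GeneticMap,
    freqs: np.ndarray,
    pool: np.ndarray,
    pool_alleles: np.ndarray,
    k: int,
    locus: tuple[str, float],
    scale_cm: float,
) -> None:
    """Overwrite pool haplotype alleles near an SI locus with the profile of
    the SI-allele lineage they carry (balancing-selection divergence).

    The overwrite probability decays as ``exp(-d / scale_cm)`` with map
    distance ``d`` from the locus, so tagging is strong immediately around
    the locus and fades within a few scale lengths.  Because the allelic
    genealogy at a balanced locus is deep, every variant arising on it
    separates the lineages into two non-trivial groups: each lineage
    profile column is a random non-trivial binary partition of the k
    alleles.  Operates in place.
    """
    chrom, locus_cm = locus
    sl = gmap.chrom_slices()[chrom]
    dist = np.abs(gmap.positions[chrom] - locus_cm)
    retain = np.exp(-dist / scale_cm)
    n_window = sl.stop - sl.start
    # random non-trivial partition of the k lineages per marker
    partitions = rng.integers(1, 2**k - 1, size=n_window)
    profiles = (
        (partitions[None, :] >> np.arange(k)[:, None]) & 1
    ).astype(np.int8)
    use = rng.random((pool.shape[0], sl.stop - sl.start)) < retain
    lineage = profiles[pool_alleles]
    pool[:, sl] = np.where(use, lineage, pool[:, sl])


def _ancestry_mosaic(
    rng: np.random.Generator,
    distances: np.ndarray,
    n_ancestral: int,
    n: int,
    generations: float,
) -> np.ndarray:
    """(n, n_loci) ancestral-haplotype indices along one chromosome."""
    n_loci = len(distances) + 1
    anc = np.empty((n, n_loci), dtype=np.int64)
    anc[:, 0] = rng.integers(n_ancestral, size=n)
    switch_p = 1.0 - np.exp(-generations * distances / 100.0)
    switches = rng.random((n, len(distances))) < switch_p
    fresh = rng.integers(n_ancestral, size=(n, len(distances)))
    for j in range(len(distances)):
        anc[:, j + 1] = np.where(switches[:, j], fresh[:, j], anc[:, j])
    return anc


# ----------------------------------------------------------------------
# SI compatibility and meiosis
# ----------------------------------------------------------------------


def is_compatible(pollen_s, pollen_z, pistil_s_pair, pistil_z_pair) -> bool:
    """Gametophytic SI rule: pollen is rejected (returns False) if and only
    if its S allele matches one of the pistil's S alleles AND its Z allele
    matches one of the pistil's Z alleles."""
    return not (pollen_s in tuple(pistil_s_pair) and
                pollen_z in tuple(pistil_z_pair))


def _compatible_mask(pollen_s, pollen_z, pistil_s_pair, pistil_z_pair):
    """Vectorized compatibility for arrays of pollen grains on one pistil."""
    s_match = (pollen_s == pistil_s_pair[0]) | (pollen_s == pistil_s_pair[1])
    z_match = (pollen_z == pistil_z_pair[0]) | (pollen_z == pistil_z_pair[1])
    return ~(s_match & z_match)


def _chromosome_layout(gmap: GeneticMap, si_model: SIModel) -> list[dict]:
    """Per-chromosome merged locus list of markers plus the S/Z positions.

    Each entry holds the merged cM positions, inter-locus distances, which
    merged loci are markers (and their flat column indices), and the merged
    index of the S / Z locus when it sits on that chromosome.
    """
    slices = gmap.chrom_slices()
    layout = []
    for chrom in gmap.chroms:
        pos = gmap.positions[chrom]
        extras = []
        if si_model.s_locus[0] == chrom:
            extras.append(("S", si_model.s_locus[1]))
        if si_model.z_locus[0] == chrom:
            extras.append(("Z", si_model.z_locus[1]))
        merged = np.concatenate([pos, [cm for _, cm in extras]])
        tags = np.concatenate(
            [np.full(len(pos), "M"), np.array([t for t, _ in extras])]
        ) if extras else np.full(len(pos), "M")
        order = np.argsort(merged, kind="stable")
        merged = merged[order]
        tags = tags[order]
        flat = np.concatenate(
            [np.arange(slices[chrom].start, slices[chrom].stop),
             np.zeros(len(extras), dtype=int)]
        )[order]
        is_marker = tags == "M"
        s_index = int(np.where(tags == "S")[0][0]) if "S" in tags else None
        z_index = int(np.where(tags == "Z")[0][0]) if "Z" in tags else None
        layout.append(
            {
                "chrom": chrom,
                "slice": slices[chrom],
                "merged_cm": merged,
                "distances": np.diff(merged),
                "is_marker": is_marker,
                "merged_to_flat": flat,
                "s_index": s_index,
                "z_index": z_index,
            }
        )
    return layout


def make_gametes(
    founders: FounderSet,
    parent_index: int,
    n: int,
    rng: np.random.Generator,
    layout: list[dict] | None = None,
):
    """Draw ``n`` recombinant gametes from one parent.

    Crossovers follow Haldane's map function: between adjacent loci at map
    distance ``d`` cM a crossover occurs with probability
    ``(1 - exp(-2 d / 100)) / 2``.  Returns ``(haplotypes, s_alleles,
    z_alleles)`` where ``haplotypes`` is ``(n, n_markers)`` and the S/Z
    alleles are the ones carried on the segment containing each locus.
    """
    if layout is None:
        layout = _chromosome_layout(founders.gmap, founders.si_model)
    m = founders.gmap.n_markers
    out = np.empty((n, m), dtype=np.int8)
    s_out = np.empty(n, dtype=np.int64)
    z_out = np.empty(n, dtype=np.int64)
    parent_h = founders.haplotypes[parent_index]
    for chrom in layout:
        d = chrom["distances"]
        rec_p = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        start = rng.integers(2, size=n)
        crossovers = rng.random((n, len(d))) < rec_p
        # haplotype indicator = start XOR (cumulative crossover count mod 2)
        flips = np.cumsum(crossovers, axis=1) % 2
        hap_idx = np.empty((n, len(d) + 1), dtype=np.int8)
        hap_idx[:, 0] = start
        hap_idx[:, 1:] = (start[:, None] + flips) % 2
        alleles = parent_h[hap_idx, chrom["merged_to_flat"][None, :]]
        out[:, chrom["slice"]] = alleles[:, chrom["is_marker"]]
        if chrom["s_index"] is not None:
            s_out[:] = founders.si_s[parent_index, hap_idx[:, chrom["s_index"]]]
        if chrom["z_index"] is not None:
            z_out[:] = founders.si_z[parent_index, hap_idx[:, chrom["z_index"]]]
    return out, s_out, z_out


def make_gamete(founders: FounderSet, parent_index: int,
                rng: np.random.Generator):
    """Single-gamete convenience wrapper around :func:`make_gametes`."""
    hap, s, z = make_gametes(founders, parent_index, 1, rng)
    return hap[0], int(s[0]), int(z[0])


# ----------------------------------------------------------------------
# polycross
# ----------------------------------------------------------------------


def simulate_polycross(
    founders: FounderSet,
    design: MatingDesign,
    enforce_si: bool = True,
    seed: int = 0,
    resample: str = "father_and_gamete",
) -> ProgenySet:
    """Simulate an open polycross with SI-mediated pollen rejection.

    For each mother and each target seed a pollen donor is drawn with
    probability proportional to fecundity (self excluded unless
    ``selfing_rate`` > 0) and one pollen gamete is sampled from it.  Under
    ``enforce_si`` an incompatible grain is discarded and — in the default
    ``father_and_gamete`` mode, which mimics mass-action pollen competition —
    both the donor and the gamete are redrawn; ``gamete_only`` keeps the
    donor and redraws the gamete.  A seed still unpollinated after
    ``max_pollen_attempts`` rounds is skipped and counted.
    """
    if resample not in ("father_and_gamete", "gamete_only"):
        raise ValueError(f"unknown resample mode: {resample}")
    if len(design.fecundity) != founders.n_parents:
        raise ValueError("fecundity length must equal number of parents")
    rng = np.random.default_rng(seed)
    layout = _chromosome_layout(founders.gmap, founders.si_model)
    n_parents = founders.n_parents
    m = founders.gmap.n_markers

    genotype_rows: list[np.ndarray] = []
    records: list[tuple] = []
    skipped = pd.Series(0, index=pd.Index(founders.ids, name="mother"))

    for mi in range(n_parents):
        n_seeds = design.progeny_per_mother
        if n_seeds == 0:
            continue
        pistil_s = founders.si_s[mi]
        pistil_z = founders.si_z[mi]
        weights = design.fecundity.copy()
        self_w = weights[mi]
        weights[mi] = 0.0
        if design.selfing_rate > 0.0:
            # self weight scaled so the marginal selfing probability matches
            weights[mi] = design.selfing_rate * weights.sum() / (
                1.0 - design.selfing_rate
            )
        probs = weights / weights.sum()

        accepted_father = np.full(n_seeds, -1, dtype=int)
        accepted_hap = np.empty((n_seeds, m), dtype=np.int8)
        accepted_s = np.empty(n_seeds, dtype=np.int64)
        accepted_z = np.empty(n_seeds, dtype=np.int64)
        attempts = np.zeros(n_seeds, dtype=int)

        pending = np.arange(n_seeds)
        pending_father = rng.choice(n_parents, size=n_seeds, p=probs)
        for _ in range(design.max_pollen_attempts):
            if len(pending) == 0:
                break
            attempts[pending] += 1
            # draw one pollen gamete per pending seed, grouped by donor
            fathers = pending_father
            hap = np.empty((len(pending), m), dtype=np.int8)
            s_al = np.empty(len(pending), dtype=np.int64)
            z_al = np.empty(len(pending), dtype=np.int64)
            for f in np.unique(fathers):
                sel = fathers == f
                h, s, z = make_gametes(founders, int(f), int(sel.sum()), rng,
                                       layout)
                hap[sel] = h
                s_al[sel] = s
                z_al[sel] = z
            if enforce_si:
                ok = _compatible_mask(s_al, z_al, pistil_s, pistil_z)
            else:
                ok = np.ones(len(pending), dtype=bool)
            good = pending[ok]
            accepted_father[good] = fathers[ok]
            accepted_hap[good] = hap[ok]
            accepted_s[good] = s_al[ok]
            accepted_z[good] = z_al[ok]
            pending = pending[~ok]
            if resample == "father_and_gamete":
                pending_father = rng.choice(n_parents, size=len(pending),
                                            p=probs)
            else:
                pending_father = fathers[~ok]

        if len(pending):
            skipped.iloc[mi] += len(pending)
            warnings.warn(
                f"mother {founders.ids[mi]}: {len(pending)} seed(s) found no "
                f"compatible pollen within {design.max_pollen_attempts} "
                "attempts and were skipped",
                stacklevel=2,
            )
        done = accepted_father >= 0
        n_done = int(done.sum())
        if n_done == 0:
            continue
        egg_hap, egg_s, egg_z = make_gametes(founders, mi, n_done, rng, layout)
        genotype_rows.append(egg_hap + accepted_hap[done])
        for k, seed_idx in enumerate(np.where(done)[0]):
            records.append(
                (
                    founders.ids[mi],
                    founders.ids[accepted_father[seed_idx]],
                    int(accepted_s[seed_idx]),
                    int(accepted_z[seed_idx]),
                    int(egg_s[k]),
                    int(egg_z[k]),
                    int(attempts[seed_idx]),
                )
            )

    n_off = len(records)
    ids = [f"O{i + 1:05d}" for i in range(n_off)]
    pedigree = pd.DataFrame(
        records,
        columns=[
            "mother",
            "father",
            "pollen_s",
            "pollen_z",
            "egg_s",
            "egg_z",
            "attempts",
        ],
        index=pd.Index(ids, name="offspring"),
    )
    genotypes = (
        np.concatenate(genotype_rows, axis=0)
        if genotype_rows
        else np.empty((0, m), dtype=np.int8)
    )
    return ProgenySet(ids=ids, genotypes=genotypes, pedigree=pedigree,
                      skipped=skipped)


# ----------------------------------------------------------------------
# GBS observation layer
# ----------------------------------------------------------------------


def simulate_gbs(
    true_genotypes: np.ndarray,
    individuals: list[str],
    gmap: GeneticMap,
    mean_depth: float = 6.5,
    depth_dispersion: float = 2.0,
    per_read_error: float = 0.005,
    seed: int = 0,
) -> CallMatrix:
    """Overlay a GBS read-depth observation model on true genotypes.

    Total depth per call is negative-binomial with the given mean and shape
    (``depth_dispersion``; smaller = more overdispersed).  Each read reports
    the alternate allele with probability ``g/2`` flipped at the per-read
    error rate.  Zero depth yields a missing call; otherwise a provisional
    call is emitted from the observed allele counts (no depth filtering here
    — quality control applies the depth rules downstream).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    g = np.asarray(true_genotypes)
    n, m = g.shape
    r = depth_dispersion
    p_nb = r / (r + mean_depth)
    depth = rng.negative_binomial(r, p_nb, size=(n, m))
    p_alt = g / 2.0
    p_obs = p_alt * (1.0 - per_read_error) + (1.0 - p_alt) * per_read_error
    alt = rng.binomial(depth, p_obs)
    ref = depth - alt
    calls = np.full((n, m), MISSING, dtype=np.int8)
    calls[(ref > 0) & (alt == 0)] = 0
    calls[(ref > 0) & (alt > 0)] = 1
    calls[(ref == 0) & (alt > 0)] = 2
    depths = np.stack([ref, alt], axis=2).astype(np.int32)
    return CallMatrix(
        individuals=list(individuals),
        markers=gmap.marker_table(),
        genotypes=calls,
        allele_depths=depths,
    )
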