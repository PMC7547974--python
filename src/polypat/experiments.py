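"""End-to-end simulation experiments.

These drive the full chain — founder simulation, SI-constrained polycross,
GBS observation, QC, paternity assignment, progeny matrix, SI encoding and
the mixed-model scan — and report how well the scan localizes the true S
and Z loci.  They are the package's evidence that the in-silico progeny
encoding recovers SI architecture when one exists, and stays quiet when
mating is random.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import association as assoc
from . import qc
from .core import CallMatrix, derive_seed
from .diversity import build_progeny_matrix
from .parentage import ParentageConfig, assign_paternity, estimate_allele_freqs
from .simulate import (
    MatingDesign,
    SIModel,
    simulate_founders,
    simulate_gbs,
    simulate_polycross,
)

__all__ = ["si_recovery_replicate"]


def _stack(parents: CallMatrix, progeny: CallMatrix) -> CallMatrix:
    return CallMatrix(
        individuals=parents.individuals + progeny.individuals,
        markers=parents.markers,
        genotypes=np.vstack([parents.genotypes, progeny.genotypes]),
        allele_depths=np.vstack(
            [parents.allele_depths, progeny.allele_depths]
        ),
    )


def si_recovery_replicate(
    seed: int,
    enforce_si: bool = True,
    n_parents: int = 60,
    n_chromosomes: int = 14,
    markers_per_chromosome: int = 214,
    k_alleles: int = 4,
    progeny_per_mother: int = 33,
    n_ancestral_haplotypes: int = 16,
    parent_depth: float = 20.0,
    progeny_depth: float = 6.5,
    fecundity_sigma: float = 0.6,
) -> dict:
    """Run one simulated polycross and scan for the S and Z loci (model A).

    The founder population descends from a small ancestral haplotype pool,
    so markers near the SI loci are in linkage disequilibrium with the
    segregating S/Z alleles.  Parents are sequenced deep (20x) and het
    calls require two reads of each allele, keeping the imputed parent
    genotypes that feed the encoding clean; the pair-level scan uses
    female/male factor covariates (see :func:`parent_pair_factors`) so
    marker tests measure pure cross-compatibility interactions.  Returns
    the map distance (cM) from the smallest-p marker on each SI chromosome
    to the true locus, the count of genome-wide significant markers at FDR
    0.05 and assignment bookkeeping.
    """
    si_model = SIModel(
        k_s=k_alleles,
        k_z=k_alleles,
        s_locus=("Chr01", 75.0),
        z_locus=("Chr02", 75.0),
    )
    founders = simulate_founders(
        n_parents=n_parents,
        n_chromosomes=n_chromosomes,
        markers_per_chromosome=markers_per_chromosome,
        maf_range=(0.1, 0.5),
        si_model=si_model,
        seed=derive_seed(seed, "founders"),
        n_ancestral_haplotypes=n_ancestral_haplotypes,
    )
    rng = np.random.default_rng(derive_seed(seed, "fecundity"))
    design = MatingDesign(
        fecundity=rng.lognormal(0.0, fecundity_sigma, n_parents),
        progeny_per_mother=progeny_per_mother,
    )
    progeny = simulate_polycross(
        founders, design, enforce_si=enforce_si,
        seed=derive_seed(seed, "polycross"),
    )

    parent_calls = simulate_gbs(
        founders.genotype_dosages(), founders.ids, founders.gmap,
        mean_depth=parent_depth, seed=derive_seed(seed, "gbs_parents"),
    )
    progeny_calls = simulate_gbs(
        progeny.genotypes, progeny.ids, founders.gmap,
        mean_depth=progeny_depth, seed=derive_seed(seed, "gbs_progeny"),
    )

    cfg = qc.FilterConfig(min_het_reads_each=2)
    combined = qc.mask_low_confidence_calls(
        _stack(parent_calls, progeny_calls), cfg
    )
    combined = qc.filter_individuals(combined, cfg)
    combined, stats = qc.filter_markers(combined, cfg)
    parent_rows = [i for i in combined.individuals if i in set(founders.ids)]
    parents_qc = combined.subset(individuals=parent_rows)
    progeny_rows = [i for i in combined.individuals
                    if i not in set(founders.ids)]
    progeny_qc = combined.subset(individuals=progeny_rows)

    # parentage on the reliability panel
    stats = qc.marker_reliability_index(stats)
    panel = qc.select_paternity_panel(stats, cfg)
    freqs = estimate_allele_freqs(parents_qc.subset(markers=panel))
    panel = freqs.index  # drop any all-missing panel markers
    pcfg = ParentageConfig(error_rate=0.01, min_typed_loci=300,
                           n_candidates=n_parents, test_selfing=False)
    mother_map = progeny.pedigree["mother"]
    assignments = assign_paternity(
        progeny_qc.subset(markers=panel),
        mother_map,
        parents_qc.subset(markers=panel),
        freqs,
        pcfg,
    )
    matrix = build_progeny_matrix(assignments, founders.ids)

    scored = assignments[assignments["father"].notna()]
    truth = progeny.pedigree.loc[scored.index, "father"]
    accuracy = float((scored["father"] == truth).mean()) if len(scored) else np.nan

    # model A: in-silico progeny encoding over all ordered pairs
    parents_complete = assoc.impute_parent_genotypes(
        parents_qc, seed=derive_seed(seed, "impute")
    )
    diallel = assoc.build_diallel(parents_complete.genotypes)
    y = assoc.binary_phenotype(matrix)
    K = assoc.genomic_relationship(diallel, coding="pm1")
    scan = assoc.mlm_scan(
        y, diallel, parents_complete.markers, K,
        covariates=assoc.parent_pair_factors(n_parents),
    )
    si_chroms = [si_model.s_locus[0], si_model.z_locus[0]]
    scan = assoc.fdr_control(scan, 0.05, chromosome_subset=si_chroms)

    def best_distance(chrom: str, true_cm: float) -> float:
        sub = scan[scan["chrom"] == chrom]
        best = sub["p"].idxmin()
        return float(abs(sub.loc[best, "cm"] - true_cm))

    return {
        "s_distance_cm": best_distance(*si_model.s_locus),
        "z_distance_cm": best_distance(*si_model.z_locus),
        "n_genome_hits": int(scan["sig_genome"].sum()),
        "n_chrom_hits": int(scan["sig_chrom"].sum()),
        "assignment_accuracy": accuracy,
        "n_assigned": int(len(scored)),
        "n_progeny": progeny.n_offspring,
        "n_markers_scanned": int(len(scan)),
        "scan": scan,
        "progeny_matrix": matrix,
    }
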