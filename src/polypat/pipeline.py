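"""End-to-end pipeline driver: simulate -> filter -> assign -> diallel -> gwas.

The driver consumes a nested configuration dictionary (typically loaded
from YAML), derives one deterministic seed per stage from the global seed,
writes every intermediate artifact in a plain-text standard format and
finishes with a manifest recording inputs, parameters and per-stage row
counts so a run can be reproduced and audited.
"""
from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import io as ppio
from . import qc
from .core import derive_seed
from .diversity import build_progeny_matrix, family_summary
from .experiments import _stack
from .parentage import (
    ParentageConfig,
    assign_paternity,
    delta_critical,
    estimate_allele_freqs,
)
from .simulate import (
    MatingDesign,
    SIModel,
    simulate_founders,
    simulate_gbs,
    simulate_polycross,
)

__all__ = ["run_pipeline", "validate_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_parents": 40,
        "n_chromosomes": 7,
        "markers_per_chromosome": 120,
        "maf_range": [0.1, 0.5],
        "k_s": 4,
        "k_z": 4,
        "s_locus": ["Chr01", 75.0],
        "z_locus": ["Chr02", 75.0],
        "n_ancestral_haplotypes": 16,
        "progeny_per_mother": 30,
        "fecundity_sigma": 0.6,
        "enforce_si": True,
        "parent_depth": 13.0,
        "progeny_depth": 6.5,
    },
    "filter": {},  # FilterConfig field overrides
    "assign": {
        "error_rate": 0.01,
        "min_typed_loci": 300,
        "calibrate": False,
        "n_sim": 5000,
    },
    "gwas": {"model": "A", "n_pcs": 5, "fdr": 0.05},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def validate_config(config: dict) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys
    before any computation starts."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {k: dict(v) if isinstance(v, dict) else v
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if isinstance(value, dict):
            unknown = set(value) - set(DEFAULT_CONFIG[key])
            if key != "filter" and unknown:
                raise ValueError(
                    f"unknown config keys under '{key}': {sorted(unknown)}"
                )
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute the full analysis chain and write artifacts to ``outdir``."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "polypat_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }

    # -- simulate ------------------------------------------------------
    sim = config["simulate"]
    si_model = SIModel(
        k_s=sim["k_s"], k_z=sim["k_z"],
        s_locus=tuple(sim["s_locus"]), z_locus=tuple(sim["z_locus"]),
    )
    founders = simulate_founders(
        n_parents=sim["n_parents"],
        n_chromosomes=sim["n_chromosomes"],
        markers_per_chromosome=sim["markers_per_chromosome"],
        maf_range=tuple(sim["maf_range"]),
        si_model=si_model,
        seed=derive_seed(seed, "founders"),
        n_ancestral_haplotypes=sim["n_ancestral_haplotypes"],
    )
    rng = np.random.default_rng(derive_seed(seed, "fecundity"))
    design = MatingDesign(
        fecundity=rng.lognormal(0.0, sim["fecundity_sigma"],
                                sim["n_parents"]),
        progeny_per_mother=sim["progeny_per_mother"],
    )
    progeny = simulate_polycross(
        founders, design, enforce_si=sim["enforce_si"],
        seed=derive_seed(seed, "polycross"),
    )
    parent_calls = simulate_gbs(
        founders.genotype_dosages(), founders.ids, founders.gmap,
        mean_depth=sim["parent_depth"], seed=derive_seed(seed, "gbs_parents"),
    )
    progeny_calls = simulate_gbs(
        progeny.genotypes, progeny.ids, founders.gmap,
        mean_depth=sim["progeny_depth"],
        seed=derive_seed(seed, "gbs_progeny"),
    )
    ppio.write_vcf(parent_calls, outdir / "parents.vcf")
    ppio.write_vcf(progeny_calls, outdir / "progeny.vcf")
    founders.si_genotype_table().to_csv(outdir / "founder_si_genotypes.csv")
    progeny.pedigree.to_csv(outdir / "true_pedigree.csv")
    manifest["stages"]["simulate"] = {
        "n_parents": founders.n_parents,
        "n_progeny": progeny.n_offspring,
        "n_markers": founders.gmap.n_markers,
        "skipped_seeds": int(progeny.skipped.sum()),
    }

    # -- filter --------------------------------------------------------
    fcfg = qc.FilterConfig(**config["filter"])
    combined = qc.mask_low_confidence_calls(
        _stack(parent_calls, progeny_calls), fcfg
    )
    n_before = combined.n_individuals
    combined = qc.filter_individuals(combined, fcfg)
    combined, stats = qc.filter_markers(combined, fcfg)
    parent_ids = set(founders.ids)
    parents_qc = combined.subset(
        individuals=[i for i in combined.individuals if i in parent_ids]
    )
    progeny_qc = combined.subset(
        individuals=[i for i in combined.individuals if i not in parent_ids]
    )
    ppio.write_vcf(combined, outdir / "filtered.vcf")
    manifest["stages"]["filter"] = {
        "markers_kept": combined.n_markers,
        "individuals_kept": combined.n_individuals,
        "individuals_dropped": n_before - combined.n_individuals,
        "filter_config": asdict(fcfg),
    }

    # -- assign --------------------------------------------------------
    acfg_in = config["assign"]
    stats = qc.marker_reliability_index(stats)
    panel = qc.select_paternity_panel(stats, fcfg)
    freqs = estimate_allele_freqs(parents_qc.subset(markers=panel))
    panel = freqs.index
    pcfg = ParentageConfig(
        error_rate=acfg_in["error_rate"],
        min_typed_loci=acfg_in["min_typed_loci"],
        n_candidates=founders.n_parents,
        n_sim=acfg_in["n_sim"],
        test_selfing=False,
    )
    thresholds = None
    if acfg_in["calibrate"]:
        thresholds = delta_critical(freqs.to_numpy(), pcfg,
                                    seed=derive_seed(seed, "calibrate"))
    assignments = assign_paternity(
        progeny_qc.subset(markers=panel),
        progeny.pedigree["mother"],
        parents_qc.subset(markers=panel),
        freqs,
        pcfg,
        thresholds=thresholds,
    )
    assignments.to_csv(outdir / "assignments.csv")
    manifest["stages"]["assign"] = {
        "panel_size": int(len(panel)),
        "n_scored": int((assignments["status"] == "scored").sum()),
        "n_assigned": int(assignments["father"].notna().sum()),
        "thresholds": thresholds,
    }

    # -- diallel -------------------------------------------------------
    matrix = build_progeny_matrix(assignments, founders.ids)
    matrix.to_csv(outdir / "progeny_matrix.tsv", sep="\t")
    stats_summary = family_summary(matrix)
    (outdir / "family_stats.json").write_text(
        json.dumps(stats_summary.to_dict(), indent=2)
    )
    manifest["stages"]["diallel"] = stats_summary.to_dict()

    # -- gwas ----------------------------------------------------------
    gcfg = config["gwas"]
    parents_complete = assoc.impute_parent_genotypes(
        parents_qc, seed=derive_seed(seed, "impute")
    )
    model = gcfg["model"].upper()
    covariates = None
    if model == "A":
        scores = assoc.build_diallel(parents_complete.genotypes)
        y = assoc.binary_phenotype(matrix)
        K = assoc.genomic_relationship(scores, coding="pm1")
        covariates = assoc.parent_pair_factors(founders.n_parents)
    elif model in ("B", "C", "D"):
        pcs = assoc.progeny_matrix_pcs(matrix, k=3)
        y = pcs.iloc[:, {"B": 0, "C": 1, "D": 2}[model]].to_numpy()
        scores = parents_complete.genotypes.astype(float)
        K = assoc.genomic_relationship(scores, coding="additive")
    else:
        raise ValueError(f"unknown GWAS model: {gcfg['model']}")
    scan = assoc.mlm_scan(y, scores, parents_complete.markers, K,
                          n_pcs=gcfg["n_pcs"], covariates=covariates)
    si_chroms = sorted({si_model.s_locus[0], si_model.z_locus[0]})
    scan = assoc.fdr_control(scan, gcfg["fdr"], chromosome_subset=si_chroms)
    scan.to_csv(outdir / "gwas_scan.csv")
    manifest["stages"]["gwas"] = {
        "model": model,
        "n_markers": int(len(scan)),
        "n_genome_hits": int(scan["sig_genome"].sum()),
        "n_chrom_hits": int(scan["sig_chrom"].sum()),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return outdir
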