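"""Reading and writing call matrices as VCF (GT + AD) and long TSV."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, CallMatrix

__all__ = ["write_vcf", "read_vcf", "write_tsv", "read_tsv", "read_genotypes"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: CallMatrix, path: str | Path) -> None:
    """Write calls as an uncompressed VCF with GT (and AD when depths are
    present) per sample."""
    path = Path(path)
    has_ad = matrix.allele_depths is not None
    fmt = "GT:AD" if has_ad else "GT"
    contigs = list(dict.fromkeys(matrix.markers["chrom"]))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polypat\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        if has_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.individuals) + "\n")
        g = matrix.genotypes
        for j, (marker_id, row) in enumerate(matrix.markers.iterrows()):
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(marker_id),
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".", fmt,
            ]
            if has_ad:
                ad = matrix.allele_depths[:, j]
                samples = [
                    f"{_GT_STRINGS[int(g[i, j])]}:{ad[i, 0]},{ad[i, 1]}"
                    for i in range(matrix.n_individuals)
                ]
            else:
                samples = [_GT_STRINGS[int(g[i, j])]
                           for i in range(matrix.n_individuals)]
            fh.write("\t".join(fields + samples) + "\n")


def read_vcf(path: str | Path) -> CallMatrix:
    """Load a VCF into a CallMatrix.

    Sites with more than one ALT allele are flagged ``multiallelic`` (their
    calls are retained as read but are dropped by marker filtering).  When
    no AD field is present, allele depths are ``None`` and a downstream
    request for depth masking fails loudly.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    genotype_cols = []
    depth_cols = []
    any_ad = False
    for variant in vcf:
        marker_id = variant.ID or f"{variant.CHROM}_{variant.POS}"
        multi = len(variant.ALT) > 1
        rows.append(
            (
                marker_id,
                variant.CHROM,
                variant.POS,
                variant.REF,
                variant.ALT[0] if variant.ALT else ".",
                multi,
            )
        )
        gt = np.asarray(variant.gt_types)
        # cyvcf2 gt_types: 0 hom_ref, 1 het, 2 unknown, 3 hom_alt
        calls = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2],
                          default=MISSING).astype(np.int8)
        genotype_cols.append(calls)
        try:
            ad = variant.format("AD")
        except KeyError:  # AD absent from the header entirely
            ad = None
        if ad is not None:
            any_ad = True
            ad = np.asarray(ad)[:, :2].astype(np.int32)
            ad[ad < 0] = 0
            depth_cols.append(ad)
        else:
            depth_cols.append(
                np.zeros((len(individuals), 2), dtype=np.int32)
            )
    markers = pd.DataFrame(
        rows, columns=["marker", "chrom", "pos", "ref", "alt", "multiallelic"]
    ).set_index("marker")
    genotypes = (
        np.stack(genotype_cols, axis=1)
        if genotype_cols
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    depths = np.stack(depth_cols, axis=1) if any_ad and depth_cols else None
    return CallMatrix(
        individuals=individuals,
        markers=markers,
        genotypes=genotypes,
        allele_depths=depths,
    )


def write_tsv(matrix: CallMatrix, path: str | Path) -> None:
    """Write calls as a long table: individual, marker, chrom, pos, call,
    ref_depth, alt_depth."""
    n, m = matrix.genotypes.shape
    ind = np.repeat(matrix.individuals, m)
    marker = np.tile(matrix.markers.index.to_numpy(), n)
    chrom = np.tile(matrix.markers["chrom"].to_numpy(), n)
    pos = np.tile(matrix.markers["pos"].to_numpy(), n)
    call = matrix.genotypes.ravel()
    df = pd.DataFrame(
        {
            "individual": ind,
            "marker": marker,
            "chrom": chrom,
            "pos": pos,
            "call": call,
        }
    )
    if matrix.allele_depths is not None:
        df["ref_depth"] = matrix.allele_depths[:, :, 0].ravel()
        df["alt_depth"] = matrix.allele_depths[:, :, 1].ravel()
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> CallMatrix:
    """Read the long-table format written by :func:`write_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "marker": str})
    individuals = list(dict.fromkeys(df["individual"]))
    marker_meta = df.drop_duplicates("marker").set_index("marker")
    markers = pd.DataFrame(
        {
            "chrom": marker_meta["chrom"],
            "pos": marker_meta["pos"].astype(int),
            "ref": "A",
            "alt": "T",
        }
    )
    pivot = df.pivot(index="individual", columns="marker", values="call")
    pivot = pivot.loc[individuals, markers.index]
    genotypes = pivot.to_numpy(dtype=np.int8)
    depths = None
    if {"ref_depth", "alt_depth"}.issubset(df.columns):
        ref = (
            df.pivot(index="individual", columns="marker", values="ref_depth")
            .loc[individuals, markers.index]
            .to_numpy(dtype=np.int32)
        )
        alt = (
            df.pivot(index="individual", columns="marker", values="alt_depth")
            .loc[individuals, markers.index]
            .to_numpy(dtype=np.int32)
        )
        depths = np.stack([ref, alt], axis=2)
    return CallMatrix(
        individuals=individuals,
        markers=markers,
        genotypes=genotypes,
        allele_depths=depths,
    )


def read_genotypes(path: str | Path, format: str = "auto") -> CallMatrix:
    """Dispatch to the VCF or TSV reader (``auto`` picks by extension)."""
    path = Path(path)
    if format == "auto":
        format = "VCF" if path.suffix.lower() == ".vcf" else "TSV"
    if format.upper() == "VCF":
        return read_vcf(path)
    if format.upper() == "TSV":
        return read_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")
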