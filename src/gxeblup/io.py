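"""Readers and writers for the pipeline's on-disk formats.

Allele depths travel either as a minimal VCF with per-sample AD tags (read
back through cyvcf2) or as a pair of plain TSV depth matrices; weather as
long-format CSV (site, date, covariate, value); plot phenotypes and stage-2
accession means as CSV; kernels as labeled square CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomics import AlleleDepths
from .kernels import Kernel

__all__ = [
    "write_vcf", "read_vcf",
    "write_depth_tsv", "read_depth_tsv",
    "write_kernel_csv", "read_kernel_csv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=gxeblup
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_vcf(depths: AlleleDepths, path) -> None:
    """Write pooled allele depths as a minimal VCF with AD per sample."""
    mk = depths.markers
    qual = mk["qual"] if "qual" in mk.columns else pd.Series(["."] * len(mk))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(pd.unique(mk["chrom"])):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, depths.accessions)) + "\n")
        for k in range(len(mk)):
            row = mk.iloc[k]
            cells = []
            for i in range(len(depths.accessions)):
                if depths.missing[i, k]:
                    cells.append("./.:.,.")
                else:
                    cells.append(f"0/1:{depths.ref[i, k]},{depths.alt[i, k]}")
            q = qual.iloc[k]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tT\t{q}\t"
                     f"PASS\tNS={len(depths.accessions)}\tGT:AD\t"
                     + "\t".join(cells) + "\n")


def read_vcf(path) -> AlleleDepths:
    """Read per-sample AD fields (and site QUAL) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    refs, alts, miss, meta = [], [], [], []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record {var.ID} lacks AD format field")
        ad = np.asarray(ad)
        m = (ad < 0).any(axis=1)
        ad = np.where(ad < 0, 0, ad)
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
        miss.append(m)
        meta.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                     var.QUAL))
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos", "qual"])
    if markers["qual"].isna().all():
        markers = markers.drop(columns="qual")
    return AlleleDepths(ref=np.column_stack(refs), alt=np.column_stack(alts),
                        accessions=samples, markers=markers,
                        missing=np.column_stack(miss))


def write_depth_tsv(depths: AlleleDepths, ref_path, alt_path) -> None:
    """TSV depth matrices (accessions x markers); missing cells are blank."""
    for mat, path in ((depths.ref, ref_path), (depths.alt, alt_path)):
        df = pd.DataFrame(mat.astype(float), index=depths.accessions,
                          columns=depths.markers["id"])
        df[depths.missing] = np.nan
        df.to_csv(path, sep="\t")


def read_depth_tsv(ref_path, alt_path, markers: pd.DataFrame = None
                   ) -> AlleleDepths:
    ref = pd.read_csv(ref_path, sep="\t", index_col=0)
    alt = pd.read_csv(alt_path, sep="\t", index_col=0)
    if list(ref.columns) != list(alt.columns) or list(ref.index) != list(alt.index):
        raise ValueError("ref/alt depth tables are not aligned")
    miss = ref.isna().to_numpy() | alt.isna().to_numpy()
    if markers is None:
        markers = pd.DataFrame({"id": ref.columns})
    return AlleleDepths(ref=np.nan_to_num(ref.to_numpy()).astype(int),
                        alt=np.nan_to_num(alt.to_numpy()).astype(int),
                        accessions=list(ref.index), markers=markers,
                        missing=miss)


def write_kernel_csv(kernel: Kernel, path) -> None:
    kernel.to_frame().to_csv(path)


def read_kernel_csv(path) -> Kernel:
    return Kernel.from_frame(pd.read_csv(path, index_col=0))
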