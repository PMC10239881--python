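"""Readers and writers: ploidy-aware VCF, TSV tables.

VCF output follows the 4.2 text convention with unphased ploidy-aware GT
fields (``0/0/0/1`` for a tetraploid carrying one alternate copy), an AD
allele-depth FORMAT when read counts are attached, and the per-site
error rate in the ERR INFO field.  Coordinates are 1-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DosageMatrix, ReadCountTable

__all__ = [
    "write_vcf",
    "read_readcounts_vcf",
    "dosage_to_tsv",
    "dosage_from_tsv",
    "write_structure",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ploidypop
##INFO=<ID=ERR,Number=1,Type=Float,Description="Per-site sequencing error rate">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=PP,Number=1,Type=Float,Description="Posterior probability of the called dosage">
"""


def _gt_string(dosage: int, ploidy: int, missing: bool) -> str:
    if missing:
        return "/".join(["."] * ploidy)
    return "/".join(["0"] * (ploidy - dosage) + ["1"] * dosage)


def write_vcf(
    dosages: DosageMatrix,
    path: str,
    reads: ReadCountTable | None = None,
) -> None:
    """Write dosage calls (and optionally read depths) as a text VCF."""
    sites = dosages.sites
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.samples)
            + "\n"
        )
        fmt = "GT:AD:DP:PP" if reads is not None else "GT:PP"
        has_pp = dosages.posterior is not None
        for l in range(dosages.n_sites):
            row = sites.iloc[l]
            qual = row["qual"] if "qual" in sites.columns else "."
            err = reads.error[l] if reads is not None else None
            info = f"ERR={err:.6g}" if err is not None else "."
            cells = []
            for i in range(dosages.n_individuals):
                gt = _gt_string(
                    int(dosages.dosage[i, l]),
                    int(dosages.ploidy[i]),
                    bool(dosages.missing[i, l]),
                )
                pp = f"{dosages.posterior[i, l]:.4f}" if has_pp else "."
                if reads is not None:
                    n, a = int(reads.total[i, l]), int(reads.alt[i, l])
                    cells.append(f"{gt}:{n - a},{a}:{n}:{pp}")
                else:
                    cells.append(f"{gt}:{pp}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t{qual}\tPASS\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_readcounts_vcf(path: str, ploidy: dict[str, int] | np.ndarray) -> ReadCountTable:
    """Read allele depths (AD) and per-site errors (ERR INFO) from a VCF.

    ``ploidy`` maps sample name to 2 or 4 (or is an array in sample order).
    Uses cyvcf2, so plain-text and compressed VCFs both work.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if isinstance(ploidy, dict):
        pl = np.array([ploidy[s] for s in samples], dtype=np.int64)
    else:
        pl = np.asarray(ploidy, dtype=np.int64)
    totals, alts, errs, rows = [], [], [], []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError("VCF lacks the AD FORMAT field")
        ad = np.asarray(ad, dtype=np.int64)
        ref_d, alt_d = ad[:, 0].clip(min=0), ad[:, 1].clip(min=0)
        totals.append(ref_d + alt_d)
        alts.append(alt_d)
        e = var.INFO.get("ERR")
        errs.append(float(e) if e is not None else 1e-3)
        rows.append(
            (var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else ".",
             var.QUAL if var.QUAL is not None else 0.0)
        )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    return ReadCountTable(
        total=np.array(totals).T,
        alt=np.array(alts).T,
        error=np.array(errs),
        ploidy=pl,
        samples=samples,
        sites=sites,
    )


def dosage_to_tsv(dosages: DosageMatrix, path: str) -> None:
    """Sites x individuals dosage table; missing cells are 'NA'."""
    vals = dosages.dosage.astype(object).T.copy()
    vals[dosages.missing.T] = "NA"
    df = pd.DataFrame(vals, columns=dosages.samples)
    out = pd.concat([dosages.sites.reset_index(drop=True), df], axis=1)
    header = "#ploidy\t" + "\t".join(str(int(v)) for v in dosages.ploidy) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False)


def dosage_from_tsv(path: str) -> DosageMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#ploidy"):
            raise ValueError("missing #ploidy header line")
        ploidy = np.array([int(x) for x in first.split("\t")[1:]], dtype=np.int64)
        df = pd.read_csv(fh, sep="\t")
    site_cols = [c for c in ("chrom", "pos", "ref", "alt", "qual") if c in df.columns]
    samples = [c for c in df.columns if c not in site_cols]
    raw = df[samples].to_numpy().T
    missing = pd.DataFrame(raw).isna().to_numpy() | (raw == "NA")
    dosage = np.where(missing, 0, raw).astype(np.int64)
    return DosageMatrix(
        dosage=dosage,
        missing=missing,
        ploidy=ploidy,
        samples=samples,
        sites=df[site_cols],
    )


def write_structure(dosages: DosageMatrix, path: str) -> None:
    """Export genotypes in the one-row-per-allele-copy layout used by
    classic model-based clustering tools.

    Each individual contributes ``ploidy`` rows; alternate copies are
    coded 1, reference copies 0, missing cells -9.  Useful for
    cross-checking the built-in admixture estimator against the original
    tools.
    """
    with open(path, "w") as fh:
        for i, sid in enumerate(dosages.samples):
            v = int(dosages.ploidy[i])
            for copy in range(v):
                row = []
                for l in range(dosages.n_sites):
                    if dosages.missing[i, l]:
                        row.append("-9")
                    else:
                        row.append("1" if copy < dosages.dosage[i, l] else "0")
                fh.write(sid + "\t" + "\t".join(row) + "\n")
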