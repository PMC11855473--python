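"""File interchange: VCF genotypes, tab-separated phenotype/variant tables,
GWAS summary statistics and instrument manifests.

Genotypes travel as VCF v4.2 with hard-call GT fields (one ALT per record);
reading goes through :mod:`cyvcf2`.  Everything tabular is TSV via pandas
with documented headers, so every artifact the pipeline writes is plain text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import RcmrError
from .simulate import Cohort, ScenarioConfig, VariantSpec

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_variant_table",
    "read_variant_table",
    "write_summary_stats",
    "read_summary_stats",
    "write_cohort",
    "read_cohort",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path: str | Path, cohort: Cohort) -> None:
    """Serialize hard-call dosages as VCF v4.2.

    REF is the other allele and ALT the effect allele, so an ALT-dosage
    reading of the file reproduces the effect-allele dosage matrix exactly.
    Missing dosages (NaN) become ``./.``.
    """
    path = Path(path)
    ids = cohort.phenotypes["participant_id"].tolist()
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rcmr-simulator\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        D = np.asarray(cohort.dosages, dtype=float)
        for j, v in enumerate(cohort.variants):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[int(d)] for d in D[:, j]
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a hard-call VCF into (dosages, variant table, sample ids).

    Dosages count ALT (= effect) alleles; unknown genotypes become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    remap = np.array([0.0, 1.0, np.nan, 2.0])
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise RcmrError(f"{rec.ID}: expected exactly one ALT allele")
        rows.append(
            dict(
                variant_id=rec.ID,
                chrom=rec.CHROM,
                pos=rec.POS,
                effect_allele=rec.ALT[0],
                other_allele=rec.REF,
            )
        )
        dosage_cols.append(remap[rec.gt_types])
    vcf.close()
    if not rows:
        raise RcmrError(f"no variant records in {path}")
    return np.column_stack(dosage_cols), pd.DataFrame(rows), samples


def write_phenotypes(path: str | Path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variant_table(path: str | Path, cohort_or_frame) -> None:
    frame = cohort_or_frame.variant_frame() if isinstance(cohort_or_frame, Cohort) else cohort_or_frame
    frame.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_stats(path: str | Path, stats: pd.DataFrame) -> None:
    """GWAS summary statistics TSV (variant_id, chrom, pos, alleles, trait,
    family, n, maf, beta, se, p, hwe_p, f_stat)."""
    stats.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(prefix: str | Path, cohort: Cohort) -> dict[str, Path]:
    """Write <prefix>.vcf, <prefix>.variants.tsv and <prefix>.phenotypes.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "variants": Path(str(prefix) + ".variants.tsv"),
        "phenotypes": Path(str(prefix) + ".phenotypes.tsv"),
    }
    write_vcf(paths["vcf"], cohort)
    write_variant_table(paths["variants"], cohort)
    write_phenotypes(paths["phenotypes"], cohort.phenotypes)
    return paths


def read_cohort(vcf_path: str | Path, phenotypes_path: str | Path) -> Cohort:
    """Reassemble a cohort from a VCF and a phenotype table.

    Participants are aligned on the VCF sample order via ``participant_id``;
    the reconstructed config is a placeholder (the files do not carry
    generative parameters).
    """
    dosages, variants, samples = read_vcf(vcf_path)
    pheno = read_phenotypes(phenotypes_path)
    if "participant_id" not in pheno.columns:
        raise RcmrError("phenotype table must have a participant_id column")
    pheno = pheno.set_index("participant_id").loc[samples].reset_index()
    specs = tuple(
        VariantSpec(
            id=r.variant_id,
            chrom=str(r.chrom),
            pos=int(r.pos),
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            maf=float(min(np.nanmean(dosages[:, j]) / 2.0, 1 - np.nanmean(dosages[:, j]) / 2.0) or 0.5),
        )
        for j, r in enumerate(variants.itertuples())
    )
    config = ScenarioConfig(n=len(pheno), variants=specs, seed=0)
    return Cohort(
        dosages=dosages,
        variants=specs,
        phenotypes=pheno,
        confounder=np.zeros(len(pheno)),
        config=config,
    )
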