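"""Readers and writers for the pipeline's on-disk formats.

Annotation travels as a flat TSV (and optionally GFF3 gene features), sites
as BED6 with the TF name in the name column, variants as minimal VCF 4.2,
counts as a TSV with a sample-metadata sidecar, gene sets as a three-column
TSV. All tabular outputs are TSV with header rows and deterministic row
order.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .models import (
    AlleleCountMatrix,
    validate_annotation,
    validate_sites,
    validate_variants,
)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation_gff3(annotation: pd.DataFrame, path) -> None:
    """Write genes as GFF3 features; the TSS maps to start (+) or end (-)."""
    validate_annotation(annotation)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples():
            # 1-based inclusive; represent the gene as a TSS-anchored span
            if row.strand == "+":
                start, end = row.tss, row.tss + row.exonic_length - 1
            else:
                start, end = max(1, row.tss - row.exonic_length + 1), row.tss
            fh.write(
                f"{row.chrom}\tasescreen\tgene\t{start}\t{end}\t.\t{row.strand}\t.\t"
                f"ID=gene:{row.gene_id};exonic_length={row.exonic_length}\n"
            )


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    """BED6: chrom, start, end, name=tf_name, score=0, strand."""
    validate_sites(sites)
    out = sites.copy()
    if "strand" not in out.columns:
        out["strand"] = "+"
    out["score"] = 0
    out[["chrom", "start", "end", "tf_name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_sites_bed(path) -> pd.DataFrame:
    sites = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "tf_name", "score", "strand"],
    )
    return validate_sites(sites[["chrom", "start", "end", "tf_name", "strand"]])


def write_variants_vcf(variants: pd.DataFrame, path, contigs: list[str] | None = None) -> None:
    """Minimal VCF 4.2 with CHROM POS ID REF ALT QUAL FILTER INFO columns."""
    validate_variants(variants)
    if contigs is None:
        contigs = sorted(variants["chrom"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=asescreen\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


def read_variants_vcf(path) -> pd.DataFrame:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for alt in alts:
                records.append((rec.chrom, rec.pos, rec.ref, alt))
    variants = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt"])
    return validate_variants(variants)


def write_counts(matrix: AlleleCountMatrix, counts_path, samples_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.samples.to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, samples_path) -> AlleleCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return AlleleCountMatrix(counts=counts, samples=samples)


def write_gene_sets(catalog: dict[str, frozenset], path, names: dict[str, str] | None = None) -> None:
    """Three-column TSV: term_id, term_name, gene_id (one row per membership)."""
    rows = [
        (term, (names or {}).get(term, term), gene)
        for term in sorted(catalog)
        for gene in sorted(catalog[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path) -> dict[str, frozenset]:
    table = pd.read_csv(path, sep="\t")
    return {
        term: frozenset(sub["gene_id"]) for term, sub in table.groupby("term_id", sort=True)
    }


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
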