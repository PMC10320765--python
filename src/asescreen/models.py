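"""Shared data containers and schema validation.

Tabular data flows through the package as pandas DataFrames with fixed column
schemas; this module declares those schemas and the light-weight containers
that bundle a count matrix with its sample metadata and a simulation with its
ground truth.

Coordinate conventions
----------------------
* gene annotation: TSS is 1-based (GFF-style)
* binding sites: 0-based half-open intervals (BED-style)
* variants: 1-based positions (VCF-style)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss", "exonic_length"]
SITE_COLUMNS = ["chrom", "start", "end", "tf_name", "strand"]
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "allele", "condition", "replicate", "group"]

ALLELES = ("parentA", "parentB")
CONDITIONS = ("control", "senescent")


class SchemaError(ValueError):
    """An input table violates its declared schema or an invariant."""


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required columns: {missing}")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-annotation table (gene_id, chrom, strand, tss, exonic_length)."""
    _require_columns(annotation, ANNOTATION_COLUMNS, "annotation")
    if annotation["gene_id"].duplicated().any():
        dup = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SchemaError(f"annotation gene_id values must be unique (duplicate: {dup!r})")
    if (annotation["tss"] < 1).any():
        raise SchemaError("annotation tss must be >= 1 (1-based coordinates)")
    if (annotation["exonic_length"] < 1).any():
        raise SchemaError("annotation exonic_length must be >= 1")
    bad = set(annotation["strand"]) - {"+", "-"}
    if bad:
        raise SchemaError(f"annotation strand must be '+' or '-', got {bad}")
    return annotation


def validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Check a binding-site table (BED-style 0-based half-open intervals)."""
    _require_columns(sites, SITE_COLUMNS[:4], "binding sites")
    if (sites["start"] >= sites["end"]).any():
        raise SchemaError("binding sites must satisfy start < end")
    if (sites["start"] < 0).any():
        raise SchemaError("binding-site start must be >= 0")
    return sites


def validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Check a variant catalog: biallelic SNVs, unique (chrom, pos)."""
    _require_columns(variants, VARIANT_COLUMNS, "variants")
    if len(variants):
        if (variants["ref"].str.len() != 1).any() or (variants["alt"].str.len() != 1).any():
            raise SchemaError("variant catalog must contain SNVs only (|ref| = |alt| = 1)")
        if variants.duplicated(["chrom", "pos"]).any():
            raise SchemaError("variant (chrom, pos) pairs must be unique")
        if (variants["pos"] < 1).any():
            raise SchemaError("variant pos must be >= 1 (1-based coordinates)")
    return variants


def site_centers(sites: pd.DataFrame) -> pd.Series:
    """Real-valued interval centers, (start + end) / 2."""
    return (sites["start"] + sites["end"]) / 2.0


@dataclass
class AlleleCountMatrix:
    """Allele-resolved count matrix plus per-sample metadata.

    ``counts`` is genes x samples (integer, non-negative) indexed by gene_id;
    ``samples`` carries one row per column of ``counts`` with allele,
    condition, replicate and group labels.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.samples, SAMPLE_COLUMNS, "sample metadata")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise SchemaError("count-matrix columns must match sample metadata order")
        if self.counts.index.duplicated().any():
            raise SchemaError("count-matrix gene ids must be unique")
        if self.samples.duplicated(["allele", "condition", "replicate", "group"]).any():
            raise SchemaError("(allele, condition, replicate, group) must be unique per sample")
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select(self, **criteria) -> list[str]:
        """Sample ids matching metadata equality criteria, e.g. allele='parentA'."""
        mask = np.ones(len(self.samples), dtype=bool)
        for key, value in criteria.items():
            mask &= (self.samples[key] == value).to_numpy()
        return list(self.samples.loc[mask, "sample_id"])


@dataclass
class SimTruth:
    """Parameters of the planted-effect simulation.

    interaction_lfc is the cis-by-condition effect delta in log2 units planted
    on variant-bearing targets of the causal TFs; planted_fraction is the
    probability such a gene actually receives delta. Dispersion is the
    negative-binomial dispersion (var = mu + dispersion * mu^2); the baseline
    per-gene mean is log-normal with the given natural-log parameters.
    """

    causal_tfs: frozenset = field(default_factory=frozenset)
    interaction_lfc: float = 1.5
    planted_fraction: float = 0.3
    dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.2
    background_effect_sd: float = 0.1
    planted_terms: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        self.causal_tfs = frozenset(self.causal_tfs)
        self.planted_terms = frozenset(self.planted_terms)
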