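"""Synthetic data with planted cis-by-condition structure.

Generates every input the screen consumes — gene annotation, TF binding
sites, an interspecies SNV catalog, allele-resolved counts and gene-set
annotations — with known ground truth, so each downstream stage can be tested
for null calibration and for recovery of planted effects.

The count model is a balanced two-allele x two-condition x R-replicate
design. Per gene g the expected count for (allele, condition) is

    mu_g * 2^(beta_g * [allele B] + gamma_g * [senescent] + delta_g * [B & senescent])

with mu_g log-normal, beta_g and gamma_g small Gaussian nuisance main
effects, and delta_g the planted interaction: nonzero (with probability
``planted_fraction``) exactly for genes that carry a variant in an in-window
binding site of a causal TF. Counts are negative binomial (Gamma-Poisson)
after per-sample scaling to a common library size.

Every generator is deterministic under its seed; each draws from its own RNG
stream keyed by (seed, operation) so stages can be regenerated independently.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (
    ALLELES,
    CONDITIONS,
    AlleleCountMatrix,
    SimTruth,
    validate_annotation,
    validate_sites,
)

# fixed stream keys so adding an op never perturbs the others
_OP_STREAMS = {
    "annotation": 11,
    "sites": 13,
    "variants": 17,
    "counts": 19,
    "gene_sets": 23,
}

_NUCLEOTIDES = np.array(list("ACGT"))


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _OP_STREAMS[op]]))


class PlacementError(ValueError):
    """Requested genes cannot be placed without violating spacing constraints."""


def generate_annotation(
    n_genes: int,
    n_chroms: int,
    chrom_length: int,
    seed: int,
    min_tss: int = 10_001,
    min_spacing: int = 12_000,
) -> pd.DataFrame:
    """Place genes round-robin on chromosomes with non-overlapping TSS.

    TSS positions are 1-based and at least ``min_tss`` (default 10,001) so a
    5-kb upstream window never runs off the chromosome start. Consecutive
    genes on a chromosome are at least ``min_spacing`` apart, which keeps
    their 5-kb upstream windows disjoint. Strands are ~50/50. Exonic lengths
    are log-normal around 1.5 kb.
    """
    if n_genes < 1 or n_chroms < 1:
        raise ValueError("n_genes and n_chroms must be >= 1")
    rng = _rng(seed, "annotation")
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    per_chrom = [len(range(c, n_genes, n_chroms)) for c in range(n_chroms)]
    usable = chrom_length - min_tss - min_spacing
    for c, k in enumerate(per_chrom):
        if k and usable / k < min_spacing:
            raise PlacementError(
                f"chromosome length {chrom_length} cannot hold {k} genes on {chroms[c]} "
                f"with min_spacing={min_spacing} and min_tss={min_tss}"
            )
    # evenly spaced slots with jitter inside each slot
    tss_by_chrom = {}
    for c, k in enumerate(per_chrom):
        if k == 0:
            tss_by_chrom[chroms[c]] = np.array([], dtype=int)
            continue
        slot = usable // k
        jitter = rng.integers(0, max(1, slot - min_spacing + 1), size=k)
        tss_by_chrom[chroms[c]] = min_tss + np.arange(k) * slot + jitter

    records = []
    cursor = {c: 0 for c in chroms}
    for i in range(n_genes):
        chrom = chroms[i % n_chroms]
        tss = int(tss_by_chrom[chrom][cursor[chrom]])
        cursor[chrom] += 1
        records.append((f"g{i + 1:05d}", chrom, tss))
    annotation = pd.DataFrame(records, columns=["gene_id", "chrom", "tss"])
    annotation["strand"] = np.where(rng.random(n_genes) < 0.5, "+", "-")
    annotation["exonic_length"] = np.maximum(
        200, np.round(np.exp(rng.normal(np.log(1500.0), 0.6, size=n_genes)))
    ).astype(int)
    annotation = annotation[["gene_id", "chrom", "strand", "tss", "exonic_length"]]
    return validate_annotation(annotation)


def upstream_window(tss: int, strand: str, window: int) -> tuple[int, int]:
    """0-based half-open upstream window for a 1-based TSS.

    '+' strand: [tss-1-window, tss-1); '-' strand: [tss, tss+window).
    """
    tss0 = tss - 1
    if strand == "+":
        return max(0, tss0 - window), tss0
    return tss0 + 1, tss0 + 1 + window


def generate_binding_sites(
    annotation: pd.DataFrame,
    tf_names: list[str],
    sites_per_tf_per_gene_prob: float,
    site_length: int = 12,
    window: int = 5000,
    decoy_prob: float = 0.1,
    seed: int = 0,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Place TF binding sites inside (and decoys outside) upstream windows.

    For each (TF, gene) pair a site is placed, with the given probability,
    uniformly and fully inside the strand-aware ``window``-bp upstream window
    of the gene; with probability ``decoy_prob`` an additional decoy site is
    placed on the same chromosome outside every gene's window. Sites inherit
    the strand of their gene; decoys get a random strand.
    """
    validate_annotation(annotation)
    if not 0.0 <= sites_per_tf_per_gene_prob <= 1.0:
        raise ValueError("sites_per_tf_per_gene_prob must be in [0, 1]")
    if site_length >= window:
        raise ValueError(f"site_length ({site_length}) must be < window ({window})")
    rng = _rng(seed, "sites")

    windows_by_chrom: dict[str, IntervalTree] = {}
    for row in annotation.itertuples():
        lo, hi = upstream_window(row.tss, row.strand, window)
        if hi > lo:
            windows_by_chrom.setdefault(row.chrom, IntervalTree()).addi(lo, hi)
    if chrom_length is None:
        chrom_length = int(annotation["tss"].max() + window + site_length + 1)

    records = []
    for tf in tf_names:
        for row in annotation.itertuples():
            if rng.random() < sites_per_tf_per_gene_prob:
                lo, hi = upstream_window(row.tss, row.strand, window)
                start = int(rng.integers(lo, hi - site_length + 1))
                records.append((row.chrom, start, start + site_length, tf, row.strand))
            if rng.random() < decoy_prob:
                tree = windows_by_chrom.get(row.chrom, IntervalTree())
                for _ in range(200):  # rejection sampling against all windows
                    start = int(rng.integers(0, chrom_length - site_length))
                    if not tree.overlap(start, start + site_length):
                        strand = "+" if rng.random() < 0.5 else "-"
                        records.append((row.chrom, start, start + site_length, tf, strand))
                        break
    sites = pd.DataFrame(records, columns=["chrom", "start", "end", "tf_name", "strand"])
    sites = sites.sort_values(["chrom", "start", "end", "tf_name"], kind="mergesort")
    sites = sites.reset_index(drop=True)
    return validate_sites(sites)


def generate_variants(
    binding_sites: pd.DataFrame,
    causal_tfs: set[str],
    p_variant_causal: float,
    p_variant_background: float,
    offset_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Drop SNVs into binding sites, enriched in sites of causal TFs.

    Each site of a causal TF receives a variant with probability
    ``p_variant_causal``, every other site with ``p_variant_background``.
    The variant position is ``round(center + Normal(0, offset_sd))`` clipped
    into the site; positions are emitted 1-based (VCF convention) and
    duplicate (chrom, pos) records are collapsed.
    """
    validate_sites(binding_sites)
    for p in (p_variant_causal, p_variant_background):
        if not 0.0 <= p <= 1.0:
            raise ValueError("variant probabilities must be in [0, 1]")
    rng = _rng(seed, "variants")
    causal = binding_sites["tf_name"].isin(set(causal_tfs)).to_numpy()
    p_site = np.where(causal, p_variant_causal, p_variant_background)
    hit = rng.random(len(binding_sites)) < p_site

    center = ((binding_sites["start"] + binding_sites["end"]) / 2.0).to_numpy()
    pos0 = np.round(center + rng.normal(0.0, offset_sd, size=len(binding_sites)))
    pos0 = np.clip(pos0, binding_sites["start"].to_numpy(), binding_sites["end"].to_numpy() - 1)
    ref_idx = rng.integers(0, 4, size=len(binding_sites))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(binding_sites))) % 4

    variants = pd.DataFrame(
        {
            "chrom": binding_sites.loc[hit, "chrom"].to_numpy(),
            "pos": pos0[hit].astype(int) + 1,
            "ref": _NUCLEOTIDES[ref_idx[hit]],
            "alt": _NUCLEOTIDES[alt_idx[hit]],
        }
    )
    variants = variants.drop_duplicates(["chrom", "pos"])
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return variants


def _sample_table(n_replicates: int, group: str = "hybrid") -> pd.DataFrame:
    rows = [
        (f"{allele}_{condition}_r{rep}", allele, condition, rep, group)
        for allele, condition, rep in itertools.product(
            ALLELES, CONDITIONS, range(1, n_replicates + 1)
        )
    ]
    return pd.DataFrame(rows, columns=["sample_id", "allele", "condition", "replicate", "group"])


def generate_counts(
    annotation: pd.DataFrame,
    binding_sites: pd.DataFrame,
    variants: pd.DataFrame,
    truth: SimTruth,
    n_replicates: int = 3,
    library_size: int = 1_000_000,
    window: int = 5000,
) -> tuple[AlleleCountMatrix, pd.DataFrame]:
    """Draw negative-binomial allele counts with the planted interaction.

    Returns the count matrix and a per-gene truth table (mu, beta, gamma,
    delta, planted flag, variant-bearing causal-target flag). Genes eligible
    for planting are exactly the variant-bearing in-window targets of the
    causal TFs, determined with the same window logic the screen uses.
    """
    from .tfscreen import assign_targets, flag_variant_sites

    validate_annotation(annotation)
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (balanced design with replication)")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    rng = _rng(truth.seed, "counts")
    n_genes = len(annotation)
    gene_ids = annotation["gene_id"].to_numpy()

    # which genes are variant-bearing targets of a causal TF
    eligible = np.zeros(n_genes, dtype=bool)
    if len(binding_sites) and truth.causal_tfs:
        targets = assign_targets(binding_sites, annotation, window=window)
        flags, _ = flag_variant_sites(binding_sites, variants)
        variant_sites = set(flags.loc[flags["n_variants"] > 0, "site_id"])
        causal_hits = targets[
            targets["tf_name"].isin(truth.causal_tfs)
            & targets["site_id"].isin(variant_sites)
        ]
        eligible = np.isin(gene_ids, causal_hits["gene_id"].unique())

    planted = eligible & (rng.random(n_genes) < truth.planted_fraction)

    mu = np.exp(rng.normal(truth.baseline_log_mean, truth.baseline_log_sd, size=n_genes))
    beta = rng.normal(0.0, truth.background_effect_sd, size=n_genes)
    gamma = rng.normal(0.0, truth.background_effect_sd, size=n_genes)
    delta = np.where(planted, truth.interaction_lfc, 0.0)

    samples = _sample_table(n_replicates)
    expected = np.empty((n_genes, len(samples)))
    for j, row in enumerate(samples.itertuples()):
        is_b = row.allele == "parentB"
        is_sen = row.condition == "senescent"
        lfc = beta * is_b + gamma * is_sen + delta * (is_b and is_sen)
        expected[:, j] = mu * np.exp2(lfc)
    # per-sample library scaling, so TPM has something to undo
    expected *= library_size / expected.sum(axis=0, keepdims=True)

    shape = 1.0 / truth.dispersion
    lam = rng.gamma(shape, expected / shape)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = AlleleCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=samples["sample_id"].to_numpy()),
        samples=samples,
    )
    truth_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mu": mu,
            "beta": beta,
            "gamma": gamma,
            "delta": delta,
            "planted": planted,
            "causal_variant_target": eligible,
        }
    )
    return matrix, truth_table


def generate_gene_sets(
    annotation: pd.DataFrame,
    n_terms: int,
    size_range: tuple[int, int],
    planted_terms: set[str] | None = None,
    planted_genes: list[str] | None = None,
    planted_bias: float = 0.8,
    seed: int = 0,
) -> dict[str, frozenset]:
    """Sample gene-set terms; planted terms draw preferentially from planted genes.

    Planted terms take ~``planted_bias`` of their members from
    ``planted_genes`` (without replacement, as available) and the rest from
    the remaining genes; other terms sample uniformly without replacement.
    """
    validate_annotation(annotation)
    lo, hi = size_range
    if lo < 2:
        raise ValueError("term sizes must be >= 2")
    genes = annotation["gene_id"].to_numpy()
    if hi > len(genes):
        raise ValueError(f"max term size {hi} exceeds the {len(genes)} available genes")
    rng = _rng(seed, "gene_sets")
    planted_terms = set(planted_terms or ())
    planted_pool = np.array(sorted(set(planted_genes or ()) & set(genes)))
    other_pool = np.array(sorted(set(genes) - set(planted_pool)))

    catalog: dict[str, frozenset] = {}
    for i in range(n_terms):
        term = f"T{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if term in planted_terms and len(planted_pool):
            k = min(int(round(planted_bias * size)), len(planted_pool))
            members = list(rng.choice(planted_pool, size=k, replace=False))
            members += list(rng.choice(other_pool, size=size - k, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        catalog[term] = frozenset(members)
    return catalog
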