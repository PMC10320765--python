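"""The binding-site variant screen.

Maps TF binding sites to the genes whose transcription start site lies
within a 5-kb strand-aware window downstream of them, flags sites carrying
interspecies single-nucleotide variants, and asks, per TF, whether
variant-bearing targets are over-represented among genes with
senescence-dependent differential allele-specific expression — a 2x2
Fisher's exact test with Benjamini-Hochberg correction across the TFs that
survive a minimum-count eligibility filter.

Conventions: sites are BED-style 0-based half-open, variants VCF-style
1-based, TSS 1-based. The upstream window of a '+' gene with 1-based TSS t
is the 0-based interval [t-1-window, t-1); for a '-' gene it is
[t, t+window). A site is in-window if it overlaps the window by >= 1 bp
(full containment available via ``containment=True``).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import site_centers, validate_annotation, validate_sites, validate_variants
from .simulate import upstream_window

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = ["tf_name", "a", "b", "c", "d", "odds_ratio", "p", "q", "eligible"]


def assign_targets(
    binding_sites: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 5000,
    containment: bool = False,
) -> pd.DataFrame:
    """Map each binding site to the genes whose upstream window it hits.

    Returns one row per (site, gene) hit with columns site_id (positional
    index into ``binding_sites``), tf_name, gene_id. A gene can be targeted
    by many TFs and a TF can have many sites per gene. Sites on chromosomes
    absent from the annotation are skipped with a logged warning.
    """
    validate_sites(binding_sites)
    validate_annotation(annotation)
    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples():
        lo, hi = upstream_window(row.tss, row.strand, window)
        if hi > lo:
            trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene_id)

    records = []
    n_skipped = 0
    for site_id, site in enumerate(binding_sites.itertuples()):
        tree = trees.get(site.chrom)
        if tree is None:
            n_skipped += 1
            continue
        if containment:
            hits = [iv for iv in tree.overlap(site.start, site.end)
                    if iv.begin <= site.start and site.end <= iv.end]
        else:
            hits = tree.overlap(site.start, site.end)
        for iv in hits:
            records.append((site_id, site.tf_name, iv.data))
    if n_skipped:
        logger.warning(
            "assign_targets: skipped %d sites on chromosomes absent from the annotation",
            n_skipped,
        )
    targets = pd.DataFrame(records, columns=["site_id", "tf_name", "gene_id"])
    return targets.sort_values(["tf_name", "gene_id", "site_id"], kind="mergesort").reset_index(
        drop=True
    )


def flag_variant_sites(
    binding_sites: pd.DataFrame, variants: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count variants per site and record signed center offsets.

    A 1-based variant at ``pos`` hits a site iff ``start <= pos-1 < end``.
    Its offset is the variant midpoint ``(pos-1) + 0.5`` minus the site
    center ``(start+end)/2``, negated for '-'-strand sites so the sign reads
    5'->3' along the site. Returns (per-site table with site_id and
    n_variants, per-hit table with site_id, pos and offset).
    """
    validate_sites(binding_sites)
    validate_variants(variants)
    trees: dict[str, IntervalTree] = {}
    for site_id, site in enumerate(binding_sites.itertuples()):
        trees.setdefault(site.chrom, IntervalTree()).addi(site.start, site.end, site_id)

    centers = site_centers(binding_sites).to_numpy()
    strands = (
        binding_sites["strand"].to_numpy()
        if "strand" in binding_sites.columns
        else np.full(len(binding_sites), "+")
    )
    hits = []
    for var in variants.itertuples():
        tree = trees.get(var.chrom)
        if tree is None:
            continue
        for iv in tree.at(var.pos - 1):  # point query, half-open by construction
            site_id = iv.data
            offset = (var.pos - 1 + 0.5) - centers[site_id]
            if strands[site_id] == "-":
                offset = -offset
            hits.append((site_id, var.pos, offset))
    hit_table = pd.DataFrame(hits, columns=["site_id", "pos", "offset"])
    n_variants = (
        hit_table.groupby("site_id").size()
        if len(hit_table)
        else pd.Series(dtype=int)
    )
    per_site = pd.DataFrame(
        {
            "site_id": np.arange(len(binding_sites)),
            "n_variants": n_variants.reindex(np.arange(len(binding_sites)), fill_value=0).to_numpy(
                dtype=int
            ),
        }
    )
    return per_site, hit_table.sort_values(["site_id", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def build_target_table(
    targets: pd.DataFrame,
    site_flags: pd.DataFrame,
    hit_table: pd.DataFrame,
    ase_results: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse sites to the (TF, gene) level and join the delta-ASE calls.

    ``has_variant`` is true if any in-window site of the TF for that gene
    carries a variant; ``n_variants`` sums over those sites and
    ``min_center_distance`` is the smallest |offset| (NaN when variant-free).
    Genes without an ASE call (filtered upstream) are dropped.
    """
    merged = targets.merge(site_flags, on="site_id", how="left")
    per_pair = merged.groupby(["tf_name", "gene_id"], as_index=False).agg(
        n_variants=("n_variants", "sum"), n_sites=("site_id", "nunique")
    )
    per_pair["has_variant"] = per_pair["n_variants"] >= 1

    if len(hit_table):
        dist = (
            merged.merge(hit_table[["site_id", "offset"]], on="site_id")
            .assign(abs_offset=lambda d: d["offset"].abs())
            .groupby(["tf_name", "gene_id"], as_index=False)["abs_offset"]
            .min()
            .rename(columns={"abs_offset": "min_center_distance"})
        )
        per_pair = per_pair.merge(dist, on=["tf_name", "gene_id"], how="left")
    else:
        per_pair["min_center_distance"] = np.nan

    calls = ase_results.set_index("gene_id")["delta_ase"]
    per_pair = per_pair[per_pair["gene_id"].isin(calls.index)].copy()
    per_pair["delta_ase"] = calls.reindex(per_pair["gene_id"]).to_numpy()
    return per_pair.reset_index(drop=True)


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    P sums hypergeometric point probabilities no larger than the observed
    table's (the conventional two-sided definition). The odds ratio is the
    sample estimate a*d / (b*c), with inf when only the denominator is zero
    and NaN when both products vanish.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("2x2 cell counts must be non-negative integers")
    if a + b + c + d < 1:
        raise ValueError("the 2x2 table must contain at least one observation")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return odds, float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values across the given family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen(
    target_table: pd.DataFrame,
    min_per_cell: int = 250,
) -> pd.DataFrame:
    """Per-TF 2x2 Fisher screen of variant presence against delta-ASE.

    Cells are a = variant+/dASE+, b = variant+/dASE-, c = variant-/dASE+,
    d = variant-/dASE-. A TF is eligible only if every cell holds at least
    ``min_per_cell`` target genes; Fisher P and BH q are computed over
    eligible TFs only, ineligible TFs are reported with NaN statistics.
    Output is sorted by ascending (q, p, tf_name) with ineligible TFs last.
    """
    rows = []
    for tf, sub in target_table.groupby("tf_name"):
        v, e = sub["has_variant"].to_numpy(bool), sub["delta_ase"].to_numpy(bool)
        a = int(np.sum(v & e))
        b = int(np.sum(v & ~e))
        c = int(np.sum(~v & e))
        d = int(np.sum(~v & ~e))
        rows.append({"tf_name": tf, "a": a, "b": b, "c": c, "d": d,
                     "eligible": min(a, b, c, d) >= min_per_cell})
    result = pd.DataFrame(rows, columns=["tf_name", "a", "b", "c", "d", "eligible"])
    result["odds_ratio"] = np.nan
    result["p"] = np.nan
    result["q"] = np.nan
    eligible = result.index[result["eligible"]]
    if len(eligible) == 0:
        logger.warning("screen: no TF passed the %d-per-cell eligibility filter", min_per_cell)
    else:
        stats_ = [
            fisher_exact(*result.loc[i, ["a", "b", "c", "d"]].astype(int)) for i in eligible
        ]
        result.loc[eligible, "odds_ratio"] = [s[0] for s in stats_]
        result.loc[eligible, "p"] = [s[1] for s in stats_]
        result.loc[eligible, "q"] = bh_adjust(result.loc[eligible, "p"])
    result = result.sort_values(
        ["q", "p", "tf_name"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return result[SCREEN_COLUMNS]


def _gaussian_kde_table(values: np.ndarray, bandwidth: float, grid: np.ndarray) -> pd.DataFrame:
    # plain Gaussian mixture at an absolute bandwidth; well-defined even for
    # zero-variance data, unlike covariance-based KDE implementations
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (len(values) * bandwidth * np.sqrt(2 * np.pi))
    return pd.DataFrame({"x": grid, "density": density})


def variant_position_profile(
    target_table: pd.DataFrame,
    hit_table: pd.DataFrame,
    targets: pd.DataFrame,
    tf_name: str,
    bandwidth: float = 2.0,
    grid_points: int = 512,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Kernel-density summaries of variant load and variant position for one TF.

    Two families of curves, each stratified by the delta-ASE status of the
    downstream gene: ``counts`` — density over the per-target-gene variant
    count; ``offsets`` — density over signed variant offsets from the site
    center. Gaussian kernel with the given absolute bandwidth, evaluated on
    a common grid spanning the pooled data +- 4 bandwidths. Strata with
    fewer than two observations are omitted with a warning.
    """
    sub = target_table[target_table["tf_name"] == tf_name]
    tf_sites = targets[targets["tf_name"] == tf_name]
    site_ase = tf_sites.merge(
        sub[["gene_id", "delta_ase"]], on="gene_id", how="inner"
    )
    offsets = hit_table.merge(site_ase[["site_id", "delta_ase"]], on="site_id")

    out: dict[str, dict[str, pd.DataFrame]] = {"counts": {}, "offsets": {}}
    for family, frame, column in (
        ("counts", sub, "n_variants"),
        ("offsets", offsets, "offset"),
    ):
        if not len(frame):
            logger.warning("variant_position_profile: no %s data for %s", family, tf_name)
            continue
        pooled = frame[column].to_numpy(float)
        lo, hi = pooled.min() - 4 * bandwidth, pooled.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, grid_points)
        for flag, label in ((True, "delta_ase"), (False, "no_delta_ase")):
            values = frame.loc[frame["delta_ase"] == flag, column].to_numpy(float)
            if len(values) < 2:
                logger.warning(
                    "variant_position_profile: stratum %s/%s for %s has <2 points; omitted",
                    family, label, tf_name,
                )
                continue
            out[family][label] = _gaussian_kde_table(values, bandwidth, grid)
    return out
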