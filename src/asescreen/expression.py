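"""TPM normalization, expression filtering and log-ratio profiles.

TPM is the standard length-then-depth normalization: per sample,
``TPM_g = 1e6 * (count_g / exonic_length_g) / sum_g'(count_g' / length_g')``,
so every column sums to one million. The expression filter retains genes
with nonzero counts in strictly more than half the samples. Group log-ratio
profiles (log2 of the ratio of group-mean TPM, with a pseudocount guarding
zeros) feed the gene-set enrichment and the cis/trans comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import AlleleCountMatrix, validate_annotation


def counts_to_tpm(counts: AlleleCountMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Convert an allele count matrix to transcripts per million.

    Raises if a sample column is all zero (TPM undefined) or a gene lacks an
    annotation entry.
    """
    validate_annotation(annotation)
    lengths = annotation.set_index("gene_id")["exonic_length"].reindex(counts.counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"gene {missing!r} has no annotation entry (exonic_length needed)")
    rate = counts.counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has an all-zero count column; TPM is undefined")
    return rate.div(totals, axis=1) * 1e6


def filter_expressed(counts: AlleleCountMatrix) -> pd.Index:
    """Genes with nonzero counts in strictly more than half the samples."""
    if counts.n_samples < 1:
        raise ValueError("need at least one sample")
    nonzero = (counts.counts > 0).sum(axis=1)
    return counts.counts.index[nonzero > counts.n_samples / 2]


def group_log_ratio(
    tpm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2 ratio of group-mean TPM, ``log2((mean_a + pc) / (mean_b + pc))``.

    Groups are sample-column selections; they must be non-empty and disjoint.
    """
    if not group_a or not group_b:
        raise ValueError("both sample groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("sample groups must be disjoint")
    mean_a = tpm[list(group_a)].mean(axis=1)
    mean_b = tpm[list(group_b)].mean(axis=1)
    r = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    r.name = "log2_ratio"
    return r


def hybrid_total_expression(tpm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Collapse allele-resolved hybrid TPM to total expression per (condition, replicate).

    Each (condition, replicate) must carry exactly the two parental alleles;
    the collapsed column is their sum, labelled ``{condition}_r{replicate}``.
    """
    meta = samples.set_index("sample_id").loc[list(tpm.columns)]
    out = {}
    for (condition, replicate), sub in meta.groupby(["condition", "replicate"], sort=True):
        alleles = sorted(sub["allele"])
        if alleles != ["parentA", "parentB"]:
            raise ValueError(
                f"(condition={condition!r}, replicate={replicate}) has alleles {alleles}; "
                "expected exactly parentA and parentB"
            )
        out[f"{condition}_r{replicate}"] = tpm[sub.index].sum(axis=1)
    return pd.DataFrame(out, index=tpm.index)


def timecourse_anova(tpm: pd.DataFrame, timepoints: list[str]) -> pd.DataFrame:
    """Per-gene one-way ANOVA across timepoints on log2(TPM + 1).

    ``timepoints`` labels the columns of ``tpm`` in order (e.g. 0h/6h/10d/20d
    with replicates). Genes with zero total variance get F = 0, p = 1 and a
    degenerate flag. Requires >= 2 timepoint groups with >= 2 replicates each.
    """
    labels = pd.Series(timepoints)
    if len(labels) != tpm.shape[1]:
        raise ValueError("one timepoint label per sample column is required")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 timepoint groups")
    if (labels.value_counts() < 2).any():
        raise ValueError("need >= 2 replicates per timepoint")
    log = np.log2(tpm.to_numpy(float) + 1.0)
    arrays = [log[:, (labels == g).to_numpy()] for g in groups]
    degenerate = np.ptp(log, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays, axis=1)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"gene_id": tpm.index, "F": f, "p": p, "degenerate": degenerate}
    ).reset_index(drop=True)


def ecdf_table(profile: pd.Series, gene_subset) -> pd.DataFrame:
    """Right-continuous empirical CDF of profile values over a gene subset."""
    subset = profile.index.intersection(pd.Index(gene_subset))
    if len(subset) == 0:
        raise ValueError("gene subset has no overlap with the profile")
    values = np.sort(profile.loc[subset].to_numpy(float))
    x, counts = np.unique(values, return_counts=True)
    return pd.DataFrame({"x": x, "proportion": np.cumsum(counts) / len(values)})
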