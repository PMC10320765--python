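"""Senescence-dependent differential allele-specific expression (delta-ASE).

In an F1 hybrid both alleles share one trans-acting environment, so an
allele-by-condition interaction in expression isolates condition-dependent
cis-regulatory divergence. Each gene's allele-resolved TPM values in the
balanced two-allele x two-condition design go into an ordinary two-way
fixed-effects ANOVA; the interaction F statistic ranks genes and the top
quartile is called delta-ASE.

The ANOVA is computed vectorized across genes from the balanced-design
sums-of-squares decomposition (cell means vs additive expectations), which
for a 2x2 design with R replicates gives the interaction term 1 and 4(R-1)
degrees of freedom.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .models import ALLELES, CONDITIONS


def _balanced_cube(
    tpm: pd.DataFrame, samples: pd.DataFrame
) -> np.ndarray:
    """Stack TPM into a genes x 2(allele) x 2(condition) x R array; errors if unbalanced."""
    meta = samples.set_index("sample_id").loc[list(tpm.columns)]
    reps = sorted(meta["replicate"].unique())
    n_rep = len(reps)
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per design cell")
    cube = np.empty((tpm.shape[0], 2, 2, n_rep))
    for i, allele in enumerate(ALLELES):
        for j, condition in enumerate(CONDITIONS):
            for k, rep in enumerate(reps):
                sel = meta.index[
                    (meta["allele"] == allele)
                    & (meta["condition"] == condition)
                    & (meta["replicate"] == rep)
                ]
                if len(sel) != 1:
                    raise ValueError(
                        f"design is not balanced: cell ({allele}, {condition}, rep {rep}) "
                        f"has {len(sel)} samples, expected 1"
                    )
                cube[:, i, j, k] = tpm[sel[0]].to_numpy(float)
    return cube


def _interaction_f(cube: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 2x2-with-replicates interaction F over the leading axis."""
    n_rep = cube.shape[3]
    cell = cube.mean(axis=3)                      # genes x 2 x 2
    allele = cell.mean(axis=2, keepdims=True)     # allele margins
    cond = cell.mean(axis=1, keepdims=True)
    grand = cell.mean(axis=(1, 2), keepdims=True)
    ss_int = n_rep * ((cell - allele - cond + grand) ** 2).sum(axis=(1, 2))
    ss_res = ((cube - cell[..., None]) ** 2).sum(axis=(1, 2, 3))
    df_res = 4 * (n_rep - 1)
    degenerate = ss_res <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_int / (ss_res / df_res)
    p = stats.f.sf(f, 1, df_res)
    return f, p, degenerate


def interaction_anova(values: dict[tuple[str, str, int], float]) -> tuple[float, float, bool]:
    """Two-way interaction ANOVA for a single gene.

    ``values`` maps (allele, condition, replicate) to the analysis-scale
    expression value; the design must be a balanced 2x2 with >= 2 replicates
    per cell. Returns (F, p, degenerate); F and p are NaN when the residual
    variance is zero (degenerate).
    """
    reps = sorted({k[2] for k in values})
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates per design cell")
    cube = np.empty((1, 2, 2, len(reps)))
    for i, allele in enumerate(ALLELES):
        for j, condition in enumerate(CONDITIONS):
            for k, rep in enumerate(reps):
                key = (allele, condition, rep)
                if key not in values:
                    raise ValueError(f"design is not balanced: missing cell {key}")
                cube[0, i, j, k] = values[key]
    f, p, degenerate = _interaction_f(cube)
    if degenerate[0]:
        return math.nan, math.nan, True
    return float(f[0]), float(p[0]), False


def ase_test(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    scale: str = "tpm",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Interaction ANOVA for every gene of an allele-resolved TPM matrix.

    ``scale`` selects the analysis scale: raw ``"tpm"`` (default) or
    ``"log2"`` for log2(TPM + pseudocount). Returns a per-gene table with
    F, p and a degenerate flag (zero residual variance; F and p are NaN).
    """
    if scale not in ("tpm", "log2"):
        raise ValueError("scale must be 'tpm' or 'log2'")
    cube = _balanced_cube(tpm, samples)
    if scale == "log2":
        cube = np.log2(cube + pseudocount)
    f, p, degenerate = _interaction_f(cube)
    f = np.where(degenerate, np.nan, f)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {"gene_id": tpm.index, "F": f, "p": p, "degenerate": degenerate}
    ).reset_index(drop=True)


def classify_delta_ase(results: pd.DataFrame, quantile: float = 0.75) -> pd.DataFrame:
    """Flag the top (1 - quantile) fraction of tested genes by interaction F.

    Degenerate genes are excluded from the "tested" denominator and never
    flagged. Exactly ``ceil((1 - quantile) * n_tested)`` genes are flagged;
    ties at the threshold break by ascending gene_id for determinism.
    """
    out = results.copy()
    tested = out.loc[~out["degenerate"]]
    if len(tested) < 4:
        raise ValueError("need >= 4 non-degenerate tested genes to take a quantile")
    k = math.ceil((1.0 - quantile) * len(tested))
    ranked = tested.sort_values(["F", "gene_id"], ascending=[False, True], kind="mergesort")
    flagged = set(ranked["gene_id"].iloc[:k])
    out["delta_ase"] = out["gene_id"].isin(flagged) & ~out["degenerate"]
    return out


def cis_trans_concordance(
    hybrid: pd.Series, purebred: pd.Series
) -> tuple[float, float, int]:
    """Spearman correlation between hybrid allelic and purebred species responses.

    Both arguments are per-gene log2-ratio profiles; the statistic is taken
    over the gene intersection (>= 10 genes required). A positive rho means
    the hybrid's cis signal partially predicts purebred expression
    divergence.
    """
    shared = hybrid.index.intersection(purebred.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; >= 10 required")
    rho, p = stats.spearmanr(hybrid.loc[shared], purebred.loc[shared])
    return float(rho), float(p), len(shared)
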