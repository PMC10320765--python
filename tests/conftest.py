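import numpy as np
import pandas as pd
import pytest

import asescreen as asc
from asescreen.models import SimTruth


def run_end_to_end(
    seed: int,
    n_genes: int = 2000,
    n_tfs: int = 20,
    causal_tfs: frozenset = frozenset({"TF01"}),
    p_variant_causal: float = 0.6,
    p_variant_background: float = 0.2,
    interaction_lfc: float = 1.5,
    planted_fraction: float = 0.3,
    site_prob: float = 0.7,
    n_replicates: int = 3,
    min_per_cell: int = 50,
    chrom_length: int = 25_000_000,
):
    """Simulate one dataset and run it through TPM -> delta-ASE -> screen."""
    ann = asc.generate_annotation(n_genes, 5, chrom_length, seed=seed)
    tf_names = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    sites = asc.generate_binding_sites(
        ann, tf_names, site_prob, seed=seed, chrom_length=chrom_length
    )
    variants = asc.generate_variants(
        sites, set(causal_tfs), p_variant_causal, p_variant_background, seed=seed
    )
    truth = SimTruth(
        causal_tfs=causal_tfs,
        interaction_lfc=interaction_lfc,
        planted_fraction=planted_fraction,
        seed=seed,
    )
    matrix, truth_table = asc.generate_counts(
        ann, sites, variants, truth, n_replicates=n_replicates
    )
    tpm = asc.counts_to_tpm(matrix, ann)
    tpm = tpm.loc[asc.filter_expressed(matrix)]
    ase_results = asc.classify_delta_ase(asc.ase_test(tpm, matrix.samples))
    targets = asc.assign_targets(sites, ann)
    site_flags, hit_table = asc.flag_variant_sites(sites, variants)
    table = asc.build_target_table(targets, site_flags, hit_table, ase_results)
    screen_result = asc.screen(table, min_per_cell=min_per_cell)
    return {
        "annotation": ann,
        "sites": sites,
        "variants": variants,
        "matrix": matrix,
        "truth_table": truth_table,
        "tpm": tpm,
        "ase": ase_results,
        "targets": targets,
        "site_flags": site_flags,
        "hit_table": hit_table,
        "target_table": table,
        "screen": screen_result,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene, 4-TF dataset with one causal TF, shared across tests."""
    ann = asc.generate_annotation(300, 3, 10_000_000, seed=11)
    tfs = ["TF_A", "TF_B", "TF_C", "TF_D"]
    sites = asc.generate_binding_sites(ann, tfs, 0.8, seed=11, chrom_length=10_000_000)
    variants = asc.generate_variants(sites, {"TF_A"}, 0.7, 0.2, seed=11)
    truth = SimTruth(causal_tfs={"TF_A"}, interaction_lfc=1.5, planted_fraction=0.5, seed=11)
    matrix, truth_table = asc.generate_counts(ann, sites, variants, truth, n_replicates=3)
    return {
        "annotation": ann,
        "tfs": tfs,
        "sites": sites,
        "variants": variants,
        "truth": truth,
        "matrix": matrix,
        "truth_table": truth_table,
    }


def balanced_values(rng: np.random.Generator, n_rep: int = 3) -> dict:
    """Random balanced 2x2xR cell values keyed by (allele, condition, replicate)."""
    return {
        (allele, condition, rep): float(rng.normal(10, 2))
        for allele in ("parentA", "parentB")
        for condition in ("control", "senescent")
        for rep in range(1, n_rep + 1)
    }
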