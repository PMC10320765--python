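"""Null calibration of the allele-by-condition interaction test.

Simulates a dataset with no planted interaction (delta = 0 everywhere) and
checks that the per-gene interaction p-values are uniform.
"""

import numpy as np
from scipy import stats

import asescreen as asc
from asescreen.models import SimTruth

CHROM_LENGTH = 25_000_000

annotation = asc.generate_annotation(2000, 5, CHROM_LENGTH, seed=3)
sites = asc.generate_binding_sites(annotation, ["TF01"], 0.7, seed=3,
                                   chrom_length=CHROM_LENGTH)
variants = asc.generate_variants(sites, set(), 0.0, 0.2, seed=3)
truth = SimTruth(interaction_lfc=0.0, seed=3)
matrix, _ = asc.generate_counts(annotation, sites, variants, truth, n_replicates=3)

tpm = asc.counts_to_tpm(matrix, annotation)
tpm = tpm.loc[asc.filter_expressed(matrix)]
results = asc.ase_test(tpm, matrix.samples)
p = results.loc[~results["degenerate"], "p"].to_numpy()

ks = stats.kstest(p, "uniform")
print(f"genes tested: {len(p)}")
print(f"fraction p < 0.05: {np.mean(p < 0.05):.4f} (expect ~0.05)")
print(f"KS distance from U(0,1): {ks.statistic:.4f} (expect < 0.05)")
print("\nWith no cis-by-condition effects the interaction F test should be "
      "well calibrated; a uniform p distribution means the downstream "
      "top-quartile delta-ASE call selects pure noise at the expected rate.")
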