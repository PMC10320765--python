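"""Target assignment, variant flagging, Fisher/BH oracles and the screen itself."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import asescreen as asc
from conftest import run_end_to_end


def _annotation(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "exonic_length"])


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf_name", "strand"])


class TestAssignTargets:
    ann = _annotation([("gA", "chr1", "+", 10_000, 1000), ("gB", "chr1", "-", 10_000, 1000)])

    @pytest.mark.parametrize(
        "start,end,strand_gene,is_target",
        [
            (6000, 6200, "+", True),    # inside 1-based [5000, 9999]
            (3000, 4000, "+", False),   # upstream of the window
            (12_000, 12_100, "-", True),  # '-' strand window is downstream in coords
            (8000, 8100, "-", False),
        ],
    )
    def test_strand_aware_window_membership(self, start, end, strand_gene, is_target):
        ann = self.ann[self.ann["strand"] == strand_gene]
        sites = _sites([("chr1", start, end, "TF1", "+")])
        targets = asc.assign_targets(sites, ann)
        assert (len(targets) == 1) == is_target

    def test_partial_overlap_counts_but_containment_mode_excludes(self):
        ann = self.ann[self.ann["strand"] == "+"]
        sites = _sites([("chr1", 4000, 5100, "TF1", "+")])  # straddles the window edge
        assert len(asc.assign_targets(sites, ann)) == 1
        assert len(asc.assign_targets(sites, ann, containment=True)) == 0

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        sites = _sites([("chrUn", 100, 200, "TF1", "+"), ("chr1", 6000, 6100, "TF1", "+")])
        with caplog.at_level("WARNING"):
            targets = asc.assign_targets(sites, self.ann)
        assert len(targets) == 1
        assert "skipped 1 sites" in caplog.text

    def test_many_to_many_mapping(self):
        ann = _annotation(
            [("gA", "chr1", "+", 10_000, 1000), ("gB", "chr1", "+", 11_000, 1000)]
        )
        sites = _sites(
            [("chr1", 8000, 8100, "TF1", "+"), ("chr1", 8200, 8300, "TF2", "+")]
        )
        targets = asc.assign_targets(sites, ann)
        # both sites fall in both (overlapping) windows
        assert len(targets) == 4
        assert set(targets["tf_name"]) == {"TF1", "TF2"}
        assert set(targets["gene_id"]) == {"gA", "gB"}


class TestFlagVariantSites:
    sites = _sites([("chr1", 100, 120, "TF1", "+")])

    def test_offset_convention_at_site_interior(self):
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [110], "ref": ["A"], "alt": ["C"]})
        flags, hits = asc.flag_variant_sites(self.sites, variants)
        assert flags.loc[0, "n_variants"] == 1
        assert hits.loc[0, "offset"] == pytest.approx(-0.5)  # (109 + 0.5) - 110.0

    @pytest.mark.parametrize("pos,counted", [(101, True), (120, True), (121, False), (100, False)])
    def test_half_open_boundaries(self, pos, counted):
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [pos], "ref": ["A"], "alt": ["C"]})
        flags, _ = asc.flag_variant_sites(self.sites, variants)
        assert (flags.loc[0, "n_variants"] == 1) == counted

    def test_multiple_variants_counted(self):
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [105, 110, 115], "ref": ["A"] * 3, "alt": ["C"] * 3}
        )
        flags, hits = asc.flag_variant_sites(self.sites, variants)
        assert flags.loc[0, "n_variants"] == 3
        assert len(hits) == 3

    def test_minus_strand_site_flips_offset_sign(self):
        minus = _sites([("chr1", 100, 120, "TF1", "-")])
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [105], "ref": ["A"], "alt": ["C"]})
        _, hits_plus = asc.flag_variant_sites(self.sites, variants)
        _, hits_minus = asc.flag_variant_sites(minus, variants)
        assert hits_minus.loc[0, "offset"] == pytest.approx(-hits_plus.loc[0, "offset"])


class TestBuildTargetTable:
    def test_any_site_aggregation_and_ase_join(self):
        targets = pd.DataFrame(
            {"site_id": [0, 1, 2], "tf_name": ["TF1"] * 3, "gene_id": ["gA", "gA", "gB"]}
        )
        flags = pd.DataFrame({"site_id": [0, 1, 2], "n_variants": [2, 0, 0]})
        hits = pd.DataFrame({"site_id": [0, 0], "pos": [110, 111], "offset": [-0.5, 0.5]})
        ase_results = pd.DataFrame(
            {"gene_id": ["gA", "gB", "gC"], "delta_ase": [True, False, True]}
        )
        table = asc.build_target_table(targets, flags, hits, ase_results)
        ga = table.set_index("gene_id").loc["gA"]
        assert bool(ga["has_variant"]) and ga["n_variants"] == 2
        assert ga["min_center_distance"] == pytest.approx(0.5)
        gb = table.set_index("gene_id").loc["gB"]
        assert not gb["has_variant"] and math.isnan(gb["min_center_distance"])
        assert "gC" not in set(table["gene_id"])  # no supporting site


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided P by exhaustive summation over tables with fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-14)].sum())


def bh_stepup_oracle(pvalues):
    """q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, by the definition."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFisherExact:
    def test_balanced_table_is_null(self):
        odds, p = asc.fisher_exact(5, 5, 5, 5)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 500:
            t = rng.integers(0, 16, size=4)
            if t.sum() == 0 or t.sum() > 60:
                continue
            a, b, c, d = map(int, t)
            _, p = asc.fisher_exact(a, b, c, d)
            assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-12)
            checked += 1

    def test_perfect_association_gives_infinite_odds(self):
        odds, p = asc.fisher_exact(10, 0, 0, 10)
        assert math.isinf(odds)
        assert p == pytest.approx(fisher_enumeration_oracle(10, 0, 0, 10), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            asc.fisher_exact(-1, 2, 3, 4)


class TestBHAdjust:
    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(asc.bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_textbook_monotone_case(self):
        q = asc.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


class TestScreen:
    @staticmethod
    def _table(cells_by_tf):
        rows = []
        for tf, (a, b, c, d) in cells_by_tf.items():
            for has_var, flag, n in ((True, True, a), (True, False, b),
                                     (False, True, c), (False, False, d)):
                for i in range(n):
                    rows.append((tf, f"{tf}_{has_var}_{flag}_{i}", has_var, flag))
        return pd.DataFrame(rows, columns=["tf_name", "gene_id", "has_variant", "delta_ase"])

    def test_eligibility_boundary_at_250(self):
        result = asc.screen(
            self._table({"ok": (250, 250, 250, 250), "short": (300, 300, 300, 249)})
        )
        by_tf = result.set_index("tf_name")
        assert bool(by_tf.loc["ok", "eligible"])
        assert not bool(by_tf.loc["short", "eligible"])
        assert math.isnan(by_tf.loc["short", "p"])

    def test_single_eligible_tf_has_q_equal_p(self):
        result = asc.screen(self._table({"solo": (10, 5, 5, 10)}), min_per_cell=5)
        row = result.iloc[0]
        assert row["q"] == pytest.approx(row["p"])

    def test_bh_family_is_eligible_tfs_only(self):
        cells = {"t1": (20, 5, 5, 20), "t2": (10, 10, 10, 10), "t3": (5, 20, 20, 5),
                 "skip": (1, 50, 50, 50)}
        result = asc.screen(self._table(cells), min_per_cell=5)
        eligible = result[result["eligible"]]
        assert len(eligible) == 3
        assert np.allclose(eligible["q"], bh_stepup_oracle(eligible["p"]))

    def test_no_tf_lost_or_duplicated(self):
        cells = {f"tf{i}": (i + 1, 2 * i + 1, 5, 7) for i in range(10)}
        result = asc.screen(self._table(cells), min_per_cell=3)
        assert sorted(result["tf_name"]) == sorted(cells)

    def test_zero_eligible_warns_and_returns_all_nan(self, caplog):
        with caplog.at_level("WARNING"):
            result = asc.screen(self._table({"t1": (1, 1, 1, 1)}), min_per_cell=99)
        assert not result["eligible"].any()
        assert "no TF passed" in caplog.text


class TestVariantPositionProfile:
    @staticmethod
    def _kde(values, bandwidth, grid):
        from asescreen.tfscreen import _gaussian_kde_table

        return _gaussian_kde_table(np.asarray(values, float), bandwidth, grid)

    def test_symmetric_data_gives_symmetric_density(self):
        grid = np.linspace(-20, 20, 401)
        table = self._kde([-10, 0, 10], 2.0, grid)
        dens = table["density"].to_numpy()
        assert np.max(np.abs(dens - dens[::-1])) < 1e-9

    def test_repeated_value_modes_at_that_value(self):
        grid = np.linspace(4, 6, 201)
        table = self._kde([5.0, 5.0, 5.0], 0.1, grid)
        assert table.loc[table["density"].idxmax(), "x"] == pytest.approx(5.0, abs=0.02)

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 5, 200)
        grid = np.linspace(values.min() - 10, values.max() + 10, 600)
        table = self._kde(values, 2.0, grid)
        area = np.trapezoid(table["density"], table["x"])
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_shifted_stratum_has_larger_mode(self):
        """Offsets centered at +15 for delta-ASE genes vs 0 for the rest:
        the delta-ASE stratum's density peaks to the right."""
        rng = np.random.default_rng(1)
        n = 60
        target_table = pd.DataFrame(
            {
                "tf_name": "TF1",
                "gene_id": [f"g{i}" for i in range(n)],
                "n_variants": 1,
                "has_variant": True,
                "delta_ase": [i < n // 2 for i in range(n)],
            }
        )
        targets = pd.DataFrame(
            {"site_id": range(n), "tf_name": "TF1", "gene_id": [f"g{i}" for i in range(n)]}
        )
        offsets = np.where(np.arange(n) < n // 2, rng.normal(15, 5, n), rng.normal(0, 5, n))
        hit_table = pd.DataFrame({"site_id": range(n), "pos": 100, "offset": offsets})
        profile = asc.variant_position_profile(
            target_table, hit_table, targets, "TF1", bandwidth=3.0
        )
        mode = {
            label: tab.loc[tab["density"].idxmax(), "x"]
            for label, tab in profile["offsets"].items()
        }
        assert mode["delta_ase"] > mode["no_delta_ase"] + 5

    def test_small_stratum_omitted_with_warning(self, caplog):
        target_table = pd.DataFrame(
            {
                "tf_name": ["TF1"] * 3,
                "gene_id": ["g0", "g1", "g2"],
                "n_variants": [1, 1, 0],
                "has_variant": [True, True, False],
                "delta_ase": [False, False, True],
            }
        )
        targets = pd.DataFrame(
            {"site_id": [0, 1, 2], "tf_name": "TF1", "gene_id": ["g0", "g1", "g2"]}
        )
        hit_table = pd.DataFrame({"site_id": [0, 1], "pos": [5, 6], "offset": [-1.0, 1.0]})
        with caplog.at_level("WARNING"):
            profile = asc.variant_position_profile(target_table, hit_table, targets, "TF1")
        assert "delta_ase" not in profile["offsets"]
        assert "omitted" in caplog.text


class TestEndToEndScreen:
    def test_causal_tf_recovered_at_top(self):
        out = run_end_to_end(seed=5, n_genes=2000, min_per_cell=50)
        screen = out["screen"]
        assert screen.iloc[0]["tf_name"] == "TF01"
        assert screen.iloc[0]["q"] < 0.05

    def test_null_screen_produces_no_discoveries(self):
        hits, total = 0, 0
        for seed in range(3):
            out = run_end_to_end(
                seed=200 + seed, n_genes=1000, p_variant_causal=0.2,
                p_variant_background=0.2, interaction_lfc=0.0, min_per_cell=25,
            )
            eligible = out["screen"][out["screen"]["eligible"]]
            hits += int((eligible["q"] < 0.05).sum())
            total += len(eligible)
        assert total >= 30
        assert hits / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)
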