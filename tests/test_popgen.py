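"""Selection-scan statistics against enumeration and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pollendrive.popgen import (
    bonferroni_adjust,
    ehh,
    gene_region_p,
    ihs,
    interval_admixture_correlation,
    quantile_binned_empirical_p,
    standardize_ihs,
    wc_fst,
    window_extreme_count,
)
from pollendrive.synth import HaplotypePanel, generate_haplotype_panel


def panel_from(matrix, cm=None):
    matrix = np.asarray(matrix, dtype=np.uint8)
    n = matrix.shape[1]
    cm = np.arange(n, dtype=float) if cm is None else np.asarray(cm, dtype=float)
    bp = (np.arange(n) + 1) * 1_000
    return HaplotypePanel(matrix, bp, cm)


def ehh_pair_enumeration(matrix, core, allele, snp):
    """Oracle: explicit homozygosity over all carrier pairs on [core, snp]."""
    carriers = matrix[matrix[:, core] == allele]
    lo, hi = min(core, snp), max(core, snp)
    n = carriers.shape[0]
    same = sum(
        np.array_equal(carriers[i, lo : hi + 1], carriers[j, lo : hi + 1])
        for i, j in itertools.combinations(range(n), 2)
    )
    return same / (n * (n - 1) / 2)


class TestEhh:
    def test_identical_carriers_have_unit_ehh_everywhere(self):
        panel = panel_from(np.tile([1, 0, 1, 1, 0], (6, 1)))
        assert np.allclose(ehh(panel, 2, 1), 1.0)

    def test_immediately_distinct_carriers_drop_to_zero(self):
        mat = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]])
        panel = panel_from(mat)
        e = ehh(panel, 0, 1)
        # four carriers pairwise split at the first flanking SNP:
        # groups {0,2} vs {1,3}, EHH = 2/6; then all four distinct: 0
        assert e[1] == pytest.approx(2 / 6)
        assert e[2] == 0.0

    def test_two_group_example_matches_pair_count(self):
        # carriers {AA, AA, AB, AB} over two flanking sites
        mat = np.array([[1, 0, 0], [1, 0, 0], [1, 0, 1], [1, 0, 1]])
        panel = panel_from(mat)
        e = ehh(panel, 0, 1)
        assert e[2] == pytest.approx((1 + 1) / 6)

    def test_matches_pair_enumeration_on_random_panels(self):
        rng = np.random.default_rng(12)
        mat = rng.integers(0, 2, size=(14, 9), dtype=np.uint8)
        core = 4
        mat[:, core] = np.repeat([0, 1], 7)  # ensure both alleles have carriers
        panel = panel_from(mat)
        for allele in (0, 1):
            e = ehh(panel, core, allele)
            for snp in range(9):
                assert e[snp] == pytest.approx(ehh_pair_enumeration(mat, core, allele, snp))

    def test_ehh_non_increasing_outward(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, size=(20, 15), dtype=np.uint8)
        mat[:, 7] = np.repeat([0, 1], 10)
        panel = panel_from(mat)
        e = ehh(panel, 7, 1)
        assert np.all(np.diff(e[7:]) <= 1e-12)
        assert np.all(np.diff(e[: 7 + 1][::-1]) <= 1e-12)

    def test_fewer_than_two_carriers_rejected(self):
        mat = np.zeros((5, 3), dtype=np.uint8)
        mat[0, 1] = 1
        with pytest.raises(ValueError):
            ehh(panel_from(mat), 1, 1)


class TestIhs:
    def test_allele_swap_symmetry_gives_zero_raw_score(self):
        # a panel closed under 0<->1 complementation: iHH_anc == iHH_der
        rng = np.random.default_rng(8)
        half = rng.integers(0, 2, size=(10, 11), dtype=np.uint8)
        mat = np.vstack([half, 1 - half])
        panel = panel_from(mat, cm=np.linspace(0, 10, 11))
        res = ihs(panel, maf_min=0.0, include_edges=True)
        assert np.allclose(res.table["ihs_raw"], 0.0, atol=1e-12)

    def test_standardized_scores_have_zero_mean_unit_sd_per_bin(self, rng):
        panel = generate_haplotype_panel(40, 150, "neutral", rng=rng)
        res = ihs(panel, n_bins=10)
        tab = res.table.dropna(subset=["ihs"])
        bins = np.clip((tab["freq_derived"] * 10).astype(int), 0, 9)
        for b in np.unique(bins):
            sub = tab[bins == b]
            if len(sub) >= 5:
                assert sub["ihs"].mean() == pytest.approx(0.0, abs=1e-9)
                assert sub["ihs"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_sweep_chromosome_concentrates_extreme_scores_at_origin(self):
        # hard-sweep chromosome plus three neutral companions, standardised
        # genome-wide; the origin-containing window collects the most
        # extreme |iHS| scores and the top SNP sits near the origin
        rng = np.random.default_rng(2)
        sweep = generate_haplotype_panel(60, 250, "sweep", rng=rng)
        tables = [ihs(sweep).table.assign(chrom="sweep")]
        for c in range(3):
            neutral = generate_haplotype_panel(60, 250, "neutral", rng=rng)
            tables.append(ihs(neutral).table.assign(chrom=f"neutral{c}"))
        alltab = standardize_ihs(pd.concat(tables, ignore_index=True), n_bins=10)
        sw = alltab[alltab["chrom"] == "sweep"].dropna(subset=["ihs"]).reset_index(drop=True)
        origin_cm = sweep.pos_cm[sweep.sweep_site]

        best = sw.loc[sw["ihs"].abs().idxmax()]
        assert abs(sweep.pos_cm[int(best["snp"])] - origin_cm) < 15.0

        threshold = np.nanquantile(np.abs(alltab["ihs"]), 0.95)
        extreme = sw[np.abs(sw["ihs"]) > threshold]
        window = 100_000
        counts = np.bincount((extreme["pos_bp"].to_numpy() - 1) // window, minlength=10)
        origin_window = int(sweep.pos_bp[sweep.sweep_site] - 1) // window
        assert counts[origin_window] == counts.max() > 0


class TestWindowExtremeCount:
    def test_no_scores_above_threshold_gives_all_zero(self):
        pos = np.arange(1, 101) * 100
        win = window_extreme_count(pos, np.zeros(100), window=5_000)
        assert (win["n_extreme"] == 0).all()

    def test_hand_placed_extremes_counted_in_their_window(self):
        # 100 background SNPs spread out, 3 outliers placed in window 0
        pos = np.r_[np.array([100, 200, 300]), np.arange(1, 101) * 9_000 + 30_000]
        scores = np.r_[np.array([5.0, 4.0, 4.5]), np.zeros(100)]
        win = window_extreme_count(pos, scores, window=10_000)
        assert win.loc[0, "n_extreme"] == 3
        assert win["n_extreme"].sum() == 3

    def test_quantile_definition_keeps_about_five_percent(self, rng):
        pos = rng.integers(1, 1_000_000, size=2_000)
        scores = rng.normal(size=2_000)
        win = window_extreme_count(pos, scores, window=10_000)
        total = win["n_extreme"].sum()
        assert total == pytest.approx(0.05 * 2_000, abs=3 * np.sqrt(0.05 * 0.95 * 2_000))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            window_extreme_count(np.array([]), np.array([]))


class TestEmpiricalP:
    def test_decile_maximum_gets_one_over_bin_size(self):
        win = pd.DataFrame(
            {
                "start": np.arange(20) * 10_000,
                "end": (np.arange(20) + 1) * 10_000,
                "n_snps": np.r_[np.full(10, 5), np.full(10, 50)],
                "n_extreme": np.r_[np.arange(10), np.arange(10)],
            }
        )
        out = quantile_binned_empirical_p(win, n_bins=2)
        top = out[(out["n_snps"] == 5) & (out["n_extreme"] == 9)]
        assert top["p_empirical"].iloc[0] == pytest.approx(1 / 10)

    def test_all_tied_windows_get_p_one(self):
        win = pd.DataFrame(
            {
                "start": np.arange(10) * 10_000,
                "end": (np.arange(10) + 1) * 10_000,
                "n_snps": np.arange(10) + 1,
                "n_extreme": np.full(10, 3),
            }
        )
        out = quantile_binned_empirical_p(win, n_bins=1)
        assert (out["p_empirical"] == 1.0).all()

    def test_matches_brute_force_rank_enumeration(self, rng):
        n = 20
        win = pd.DataFrame(
            {
                "start": np.arange(n) * 10_000,
                "end": (np.arange(n) + 1) * 10_000,
                "n_snps": rng.integers(1, 100, size=n),
                "n_extreme": rng.integers(0, 8, size=n),
            }
        )
        out = quantile_binned_empirical_p(win, n_bins=4)
        # oracle: within each assigned bin, p = #(stat >= own)/bin size
        for b, sub in out.groupby("snp_bin"):
            vals = sub["n_extreme"].to_numpy()
            for i, row in sub.iterrows():
                expected = (vals >= row["n_extreme"]).sum() / len(sub)
                assert row["p_empirical"] == pytest.approx(expected)

    def test_too_few_windows_rejected(self):
        win = pd.DataFrame({"n_snps": [1], "n_extreme": [0]})
        with pytest.raises(ValueError):
            quantile_binned_empirical_p(win, n_bins=10)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni_adjust(np.array([0.01]), 4)[0] == pytest.approx(0.04)
        assert bonferroni_adjust(np.array([0.5]), 4)[0] == 1.0
        assert np.allclose(bonferroni_adjust(np.array([0.3, 0.02]), 1), [0.3, 0.02])


class TestWcFst:
    @staticmethod
    def hand_theta(p, n):
        """Weir-Cockerham variance components computed longhand."""
        r = len(p)
        p, n = np.asarray(p, float), np.asarray(n, float)
        nbar_sum = n.sum()
        pbar = (n * p).sum() / nbar_sum
        msp = (n * (p - pbar) ** 2).sum() / (r - 1)
        msg = (n * p * (1 - p)).sum() / (n - 1).sum()
        n_c = (nbar_sum - (n**2).sum() / nbar_sum) / (r - 1)
        return (msp - msg) / (msp + (n_c - 1) * msg)

    def test_fixed_difference_gives_one(self):
        fst, _ = wc_fst(np.array([[10, 0]]), np.array([[10, 10]]))
        assert fst == pytest.approx(1.0)

    def test_identical_frequencies_give_small_nonpositive_estimate(self):
        fst, _ = wc_fst(np.array([[5, 5]]), np.array([[10, 10]]))
        assert fst <= 0.0
        assert fst == pytest.approx(self.hand_theta([0.5, 0.5], [10, 10]))

    def test_single_snp_matches_hand_computed_theta(self):
        fst, _ = wc_fst(np.array([[8, 2]]), np.array([[10, 10]]))
        assert fst == pytest.approx(self.hand_theta([0.8, 0.2], [10, 10]), abs=1e-12)

    def test_random_configurations_match_hand_computation(self, rng):
        for _ in range(100):
            r = int(rng.integers(2, 5))
            n = rng.integers(4, 30, size=r)
            alt = np.array([rng.integers(0, ni + 1) for ni in n])
            if len(set(alt / n)) == 1 and (alt / n)[0] in (0.0, 1.0):
                continue  # monomorphic: estimator undefined
            fst, _ = wc_fst(alt[None, :], n[None, :])
            expected = self.hand_theta(alt / n, n)
            if np.isnan(expected):
                assert np.isnan(fst)
            else:
                assert fst == pytest.approx(expected, abs=1e-10)

    def test_windowed_weighted_estimate_pools_components(self):
        alt = np.array([[8, 2], [7, 3], [10, 0]])
        n = np.full((3, 2), 10)
        pos = np.array([1_000, 2_000, 15_000])
        win, per_snp = wc_fst(alt, n, pos_bp=pos, window=10_000)
        assert len(win) == 2
        assert win.loc[1, "fst"] == pytest.approx(1.0)
        assert per_snp.size == 3

    def test_monomorphic_window_is_missing(self):
        win, _ = wc_fst(
            np.array([[0, 0]]), np.array([[10, 10]]), pos_bp=np.array([5_000]), window=10_000
        )
        assert np.isnan(win.loc[0, "fst"])


class TestGeneRegionP:
    def windows(self):
        return pd.DataFrame(
            {
                "start": [0, 10_000, 20_000],
                "end": [10_000, 20_000, 30_000],
                "p": [0.3, 0.02, 0.5],
            }
        )

    def test_gene_inside_one_window_takes_its_p(self):
        genes = pd.DataFrame({"name": ["g"], "start": [22_000], "end": [24_000]})
        out = gene_region_p(genes, self.windows(), flank=0)
        assert out["p"].iloc[0] == 0.5

    def test_gene_spanning_two_windows_takes_minimum(self):
        genes = pd.DataFrame({"name": ["g"], "start": [8_000], "end": [12_000]})
        out = gene_region_p(genes, self.windows(), flank=0)
        assert out["p"].iloc[0] == 0.02

    def test_flank_pulls_in_adjacent_window(self):
        genes = pd.DataFrame({"name": ["g"], "start": [20_500], "end": [24_000]})
        assert gene_region_p(genes, self.windows(), flank=0)["p"].iloc[0] == 0.5
        assert gene_region_p(genes, self.windows(), flank=1_000)["p"].iloc[0] == 0.02

    def test_gene_outside_all_windows_is_missing(self):
        genes = pd.DataFrame({"name": ["g"], "start": [90_000], "end": [95_000]})
        assert np.isnan(gene_region_p(genes, self.windows(), flank=1_000)["p"].iloc[0])


class TestIntervalCorrelation:
    def test_duplicated_intervals_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.random(8)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.random(8)})
        rho, _ = interval_admixture_correlation(table)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks_correlate_minus_one(self):
        x = np.arange(8.0)
        table = pd.DataFrame({"a": x, "b": x[::-1], "c": np.random.default_rng(1).random(8)})
        rho, _ = interval_admixture_correlation(table)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_monomorphic_interval_is_missing(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"a": rng.random(8), "fixed": np.full(8, 0.0)})
        rho, q = interval_admixture_correlation(table)
        assert np.isnan(rho.loc["a", "fixed"])
        assert np.isnan(q.loc["a", "fixed"])

    def test_correlated_blocks_recovered(self):
        rng = np.random.default_rng(3)
        base1, base2 = rng.random(12), rng.random(12)
        table = pd.DataFrame(
            {
                "a1": base1 + rng.normal(0, 0.01, 12),
                "a2": base1 + rng.normal(0, 0.01, 12),
                "b1": base2 + rng.normal(0, 0.01, 12),
                "b2": base2 + rng.normal(0, 0.01, 12),
            }
        )
        rho, q = interval_admixture_correlation(table)
        assert rho.loc["a1", "a2"] > 0.9
        assert rho.loc["b1", "b2"] > 0.9
        assert abs(rho.loc["a1", "b1"]) < 0.9
        assert q.loc["a1", "a2"] < 0.05

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError):
            interval_admixture_correlation(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))
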