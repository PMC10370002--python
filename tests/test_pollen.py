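"""Single-pollen analysis: binning, smoothing, HMM imputation, drive calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pollendrive.genetics import MarkerSet, haldane_r, meiosis_batch
from pollendrive.pollen import (
    SparseGenotypeMatrix,
    aggregate_allele_frequency,
    bin_signal,
    call_driven_intervals,
    impute_ancestry_hmm,
    sliding_window_smooth,
)
from pollendrive.synth import ObservationModel, observe_pollen_genotypes


def small_markers(positions, cms=None, chrom="chr1"):
    n = len(positions)
    return MarkerSet(
        pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "pos": positions,
                "cm": cms if cms is not None else np.linspace(0, n - 1, n),
                "ref": "W22",
                "alt": "mex",
            }
        )
    )


class TestBinSignal:
    def test_two_markers_land_in_their_own_bins(self):
        markers = small_markers([50_000, 150_000])
        mat = SparseGenotypeMatrix(np.array([[1], [-1]], dtype=np.int8), markers)
        track = bin_signal(mat, bin_size=100_000)
        assert track.values[0, 0] == 1.0
        assert track.values[1, 0] == -1.0

    def test_all_missing_bin_is_nan_not_zero(self):
        markers = small_markers([50_000, 150_000])
        mat = SparseGenotypeMatrix(np.array([[0], [1]], dtype=np.int8), markers)
        track = bin_signal(mat, bin_size=100_000)
        assert np.isnan(track.values[0, 0])

    def test_mixed_bin_is_the_mean_of_calls(self):
        markers = small_markers([10_000, 20_000, 30_000])
        mat = SparseGenotypeMatrix(np.array([[1], [1], [-1]], dtype=np.int8), markers)
        track = bin_signal(mat, bin_size=100_000)
        assert track.values[0, 0] == pytest.approx(1 / 3)

    def test_nonpositive_bin_size_rejected(self):
        markers = small_markers([100])
        mat = SparseGenotypeMatrix(np.zeros((1, 1), dtype=np.int8), markers)
        with pytest.raises(ValueError):
            bin_signal(mat, bin_size=0)


class TestSlidingWindowSmooth:
    def test_constant_track_stays_constant(self):
        markers = small_markers(list(range(50_000, 2_000_000, 100_000)))
        mat = SparseGenotypeMatrix(np.ones((20, 1), dtype=np.int8), markers)
        smooth = sliding_window_smooth(bin_signal(mat), window=1_000_000, step=200_000)
        assert np.allclose(smooth["grain0"].dropna(), 1.0)

    def test_step_function_becomes_a_ramp(self):
        # left half -1, right half +1: window means ramp linearly through 0
        markers = small_markers(list(range(50_000, 4_000_000, 100_000)))
        calls = np.where(np.array(markers.pos) < 2_000_000, -1, 1).astype(np.int8)
        mat = SparseGenotypeMatrix(calls[:, None], markers)
        smooth = sliding_window_smooth(bin_signal(mat), window=1_000_000, step=200_000)
        vals = smooth["grain0"].dropna().to_numpy()
        # oracle: direct mean of bin values inside each window
        track = bin_signal(mat)
        mids = (track.bins["start"] + track.bins["end"]).to_numpy() / 2
        expect = []
        for _, row in smooth.iterrows():
            inw = (mids >= row["start"]) & (mids < row["end"])
            if inw.any():
                expect.append(track.values[inw, 0].mean())
        assert np.allclose(vals, expect)
        assert np.all(np.diff(vals) >= -1e-12)  # monotone ramp

    def test_all_missing_smooths_to_all_missing(self):
        markers = small_markers([50_000, 150_000])
        mat = SparseGenotypeMatrix(np.zeros((2, 1), dtype=np.int8), markers)
        smooth = sliding_window_smooth(bin_signal(mat))
        assert smooth["grain0"].isna().all()

    def test_window_smaller_than_step_rejected(self):
        markers = small_markers([50_000])
        mat = SparseGenotypeMatrix(np.ones((1, 1), dtype=np.int8), markers)
        with pytest.raises(ValueError):
            sliding_window_smooth(bin_signal(mat), window=100_000, step=200_000)


def brute_force_posterior(obs, cm, eps):
    """Enumerate all 2^m ancestry paths and marginalise exactly."""
    m = len(obs)
    r = haldane_r(np.diff(cm))
    post = np.zeros((m, 2))
    for path in itertools.product((0, 1), repeat=m):
        p = 0.5
        for j in range(1, m):
            p *= r[j - 1] if path[j] != path[j - 1] else 1 - r[j - 1]
        for j, s in enumerate(path):
            if obs[j] == 0:
                continue
            match = (obs[j] == 1) == (s == 1)
            p *= (1 - eps) if match else eps
        for j, s in enumerate(path):
            post[j, s] += p
    return post[:, 1] / post.sum(axis=1)


class TestAncestryHmm:
    @pytest.mark.parametrize(
        "obs",
        [
            [1, 1, 0, -1, -1],
            [1, -1, 1, -1, 1, 0, 0, -1],
            [0, 1, 1, 1, -1, -1, 0, 1, -1, 1],
        ],
    )
    def test_posterior_matches_brute_force_enumeration(self, obs):
        obs = np.array(obs, dtype=np.int8)
        m = obs.size
        cms = np.cumsum(np.linspace(1, 6, m)) - 1
        markers = small_markers(list(range(1, m * 10, 10)), cms=cms)
        res = impute_ancestry_hmm(obs, markers, eps=0.05)
        oracle = brute_force_posterior(obs, cms, 0.05)
        assert np.allclose(res.p_alt, oracle, atol=1e-12)

    def test_single_switch_decoded_within_one_interval(self):
        m = 20
        markers = small_markers(list(range(1, m * 10, 10)), cms=np.arange(m) * 2.0)
        truth = np.array([0] * 10 + [1] * 10)
        obs = np.where(truth == 1, 1, -1).astype(np.int8)
        res = impute_ancestry_hmm(obs, markers, eps=1e-4)
        assert res.switch_points == [10]

    def test_all_alt_calls_give_posterior_near_one(self):
        markers = small_markers(list(range(1, 51, 10)), cms=np.arange(5) * 1.0)
        res = impute_ancestry_hmm(np.ones(5, dtype=np.int8), markers, eps=0.05)
        assert np.all(res.p_alt > 0.99)

    def test_uninformative_grain_rejected(self):
        markers = small_markers(list(range(1, 51, 10)), cms=np.arange(5) * 1.0)
        with pytest.raises(ValueError):
            impute_ancestry_hmm(np.zeros(5, dtype=np.int8), markers, eps=0.05)

    def test_decoding_accuracy_on_sparse_noisy_grains(self, rng):
        # 200 markers over 100 cM, 80% missing, 5% genotyping error
        m = 200
        markers = small_markers(
            list(range(1, m * 500_000, 500_000)), cms=np.linspace(0, 100, m)
        )
        from pollendrive.genetics import DiploidGenotype, GeneticMap, Haplotype

        parent = DiploidGenotype(
            Haplotype(np.zeros(m, dtype=np.int8), markers),
            Haplotype(np.ones(m, dtype=np.int8), markers),
        )
        gmap = GeneticMap(markers)
        truth = meiosis_batch(parent, gmap, rng, 50)
        model = ObservationModel(missing_rate=0.8, error_rate=0.05)
        mat = observe_pollen_genotypes(truth, markers, model, rng)
        correct = total = 0
        for g in range(50):
            if np.count_nonzero(mat.data[:, g]) < 2:
                continue
            res = impute_ancestry_hmm(mat.data[:, g], markers, eps=0.05)
            hard = res.decoded != 0
            states = np.where(res.decoded[hard] == 1, 1, 0)
            correct += (states == truth[g][hard]).sum()
            total += hard.sum()
        assert total > 0
        assert correct / total >= 0.99


class TestAggregateFrequency:
    def test_driven_loci_fixed_in_surviving_pollen(self, scenario, rng):
        from pollendrive.simulate import simulate_pollen_population

        pop = simulate_pollen_population(scenario.drive_parent, scenario.rule, 800, rng, scenario.gmap)
        truth = np.where(pop.viable_gametes().T == 1, 1, -1).astype(np.int8)
        mat = SparseGenotypeMatrix(truth, scenario.markers)
        freq = aggregate_allele_frequency(mat)
        assert freq[scenario.loci["Tpd1"]] == 1.0
        assert freq[scenario.loci["Tpd2"]] == 1.0

    def test_frequency_equals_truth_matrix_mean_exactly(self, scenario, rng):
        gam = meiosis_batch(scenario.drive_parent, scenario.gmap, rng, 64)
        truth = np.where(gam.T == 1, 1, -1).astype(np.int8)
        mat = SparseGenotypeMatrix(truth, scenario.markers)
        assert np.allclose(aggregate_allele_frequency(mat), gam.mean(axis=0))

    def test_single_ref_grain_gives_zero(self):
        markers = small_markers([10])
        mat = SparseGenotypeMatrix(np.array([[-1]], dtype=np.int8), markers)
        assert aggregate_allele_frequency(mat)[0] == 0.0

    def test_uncalled_marker_is_missing(self):
        markers = small_markers([10, 20])
        mat = SparseGenotypeMatrix(np.array([[0], [1]], dtype=np.int8), markers)
        freq = aggregate_allele_frequency(mat)
        assert np.isnan(freq[0]) and freq[1] == 1.0


def null_matrix(n_grains, rng, n_markers=50):
    """Fair-transmission single-chromosome observation matrix."""
    from pollendrive.genetics import DiploidGenotype, GeneticMap, Haplotype

    markers = small_markers(
        list(range(1, n_markers * 2_000_000, 2_000_000)), cms=np.linspace(0, 100, n_markers)
    )
    parent = DiploidGenotype(
        Haplotype(np.zeros(n_markers, dtype=np.int8), markers),
        Haplotype(np.ones(n_markers, dtype=np.int8), markers),
    )
    truth = meiosis_batch(parent, GeneticMap(markers), rng, n_grains)
    model = ObservationModel(missing_rate=0.8, error_rate=0.05)
    return observe_pollen_genotypes(truth, markers, model, rng)


class TestDrivenIntervals:
    def test_recovers_both_planted_drive_loci(self, scenario, rng):
        from pollendrive.simulate import simulate_pollen_population

        pop = simulate_pollen_population(scenario.drive_parent, scenario.rule, 800, rng, scenario.gmap)
        viable = pop.viable_gametes()[:178]
        model = ObservationModel(missing_rate=0.8, error_rate=0.05)
        mat = observe_pollen_genotypes(viable, scenario.markers, model, rng)
        intervals, _ = call_driven_intervals(mat, bin_size=2_000_000)
        tab = scenario.markers.table

        def covered(locus):
            chrom = tab["chrom"].iloc[scenario.loci[locus]]
            pos = tab["pos"].iloc[scenario.loci[locus]]
            sub = intervals[intervals["chrom"] == chrom]
            return ((sub["start"] < pos) & (pos <= sub["end"])).any()

        assert covered("Tpd1") and covered("Tpd2")
        # the neutral chromosome is never called
        assert not (intervals["chrom"] == "chr1").any()

    def test_false_call_rate_calibrated_under_the_null(self, rng):
        reps = 1000
        hits = 0
        for _ in range(reps):
            mat = null_matrix(178, rng)
            intervals, _ = call_driven_intervals(mat, bin_size=2_000_000, alpha=0.05)
            hits += int(len(intervals) > 0)
        rate = hits / reps
        # BH at alpha=0.05 with discrete binomial p-values is conservative
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_exactly_mendelian_frequencies_yield_no_calls(self):
        markers = small_markers(list(range(1, 10 * 100_000, 100_000)))
        # every marker called in all 20 grains, exactly half of them donor
        data = np.tile(np.array([1, -1], dtype=np.int8), (10, 10))
        mat = SparseGenotypeMatrix(data, markers)
        intervals, _ = call_driven_intervals(mat, bin_size=100_000)
        assert len(intervals) == 0

    def test_too_few_grains_rejected(self):
        markers = small_markers([10])
        mat = SparseGenotypeMatrix(np.ones((1, 5), dtype=np.int8), markers)
        with pytest.raises(ValueError):
            call_driven_intervals(mat)


@given(st.permutations(list(range(6))))
def test_binning_and_smoothing_commute_with_grain_relabeling(perm):
    rng = np.random.default_rng(99)
    markers = small_markers(list(range(50_000, 3_000_000, 150_000)))
    data = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(markers.n_markers, 6))
    mat = SparseGenotypeMatrix(data, markers)
    permuted = SparseGenotypeMatrix(data[:, perm], markers)
    a = sliding_window_smooth(bin_signal(mat))
    b = sliding_window_smooth(bin_signal(permuted))
    for new, old in enumerate(perm):
        assert np.allclose(
            a[f"grain{old}"].to_numpy(), b[f"grain{new}"].to_numpy(), equal_nan=True
        )
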