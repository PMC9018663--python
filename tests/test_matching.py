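"""Channel scoring, score fusion, and the conjunctive hit rule."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asapscreen.matching import (
    MatchCriteria,
    MatchResult,
    apply_criteria,
    channel_score,
    fuse_scores,
    screen,
)
from asapscreen.spectra import Spectrum
from asapscreen.synthetic import (
    SampleDefinition,
    SimulationParams,
    generate_validation_set,
    simulate_acquisition,
)


def spec(pairs):
    return Spectrum.from_pairs(pairs)


def brute_force_cosine_score(query_pairs, ref_pairs):
    """Independent oracle: explicit union-bin dot product on sqrt intensities."""
    q = {int(round(m)): 0.0 for m, _ in query_pairs} | {int(round(m)): 0.0 for m, _ in ref_pairs}
    r = dict(q)
    for m, i in query_pairs:
        q[int(round(m))] += i
    for m, i in ref_pairs:
        r[int(round(m))] += i
    dot = nq = nr = 0.0
    for mz in q:
        a, b = math.sqrt(q[mz]), math.sqrt(r[mz])
        dot += a * b
        nq += a * a
        nr += b * b
    if nq == 0 or nr == 0:
        return 0
    return math.floor(1000.0 * dot / math.sqrt(nq * nr) + 0.5)


class TestChannelScore:
    def test_self_match_is_1000(self):
        s = spec([(345, 100.0), (271, 28.0), (109, 23.8)])
        assert channel_score(s, s) == 1000

    def test_disjoint_sets_score_0(self):
        assert channel_score(spec([(345, 100.0)]), spec([(383, 100.0)])) == 0

    def test_hand_computed_cosine_example(self):
        # single-peak query vs two-peak reference: cos = 10*10/(10*sqrt(200))
        q, r = [(331, 100.0)], [(331, 100.0), (271, 100.0)]
        assert channel_score(spec(q), spec(r)) == 707
        assert brute_force_cosine_score(q, r) == 707

    def test_against_matchms_oracle(self, library):
        """Cross-check against matchms CosineGreedy on sqrt intensities."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        sample = SampleDefinition({"T En": 100.0, "E2 V1": 60.0}, matrix="oil", seed=3)
        acq, _ = simulate_acquisition(sample)
        from asapscreen.spectra import preprocess

        for abbr in ("T En", "E2 V1", "T Dc"):
            for v in (12, 40):
                q = preprocess(acq[v], library.build_params)
                r = library[abbr].channels[v]
                ms_q = matchms.Spectrum(mz=q.mz, intensities=np.sqrt(q.intensities),
                                        metadata={}, metadata_harmonization=False)
                ms_r = matchms.Spectrum(mz=r.mz, intensities=np.sqrt(r.intensities),
                                        metadata={}, metadata_harmonization=False)
                expected = float(CosineGreedy(tolerance=0.5).pair(ms_q, ms_r)["score"])
                assert abs(channel_score(q, r) - 1000 * expected) <= 1

    @given(
        st.lists(st.tuples(st.integers(50, 600), st.floats(0.1, 100)),
                 min_size=1, max_size=12, unique_by=lambda p: p[0]),
        st.lists(st.tuples(st.integers(50, 600), st.floats(0.1, 100)),
                 min_size=1, max_size=12, unique_by=lambda p: p[0]),
    )
    @settings(max_examples=75, deadline=None)
    def test_symmetry_range_and_oracle(self, a, b):
        sa, sb = spec(a), spec(b)
        s_ab = channel_score(sa, sb)
        assert s_ab == channel_score(sb, sa)
        assert 0 <= s_ab <= 1000
        assert s_ab == brute_force_cosine_score(a, b)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            channel_score(spec([]), spec([(345, 100.0)]))

    def test_reference_kind_ignores_extra_query_peaks(self):
        ref = spec([(345, 100.0), (271, 28.0)])
        mixture = spec([(345, 100.0), (271, 28.0), (383, 100.0), (401, 95.0)])
        assert channel_score(mixture, ref, kind="reference") == 1000
        assert channel_score(mixture, ref) < 1000


class TestFuseScores:
    def test_equal_scores(self):
        assert fuse_scores((900, 900, 900, 900)) == 900.0

    def test_boundary_average(self):
        assert fuse_scores((850, 825, 825, 825)) == 831.25

    def test_degenerate_weighting(self):
        assert fuse_scores((700, 0, 0, 0), weights=(1, 0, 0, 0)) == 700.0

    def test_weight_count_mismatch(self):
        with pytest.raises(ValueError):
            fuse_scores((900, 900), weights=(0.25, 0.25, 0.25, 0.25))


def result(scores, weights=(0.25,) * 4):
    cs = dict(zip((12, 20, 30, 40), scores))
    return MatchResult("X", cs, fuse_scores(cs, weights), hit=False)


class TestCriteria:
    def test_boundary_triple_is_hit(self):
        assert apply_criteria(result((850, 825, 825, 825)))

    def test_single_violations_defeat_hit(self):
        assert not apply_criteria(result((900, 800, 900, 900)))  # channel 2 low
        assert not apply_criteria(result((840, 900, 900, 900)))  # channel 1 low

    def test_truth_table_grid_matches_brute_force(self):
        """Exhaustive grid around the three thresholds vs the printed conjunction."""
        crit = MatchCriteria()
        grid = (790, 800, 824, 825, 826, 849, 850, 851, 1000)
        for scores in itertools.product(grid, repeat=4):
            r = result(scores)
            expected = (
                scores[0] >= 850
                and all(s >= 825 for s in scores[1:])
                and sum(scores) / 4 >= 800
            )
            assert apply_criteria(r, crit) == expected

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            MatchCriteria(channel1_min=1100)
        with pytest.raises(ValueError):
            MatchCriteria(weights=(0.5, 0.5, 0.5, -0.5))


class TestScreen:
    def test_self_screening_scores_1000(self, library):
        entry = library["T En"]
        results = screen(entry.channels, library)
        top = results[0]
        assert top.compound == "T En"
        assert all(s == 1000 for s in top.channel_scores.values())
        assert top.average_score == 1000.0
        assert top.hit

    def test_pure_standard_ranked_first(self, library):
        sample = SampleDefinition({"T Pr": 100.0}, matrix="oil", seed=11)
        acq, _ = simulate_acquisition(sample)
        results = screen(acq, library)
        assert results[0].compound == "T Pr"
        assert results[0].hit

    def test_params_mismatch_rejected(self, library):
        from asapscreen.spectra import PreprocessParams

        entry = library["T En"]
        with pytest.raises(ValueError, match="parameters"):
            screen(entry.channels, library, params=PreprocessParams(threshold_pct=10.0))

    def test_results_sorted_desc_with_lexicographic_ties(self, library):
        sample = SampleDefinition({"T Pr": 100.0}, matrix="oil", seed=11)
        acq, _ = simulate_acquisition(sample)
        results = screen(acq, library)
        keys = [(-r.average_score, r.compound) for r in results]
        assert keys == sorted(keys)


class TestScreeningProperties:
    def test_full_criteria_hits_subset_of_average_only(self, library):
        """The mechanism behind the false-positive reduction: adding per-channel
        conditions can only remove hits relative to the average-only rule."""
        full = MatchCriteria()
        avg_only = MatchCriteria(channel1_min=0, other_channels_min=0, average_min=800)
        for seed in range(6):
            sample = SampleDefinition(
                {"E2 DiPr": 100.0, "Tr En": 100.0}, matrix="oil", seed=seed
            )
            acq, _ = simulate_acquisition(sample)
            hits_full = {r.compound for r in screen(acq, library, full) if r.hit}
            hits_avg = {r.compound for r in screen(acq, library, avg_only) if r.hit}
            assert hits_full <= hits_avg

    def test_mixture_degrades_score_relative_to_pure(self, library):
        clean = SimulationParams(noise_sigma=0.0)
        pure, _ = simulate_acquisition(
            SampleDefinition({"T Pr": 100.0}, matrix="none", seed=1), clean
        )
        mixed, _ = simulate_acquisition(
            SampleDefinition({"T Pr": 100.0, "B Un": 100.0, "E2 Bz": 100.0},
                             matrix="none", seed=1),
            clean,
        )
        score_pure = next(r for r in screen(pure, library) if r.compound == "T Pr")
        score_mixed = next(r for r in screen(mixed, library) if r.compound == "T Pr")
        for v in (12, 20, 30, 40):
            assert score_mixed.channel_scores[v] <= score_pure.channel_scores[v]
        assert score_mixed.average_score <= score_pure.average_score

    def test_cocktails_recovered_under_reference_kind_score(self, library):
        """The symmetric union-bin cosine penalizes the extra precursor ions a
        cocktail adds at 12 V, so cocktail constituents cannot all reach the
        channel-1 threshold under the default score; the mixture-tolerant
        reference-bin variant recovers every constituent."""
        data = generate_validation_set(
            n_samples=12, mixture_sizes=(3,), concentration_range=(100.0, 100.0),
            matrix="oil", seed=99,
        )
        for sample, (acq, _) in data:
            truth = set(sample.constituents)
            hits_default = {r.compound for r in screen(acq, library) if r.hit}
            hits_reference = {r.compound for r in screen(acq, library, kind="reference") if r.hit}
            assert not (truth <= hits_default)  # default score misses constituents
            assert truth <= hits_reference

    def test_estradiol_esters_more_confusable_than_cross_family(self, library):
        """Shared fragment ions (279/255/159/135/109) make the two estradiol
        esters mutually similar at high voltage, unlike unrelated esters."""
        for v in (30, 40):
            e2_pair = channel_score(
                library["E2 V1"].channels[v], library["E2 DiPr"].channels[v]
            )
            cross = channel_score(
                library["E2 V1"].channels[v], library["T Dc"].channels[v]
            )
            assert e2_pair > cross
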