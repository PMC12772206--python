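"""Excision and deamination simulators: distributions, determinism, truth."""

import math

import numpy as np
import pytest

from gaptract import (
    CircularInterval,
    DeaminationModelParams,
    ExcisionModelParams,
    find_protected_intervals,
    simulate_deamination,
    simulate_exo1,
    simulate_mlh_mixture,
    simulate_nick_dissociation,
)
from gaptract.simulate import DistSpec, GapSet, fixed, _dissociate
from gaptract.substrate import reverse_complement


class TestExo1:
    def test_point_distribution_gives_identical_gaps(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="exo1", exo1_tract_length_dist=fixed(500), seed=1)
        for gs in simulate_exo1(fixture_substrate, params, 10):
            (gap,) = gs.gaps
            assert gap.start == fixture_substrate.nick_position
            assert gap.length(2900) == 500
            assert gs.origin_tags == ["nick_initiated"]

    def test_uniform_support_is_respected(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="exo1", seed=2)  # default uniform [327, 832]
        lengths = [gs.gaps[0].length(2900) for gs in simulate_exo1(fixture_substrate, params, 1000)]
        assert min(lengths) >= 327
        assert max(lengths) <= 832

    def test_determinism_under_seed(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="exo1", seed=3)
        a = simulate_exo1(fixture_substrate, params, 50)
        b = simulate_exo1(fixture_substrate, params, 50)
        assert [gs.gaps for gs in a] == [gs.gaps for gs in b]

    def test_full_circle_excision_rejected(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="exo1", exo1_tract_length_dist=fixed(2900))
        with pytest.raises(ValueError, match="full-circle"):
            simulate_exo1(fixture_substrate, params, 1)


class TestMlhMixture:
    def test_mixture_collapse_at_probability_one(self, fixture_substrate):
        params = ExcisionModelParams(polar_probability=1.0, seed=4)
        for gs in simulate_mlh_mixture(fixture_substrate, params, 50):
            assert gs.origin_tags == ["nick_initiated"]
            assert gs.gaps[0].start == fixture_substrate.nick_position

    def test_polar_fraction_within_binomial_error(self, fixture_substrate):
        n = 10_000
        params = ExcisionModelParams(polar_probability=0.4, seed=5)
        gapsets = simulate_mlh_mixture(fixture_substrate, params, n)
        frac = sum(1 for gs in gapsets if "nick_initiated" in gs.origin_tags) / n
        assert abs(frac - 0.4) <= 3 * math.sqrt(0.4 * 0.6 / n)

    def test_fixed_count_gives_exactly_k_disjoint_gaps(self, fixture_substrate):
        params = ExcisionModelParams(polar_probability=0.0,
                                     dispersed_gap_count_dist=fixed(6), seed=6)
        for gs in simulate_mlh_mixture(fixture_substrate, params, 30):
            assert len(gs.gaps) == 6
            gs.validate(2900)  # raises if any pair overlaps

    def test_dispersed_lengths_within_truncation(self, fixture_substrate):
        params = ExcisionModelParams(polar_probability=0.0, seed=7)
        lengths = [g.length(2900) for gs in simulate_mlh_mixture(fixture_substrate, params, 500)
                   for g in gs.gaps]
        assert min(lengths) >= 1
        assert max(lengths) <= 132


class TestNickDissociation:
    def test_hand_enumerated_fragment_loss(self):
        # nicks at 10, 15, 100 on a 2,900 circle; only the 5 nt fragment
        # between 10 and 15 is under the 20 nt threshold
        gaps, tags = _dissociate([10, 15, 100], 2900, threshold=20, primary_nick=10)
        assert [(g.start, g.end) for g in gaps] == [(10, 15)]
        assert tags == ["nick_initiated"]

    def test_adjacent_losses_coalesce(self):
        gaps, _ = _dissociate([10, 15, 25, 100], 2900, threshold=20, primary_nick=100)
        assert [(g.start, g.end) for g in gaps] == [(10, 25)]

    def test_lone_nick_produces_no_gap(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="mlh_pms1_nick_dissociation",
                                     nick_rate=0.0, seed=8)
        nicks, gaps = simulate_nick_dissociation(fixture_substrate, params, 5)
        for ns, gs in zip(nicks, gaps):
            assert ns.nick_positions == [fixture_substrate.nick_position]
            assert gs.gaps == []

    def test_threshold_beyond_plasmid_rejected(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="mlh_pms1_nick_dissociation",
                                     dissociation_threshold=3000)
        with pytest.raises(ValueError, match="exceeds plasmid length"):
            simulate_nick_dissociation(fixture_substrate, params, 1)

    def test_threshold_one_keeps_everything(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="mlh_pms1_nick_dissociation",
                                     nick_rate=10.0, dissociation_threshold=1, seed=9)
        _, gaps = simulate_nick_dissociation(fixture_substrate, params, 20)
        assert all(gs.gaps == [] for gs in gaps)

    def test_large_threshold_keeps_only_guard_fragment(self, fixture_substrate):
        params = ExcisionModelParams(mechanism="mlh_pms1_nick_dissociation",
                                     nick_rate=10.0, dissociation_threshold=2900, seed=10)
        _, gaps = simulate_nick_dissociation(fixture_substrate, params, 10)
        for gs in gaps:
            lost = sum(g.length(2900) for g in gs.gaps)
            assert lost < 2900  # the longest fragment is always retained


class TestDeamination:
    def test_certainty_limit_hits_every_eligible_position(self, fixture_substrate):
        gap = CircularInterval(100, 400)
        gs = GapSet("m0", [gap], ["internal"])
        params = DeaminationModelParams(context_probability={"pyrimidine-C": 1.0, "purine-C": 1.0},
                                        use_protection=False, seed=11)
        clone = simulate_deamination(fixture_substrate, gs, params)
        expected = [p for p in range(100, 400) if fixture_substrate.base(p) == "G"]
        assert clone.truth_deaminated == expected
        diffs = [i for i, (a, b) in enumerate(zip(fixture_substrate.sequence_nicked_strand,
                                                  clone.sequence)) if a != b]
        assert diffs == expected

    def test_zero_probability_leaves_reference_untouched(self, fixture_substrate):
        gs = GapSet("m0", [CircularInterval(0, 2000)], ["internal"])
        params = DeaminationModelParams(context_probability={"pyrimidine-C": 0.0, "purine-C": 0.0})
        clone = simulate_deamination(fixture_substrate, gs, params)
        assert clone.sequence == fixture_substrate.sequence_nicked_strand

    def test_protected_interval_excluded_from_deamination(self, fixture_substrate):
        import dataclasses
        sub = dataclasses.replace(fixture_substrate,
                                  protected_intervals=[CircularInterval(200, 260)])
        gs = GapSet("m0", [CircularInterval(100, 400)], ["internal"])
        params = DeaminationModelParams(context_probability={"pyrimidine-C": 1.0, "purine-C": 1.0},
                                        use_protection=True, seed=12)
        clone = simulate_deamination(sub, gs, params)
        expected = [p for p in range(100, 400)
                    if sub.base(p) == "G" and not 200 <= p < 260]
        assert clone.truth_deaminated == expected

    def test_substitutions_confined_to_truth_gaps(self, fixture_substrate):
        """Conservation: every substitution lies inside a truth gap."""
        gs = GapSet("m0", [CircularInterval(2800, 150), CircularInterval(500, 600)],
                    ["internal", "internal"])
        params = DeaminationModelParams(seed=13)
        clone = simulate_deamination(fixture_substrate, gs, params)
        inside = set(gs.gaps[0].positions(2900)) | set(gs.gaps[1].positions(2900))
        diffs = {i for i, (a, b) in enumerate(zip(fixture_substrate.sequence_nicked_strand,
                                                  clone.sequence)) if a != b}
        assert diffs <= inside


class TestDistSpec:
    def test_zero_truncated_poisson_support(self):
        rng = np.random.default_rng(0)
        d = DistSpec("zero_truncated_poisson", {"mean": 1.6, "max": 6})
        draws = [d.sample(rng) for _ in range(2000)]
        assert min(draws) >= 1 and max(draws) <= 6

    def test_lognormal_median_and_truncation(self):
        rng = np.random.default_rng(1)
        d = DistSpec("lognormal_int", {"median": 17, "sigma": 1.0, "low": 1, "high": 132})
        draws = sorted(d.sample(rng) for _ in range(4000))
        assert 1 <= draws[0] and draws[-1] <= 132
        med = draws[len(draws) // 2]
        assert 13 <= med <= 21  # median near the nominal 17 nt

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            DistSpec("cauchy", {}).sample(np.random.default_rng(0))


class TestProtectedIntervalFinder:
    def test_planted_hairpin_detected(self):
        # A/C-only background cannot pair with itself (no T or G), so the
        # planted G/C hairpin (stem >= 5, loop 3) is the only inverted repeat
        seq = "ACAACCACAACACCACCAAC" + "GGGGCCAAAGGCCCC" + "CACCAACACACCACAACCAA"
        hits = find_protected_intervals(seq, stem_min=5, loop_max=4)
        assert len(hits) == 1
        (iv,) = hits
        assert iv.contains(25, len(seq))  # middle of the hairpin insert

    def test_homopolymer_has_no_hairpin(self):
        assert find_protected_intervals("A" * 80, stem_min=5, loop_max=6) == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        L = len(seq)
        fwd = find_protected_intervals(seq, stem_min=5, loop_max=6)
        rev = find_protected_intervals(reverse_complement(seq), stem_min=5, loop_max=6)
        fwd_mapped = {frozenset((L - 1 - p) % L for p in iv.positions(L)) for iv in fwd}
        rev_sets = {frozenset(iv.positions(L)) for iv in rev}
        assert fwd_mapped == rev_sets

    def test_stem_min_validation(self):
        with pytest.raises(ValueError):
            find_protected_intervals("ACGT" * 30, stem_min=2)
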