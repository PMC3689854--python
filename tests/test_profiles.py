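"""Transition-probability profiles, pattern scoring and featurization."""

import numpy as np
import pytest

from mireader.duplex import EncodedPattern
from mireader.profiles import (
    build_profiles, cluster_patterns, featurize, load_profiles,
    save_profiles, score_pattern,
)
from oracles import score_pattern_oracle


def P(s):
    return EncodedPattern(s)


class TestBuildProfiles:
    def test_single_pattern_cell_is_one_unsmoothed(self):
        profs = build_profiles([P("MMXMX")], pseudocount=0.0, min_support=1)
        ps = profs[5]
        assert ps.subprofiles["XX"][2, 4] == 1.0

    def test_absent_state_smoothing_floor(self):
        profs = build_profiles([P("MMXMX"), P("MXMXM")], pseudocount=0.5,
                               min_support=1)
        ii = profs[5].subprofiles["II"]
        upper = ii[np.triu_indices_from(ii, k=1)]
        # no insertions anywhere: every cell at the pseudocount floor
        assert np.allclose(upper, 0.5 / (0 + 0.5 * 5))

    def test_distinct_lengths_distinct_clusters(self):
        profs = build_profiles([P("MMXMX")] * 5 + [P("MMXMXM")] * 5,
                               min_support=5)
        assert sorted(profs) == [5, 6]

    def test_probabilities_in_unit_interval(self, rng):
        pats = [P("".join(rng.choice(list("MXID"), size=12,
                                     p=[0.7, 0.2, 0.05, 0.05])))
                for _ in range(40)]
        for ps in build_profiles(pats, min_support=1).values():
            for mat in ps.subprofiles.values():
                assert ((mat >= 0) & (mat <= 1)).all()

    def test_small_clusters_merge_to_nearest(self):
        pats = [P("M" * 10)] * 6 + [P("M" * 11)] * 2
        clusters = cluster_patterns(pats, min_support=5)
        assert sorted(clusters) == [10]
        assert len(clusters[10]) == 8

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            build_profiles([])


class TestScorePattern:
    def test_all_match_scores_zero(self):
        profs = build_profiles([P("MXMMX")] * 5, min_support=1)
        total, vec = score_pattern("MMMMM", profs[5])
        assert total == 0.0 and not vec.any()

    def test_first_nonmatch_has_no_prior(self):
        profs = build_profiles([P("MXMMX")] * 5, pseudocount=0.0, min_support=1)
        total, vec = score_pattern("MXMMX", profs[5])
        assert vec[1] == 0.0            # no earlier non-M state
        assert vec[4] == 1.0            # X@1 -> X@4 seen in every pattern
        assert total == 1.0

    def test_cross_family_id_transition_scores_zero(self):
        profs = build_profiles([P("MIMMD")] * 4, pseudocount=0.0, min_support=1)
        total, vec = score_pattern("MIMMD", profs[5])
        # only prior non-M state is I at 1; I->D has no subprofile
        assert vec[4] == 0.0

    def test_invalid_state_rejected(self):
        profs = build_profiles([P("MXMMX")], min_support=1)
        with pytest.raises(ValueError):
            score_pattern("MXQMM", profs[5])

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Positional max over all prior non-M cells, 1000 random patterns."""
        train = [P("".join(rng.choice(list("MXID"), size=14,
                                      p=[0.6, 0.25, 0.1, 0.05])))
                 for _ in range(30)]
        profs = build_profiles(train, min_support=1)
        ps = profs[14]
        for _ in range(1000):
            q = "".join(rng.choice(list("MXID"), size=14,
                                   p=[0.55, 0.25, 0.1, 0.1]))
            total, _ = score_pattern(q, ps)
            assert total == pytest.approx(score_pattern_oracle(q, ps))


class TestFeaturize:
    def _profiles(self):
        pats = ([P("MMXMMMMMMMXMMM")] * 10 + [P("MMMMXMMMMMMMXMMM")] * 6)
        return build_profiles(pats, min_support=5)

    def test_training_pattern_self_consistent(self):
        profs = self._profiles()
        fv = featurize("MMXMMMMMMMXMMM", profs)
        assert fv.representative_profile == 14

    def test_all_match_ties_break_to_support(self):
        profs = self._profiles()
        fv = featurize("M" * 15, profs)
        assert fv.rscore == 0.0
        assert fv.representative_profile == 14  # larger training support

    def test_best_matrix_score_wins(self):
        profs = self._profiles()
        fv = featurize("MMMMXMMMMMMMXMMM", profs)
        assert fv.representative_profile == 16
        s16, _ = score_pattern("MMMMXMMMMMMMXMMM", profs[16])
        assert fv.rscore == pytest.approx(s16)

    def test_inadmissible_length_flagged(self):
        profs = self._profiles()
        fv = featurize("MX" * 15, profs)  # length 30, nearest cluster 16
        assert fv.flagged and fv.representative_profile == 16

    def test_vector_width_is_cluster_length(self):
        profs = self._profiles()
        for q in ("MMXMMMMMMMXM", "MMXMMMMMMMXMMMM"):
            fv = featurize(q, profs)
            assert len(fv.values) == fv.representative_profile
            assert fv.rscore == pytest.approx(fv.values.sum())


def test_discrimination_of_structured_patterns():
    """Patterns from the structured positive model outscore their own
    state-shuffled permutations under the positive profile in >= 95% of
    seeded repetitions (n=200 per side)."""
    from mireader.fixtures import SyntheticDuplexSpec, simulate_duplexes

    wins = 0
    reps = 20
    for rep in range(reps):
        spec = SyntheticDuplexSpec(200, 0, seed=500 + rep)
        pats = [d.pattern for d in simulate_duplexes(spec)]
        profs = build_profiles([P(p) for p in pats])
        rng = np.random.default_rng(900 + rep)
        pos_scores = [featurize(p, profs).rscore for p in pats]
        shuf_scores = [
            featurize("".join(rng.permutation(list(p))), profs).rscore
            for p in pats
        ]
        wins += np.mean(pos_scores) > np.mean(shuf_scores)
    assert wins >= 0.95 * reps


def test_profile_persistence_roundtrip(tmp_path, rng):
    pats = [P("".join(rng.choice(list("MXID"), size=10,
                                 p=[0.7, 0.2, 0.05, 0.05])))
            for _ in range(12)]
    profs = build_profiles(pats, min_support=1)
    path = tmp_path / "profiles.json"
    save_profiles(profs, path)
    loaded = load_profiles(path)
    assert sorted(loaded) == sorted(profs)
    for L in profs:
        for fam in profs[L].subprofiles:
            np.testing.assert_array_equal(
                loaded[L].subprofiles[fam], profs[L].subprofiles[fam]
            )
        assert loaded[L].training_support == profs[L].training_support
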