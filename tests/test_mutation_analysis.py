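"""Mutation enrichment score and Mann-Whitney classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutprop.library_design import IdrRegion, VariantRecord, tile_region
from mutprop.mutation_analysis import (
    DIRECTION_DIMINISHING,
    DIRECTION_ENHANCING,
    DIRECTION_NEUTRAL,
    PairObservation,
    classify,
    collapse_pairs,
    enrichment_score,
    individual_pair_significance,
    mw_test,
    mw_test_vectors,
)


def obs(pairs):
    return [PairObservation(w, m, i, "r1") for i, (w, m) in enumerate(pairs)]


class TestEnrichmentScore:
    @pytest.mark.parametrize("counts,expected", [
        ([(0, 5)], 1.0),
        ([(3, 3)], 0.0),
        ([(10, 0), (8, 0), (2, 0)], -3.0),
    ])
    def test_examples(self, counts, expected):
        assert enrichment_score(obs(counts)) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            enrichment_score([])

    def test_zero_zero_observation_rejected(self):
        with pytest.raises(ValueError):
            PairObservation(0.0, 0.0, 1, "r1")

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(0, 10_000)),
                    min_size=1, max_size=12))
    def test_bounded_and_antisymmetric(self, counts):
        counts = [(float(w), float(m)) for w, m in counts if w + m > 0]
        if not counts:
            return
        s = enrichment_score(obs(counts))
        assert abs(s) <= len(counts) + 1e-9
        swapped = enrichment_score(obs([(m, w) for w, m in counts]))
        assert swapped == pytest.approx(-s)
        one_sided = all(w == 0 or m == 0 for w, m in counts)
        assert (abs(s) == pytest.approx(len(counts))) == one_sided

    def test_scale_invariance_within_replicate(self):
        counts = [(3.0, 9.0), (5.0, 1.0), (2.0, 2.0)]
        scaled = [(w * 7.3, m * 7.3) for w, m in counts]
        assert enrichment_score(obs(scaled)) == pytest.approx(enrichment_score(obs(counts)))


def brute_force_mw_p(x, y):
    """Exhaustive relabeling oracle for the two-sided Mann-Whitney test."""
    pooled = list(x) + list(y)
    n, total = len(x), len(x) + len(y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(total), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(total) if i not in chosen]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestMannWhitney:
    def test_perfect_separation_three_vs_three(self):
        # 2 of C(6,3)=20 labelings are as extreme -> p = 0.1
        assert mw_test(obs([(1, 10), (2, 11), (3, 12)])) == pytest.approx(0.1)

    def test_identical_vectors_give_p_one(self):
        assert mw_test(obs([(5, 5), (5, 5)])) == 1.0

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 5))
            m = int(rng.integers(1, 5))
            vals = rng.permutation(1000)[: n + m].astype(float)
            x, y = list(vals[:n]), list(vals[n:])
            assert mw_test_vectors(np.array(x), np.array(y)) == pytest.approx(
                brute_force_mw_p(x, y), abs=1e-12
            )

    def test_swap_preserves_p(self):
        pairs = [(1.0, 9.0), (4.0, 2.0), (3.0, 8.0), (7.0, 5.0)]
        assert mw_test(obs(pairs)) == pytest.approx(mw_test(obs([(m, w) for w, m in pairs])))


class TestClassify:
    @pytest.mark.parametrize("score,p,expected", [
        (-16.0, 7.8e-8, DIRECTION_DIMINISHING),
        (12.0, 9.6e-7, DIRECTION_ENHANCING),
        (3.0, 0.05, DIRECTION_NEUTRAL),
    ])
    def test_direction_calls(self, score, p, expected):
        assert classify(score, p, p_cutoff=0.001) == expected


class TestCollapse:
    @staticmethod
    def _designs():
        seq = "MKLVDEAGHTWSNQRFYPIMKLV"  # 23 residues -> windows 1,5 (+anchor 8 unused)
        region = IdrRegion("P1", 1, 23, seq)
        return tile_region(region, [VariantRecord("P1", 8, "G", "W")])

    def test_counts_all_windows_and_replicates(self):
        designs = self._designs()
        assert len(designs) == 2
        rows = []
        for d in designs:
            for rep in ("r1", "r2", "r3"):
                rows.append({"peptide": d.wt_peptide, rep: 10.0})
                rows.append({"peptide": d.mut_peptide, rep: 6.0})
        merged = pd.DataFrame(rows).groupby("peptide").max().fillna(0.0)
        collapsed = collapse_pairs(merged, designs)
        assert list(collapsed) == [("P1", "G8W")]
        assert len(collapsed[("P1", "G8W")]) == 6  # 2 windows x 3 replicates

    def test_one_sided_presence_retained_and_absent_dropped(self):
        designs = self._designs()[:1]
        d = designs[0]
        merged = pd.DataFrame(
            {"peptide": [d.wt_peptide, d.mut_peptide], "r1": [12.0, 0.0], "r2": [0.0, 0.0]}
        ).set_index("peptide")
        observations = collapse_pairs(merged, designs)[("P1", "G8W")]
        assert len(observations) == 1
        assert (observations[0].nc_wt, observations[0].nc_mut) == (12.0, 0.0)


class TestIndividualPairs:
    def test_perfectly_separated_window_counted(self):
        window_obs = [PairObservation(10.0 + i, 100.0 + i, 1, f"r{i}") for i in range(4)]
        assert individual_pair_significance(window_obs) == 1

    def test_all_tied_windows_give_zero(self):
        window_obs = [PairObservation(5.0, 5.0, w, f"r{i}") for w in (1, 2) for i in range(4)]
        assert individual_pair_significance(window_obs) == 0

    def test_single_planted_window_in_mixture(self):
        planted = [PairObservation(100.0 + i, 2.0 + i, 1, f"r{i}") for i in range(4)]
        flat = [PairObservation(7.0, 7.0, 2, f"r{i}") for i in range(4)]
        assert individual_pair_significance(planted + flat) == 1

    def test_single_replicate_window_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert individual_pair_significance([PairObservation(9.0, 1.0, 1, "r1")]) == 0
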