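"""E.C.-averaged WD, personalized/uniform selection and the paired Wilcoxon test."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from pedalbci import benchmarks
from pedalbci.errors import ValidationError
from pedalbci.metrics import round_half_away
from pedalbci.montage import DEFAULT_CONFIG_SIZES
from pedalbci.selection import (
    WDMatrix,
    compare_paired_wd,
    ec_averaged_wd,
    select_personalized,
    select_uniform_algorithm,
    select_uniform_configuration,
)


def _random_matrix(rng, subject="SX", algorithms="ABCDE"):
    values = pd.DataFrame(
        rng.uniform(-1, 1, (8, len(algorithms))),
        index=range(1, 9),
        columns=list(algorithms),
    )
    return WDMatrix(subject, "offline", "4s", values)


class TestEcAveragedWd:
    def test_reproduces_published_column_average(self):
        avg = ec_averaged_wd(benchmarks.offline_matrix("S2"))
        assert round_half_away(avg["E"], 2) == 0.73

    def test_constant_matrix(self):
        m = WDMatrix("S", "offline", "4s", pd.DataFrame(0.4, index=range(1, 9), columns=list("ABC")))
        assert (ec_averaged_wd(m) == 0.4).all()

    def test_matches_brute_force_mean(self, rng):
        m = _random_matrix(rng)
        avg = ec_averaged_wd(m)
        for alg in "ABCDE":
            assert avg[alg] == pytest.approx(sum(m.values[alg]) / 8)


class TestSelectPersonalized:
    @pytest.mark.parametrize(
        "subject,algorithm,config",
        [("S1", "D", 4), ("S2", "E", 6), ("S3", "D", 1), ("S5", "A", 1)],
    )
    def test_reproduces_published_offline_picks(self, subject, algorithm, config):
        pick = select_personalized(benchmarks.offline_matrix(subject), DEFAULT_CONFIG_SIZES)
        assert (pick.algorithm, pick.config_id) == (algorithm, config)

    def test_subject4_offline_resolves_to_documented_tie(self):
        pick = select_personalized(
            benchmarks.offline_matrix("S4"),
            DEFAULT_CONFIG_SIZES,
            rng=np.random.default_rng(0),
        )
        assert pick.algorithm == "C"
        assert pick.config_id in (3, 4)
        assert pick.tie_broken_randomly
        assert (3, "C", 0.61) in pick.preselected and (4, "C", 0.61) in pick.preselected

    @pytest.mark.parametrize(
        "subject,algorithm,config",
        [("S1", "D", 4), ("S2", "B", 8), ("S3", "D", 2), ("S4", "C", 2), ("S5", "E", 4)],
    )
    def test_reproduces_published_pseudo_online_picks(self, subject, algorithm, config):
        pick = select_personalized(
            benchmarks.pseudo_online_matrix(subject), DEFAULT_CONFIG_SIZES
        )
        assert (pick.algorithm, pick.config_id) == (algorithm, config)

    def test_strictly_dominant_cell_always_wins(self, rng):
        values = pd.DataFrame(0.1, index=range(1, 9), columns=list("ABCDE"))
        values.loc[7, "B"] = 0.9
        pick = select_personalized(
            WDMatrix("S", "offline", "4s", values), DEFAULT_CONFIG_SIZES
        )
        assert (pick.algorithm, pick.config_id) == ("B", 7)

    def test_incomplete_size_table_rejected(self):
        with pytest.raises(ValidationError):
            select_personalized(benchmarks.offline_matrix("S1"), {1: 9})

    def test_personalized_not_worse_than_uniform_within_tolerance(self, rng):
        # valid whenever the uniform algorithm is among the subject's best two
        for _ in range(50):
            matrices = [_random_matrix(rng, f"S{i}") for i in range(3)]
            uni_alg = select_uniform_algorithm(matrices)
            uni_cfg = select_uniform_configuration(matrices, uni_alg)
            for m in matrices:
                pick = select_personalized(m, DEFAULT_CONFIG_SIZES)
                if uni_alg in pick.best_two_algorithms:
                    uniform_wd = float(m.values.loc[uni_cfg, uni_alg])
                    assert pick.wd >= uniform_wd - 0.01 - 1e-12


class TestUniformSelection:
    def test_single_subject_reduces_to_own_best(self, rng):
        m = _random_matrix(rng)
        assert select_uniform_algorithm([m]) == ec_averaged_wd(m).idxmax()

    def test_all_equal_ties_to_first_column(self):
        m = WDMatrix("S", "offline", "4s", pd.DataFrame(0.2, index=range(1, 9), columns=list("ABC")))
        assert select_uniform_algorithm([m]) == "A"

    def test_uniform_configuration_is_column_argmax(self, rng):
        m = _random_matrix(rng)
        assert select_uniform_configuration([m], "C") == int(m.values["C"].idxmax())

    def test_subject_order_irrelevant(self, rng):
        matrices = [_random_matrix(rng, f"S{i}") for i in range(4)]
        alg = select_uniform_algorithm(matrices)
        assert select_uniform_algorithm(matrices[::-1]) == alg
        assert select_uniform_configuration(matrices[::-1], alg) == select_uniform_configuration(
            matrices, alg
        )


class TestComparePairedWd:
    def test_identical_samples_give_p_one(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert compare_paired_wd(vals, vals)[1] == 1.0

    def test_exact_p_matches_sign_enumeration(self):
        a = [1, 2, 3, 4, 5, 6]
        b = [2, 3, 4, 5, 6, 7]
        _, p = compare_paired_wd(a, b)
        # oracle: enumerate all 2^6 sign assignments of tied |d| ranks
        ranks = np.full(6, 3.5)
        w_obs = 0.0  # all differences negative -> W+ = 0
        null = []
        for signs in product([0, 1], repeat=6):
            null.append(sum(r for s, r in zip(signs, ranks) if s))
        null = np.array(null)
        total = np.sum(ranks)
        p_oracle = (np.mean(null <= w_obs) + np.mean(null >= total - w_obs))
        assert p == pytest.approx(p_oracle)

    def test_symmetric_in_arguments(self, rng):
        a = rng.uniform(0, 1, 12).tolist()
        b = rng.uniform(0, 1, 12).tolist()
        assert compare_paired_wd(a, b)[1] == pytest.approx(compare_paired_wd(b, a)[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_paired_wd([1, 2, 3, 4, 5], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            compare_paired_wd([1, 2], [2, 3])
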