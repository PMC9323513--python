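"""Agreement analytics: pairwise statistics, stratification, grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sced import (
    RaterModel,
    RatingPanel,
    SynthConfig,
    cohens_kappa,
    generate_dataset,
    kappa_interpretation,
    majority_groups,
    mean_pairwise_agreement,
    percent_agreement,
    phase_length_table,
    simulate_panel,
    spearman_rho,
    stratified_agreement,
)

from conftest import make_graph

binary_seq = st.lists(st.integers(0, 1), min_size=1, max_size=40)


def panel_from_labels(label_rows, scores=None):
    """Rows = graphs, columns = raters."""
    arr = np.asarray(label_rows)
    names = [f"r{j}" for j in range(arr.shape[1])]
    labels = {n: arr[:, j] for j, n in enumerate(names)}
    if scores is None:
        scores = {n: np.where(arr[:, j] == 1, 8.0, 2.0) for j, n in enumerate(names)}
    ids = [f"g{i}" for i in range(arr.shape[0])]
    return RatingPanel.from_arrays(ids, labels, scores)


class TestPairwiseStatistics:
    def test_percent_agreement_examples(self):
        assert percent_agreement([1, 1, 0, 0], [1, 0, 0, 0]) == 0.75
        assert percent_agreement([1, 0, 1], [1, 0, 1]) == 1.0

    def test_kappa_perfect_and_chance_level(self):
        assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0
        # one rater constant, the other half yes: observed = expected = 0.5
        assert cohens_kappa([1, 1, 1, 1], [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_kappa_hand_computed_table(self):
        """2x2 table 70/10/5/15: p_o = .85, p_e = .65, kappa = .5714."""
        a = [1] * 80 + [0] * 20
        b = [1] * 70 + [0] * 10 + [1] * 5 + [0] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.5714, abs=5e-5)

    def test_kappa_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            if len(set(a)) == 1 and len(set(b)) == 1:
                continue
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_both_constant_identical_is_perfect(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    @given(binary_seq, binary_seq)
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_and_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert percent_agreement(a, b) == percent_agreement(b, a)
        k = cohens_kappa(a, b)
        assert k == pytest.approx(cohens_kappa(b, a))
        assert -1.0 <= k <= 1.0 + 1e-12

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            percent_agreement([1], [1, 0])
        with pytest.raises(ValueError, match="empty"):
            cohens_kappa([], [])


class TestKappaInterpretation:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.66, "substantial"),
            (0.10, "slight"),
            (0.20, "slight"),
            (0.205, "fair"),
            (0.21, "fair"),
            (0.50, "moderate"),
            (0.95, "almost perfect"),
            (-0.2, "poor (below chance)"),
        ],
    )
    def test_bands(self, kappa, band):
        assert kappa_interpretation(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_interpretation(1.5)


class TestSpearmanRho:
    def test_monotone_and_antitone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_tied_ranks(self):
        assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(
            0.9487, abs=5e-5
        )

    def test_constant_input_is_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=3, max_size=20, unique=True
        )
    )
    @settings(derandomize=True, max_examples=40)
    def test_invariance_to_increasing_transform(self, xs):
        ys = list(reversed(xs))
        base = spearman_rho(xs, ys)
        transformed = spearman_rho([math.atan(x / 50) for x in xs], ys)
        assert transformed == pytest.approx(base, abs=1e-9)


class TestPanelSimulationAgreement:
    def test_error_free_panel_agrees_perfectly(self, rng):
        graphs, labels = generate_dataset(200, SynthConfig(seed=1, effect_prob=0.4))
        panel = simulate_panel(graphs, labels, [RaterModel(0.0, 0.0)] * 5, rng)
        stats = mean_pairwise_agreement(panel)
        assert stats["mean_proportion"] == 1.0
        assert stats["mean_kappa"] == 1.0
        assert stats["n_pairs"] == 10

    def test_symmetric_error_matches_closed_form(self, rng):
        """Two raters flipping truth independently with rate eps agree
        with probability eps^2 + (1-eps)^2."""
        eps = 0.1
        n = 1000
        graphs, labels = generate_dataset(n, SynthConfig(seed=2, effect_prob=0.5))
        panel = simulate_panel(graphs, labels, [RaterModel(eps, eps)] * 2, rng)
        expected = eps**2 + (1 - eps) ** 2
        se = math.sqrt(expected * (1 - expected) / n)
        observed = percent_agreement(
            panel.labels.iloc[:, 0], panel.labels.iloc[:, 1]
        )
        assert abs(observed - expected) <= 3 * se


class TestStratifiedAgreement:
    def test_perfect_panel_is_perfect_in_both_strata(self):
        method = [1, 1, 0, 0, 1, 0]
        panel = panel_from_labels([[m] * 3 for m in method])
        df = stratified_agreement(method, panel)
        assert (df["effect"] == 1.0).all()
        assert (df["no_effect"] == 1.0).all()

    def test_panel_agreeing_only_on_null_graphs(self):
        method = [1, 1, 0, 0]
        ratings = [[0, 0], [0, 0], [0, 0], [0, 0]]  # raters always say no
        panel = panel_from_labels(ratings)
        df = stratified_agreement(method, panel)
        assert (df.loc[panel.rater_names, "effect"] == 0.0).all()
        assert (df.loc[panel.rater_names, "no_effect"] == 1.0).all()

    def test_symmetric_error_lands_near_both_strata(self, rng):
        graphs, labels = generate_dataset(1500, SynthConfig(seed=6, effect_prob=0.5))
        panel = simulate_panel(graphs, labels, [RaterModel(0.1, 0.1)] * 3, rng)
        df = stratified_agreement(np.asarray(labels).astype(int), panel)
        means = df.loc["mean"]
        assert means["effect"] == pytest.approx(0.9, abs=0.05)
        assert means["no_effect"] == pytest.approx(0.9, abs=0.05)

    def test_empty_stratum_is_undefined(self):
        method = [0, 0, 0]
        panel = panel_from_labels([[0, 0], [0, 0], [1, 1]])
        df = stratified_agreement(method, panel)
        assert df["effect"].isna().all()
        assert df["no_effect"].notna().all()


class TestMajorityGroups:
    def test_four_of_five_consensus(self):
        panel = panel_from_labels([[1, 1, 1, 1, 0], [1, 1, 1, 0, 0]])
        groups = majority_groups(panel, cdc=[1, 0], svc=[1, 0], k=4)
        assert groups.visual_agreement == ("g0",)
        assert groups.visual_disagreement == ("g1",)
        assert groups.majority_label["g0"] == 1

    def test_method_disagreement_within_consensus(self):
        panel = panel_from_labels([[1, 1, 1, 1, 1], [0, 0, 0, 0, 1]])
        groups = majority_groups(panel, cdc=[0, 0], svc=[1, 1], k=4)
        assert groups.cdc_disagree == ("g0",)  # majority 1, cdc said 0
        assert groups.svc_disagree == ("g1",)  # majority 0, svc said 1

    def test_groups_cover_every_graph_once(self, rng):
        graphs, labels = generate_dataset(300, SynthConfig(seed=8, effect_prob=0.4))
        panel = simulate_panel(graphs, labels, [RaterModel(0.15, 0.15)] * 5, rng)
        decisions = rng.integers(0, 2, 300)
        groups = majority_groups(panel, decisions, decisions, k=4)
        combined = sorted(groups.visual_agreement + groups.visual_disagreement)
        assert combined == sorted(panel.labels.index)
        assert set(groups.cdc_disagree) <= set(groups.visual_agreement)
        assert set(groups.svc_disagree) <= set(groups.visual_agreement)

    def test_even_panel_split_is_flagged(self):
        panel = panel_from_labels([[1, 1, 0, 0]])
        groups = majority_groups(panel, [1], [1], k=3)
        assert groups.no_majority == ("g0",)
        assert groups.visual_agreement == ()

    def test_k_must_define_a_majority(self):
        panel = panel_from_labels([[1, 1, 0, 0]])
        with pytest.raises(ValueError, match="majority"):
            majority_groups(panel, [1], [1], k=2)


class TestPhaseLengthTable:
    def _graphs(self, a_lengths, b_len=5):
        return [
            make_graph(list(range(n)), list(range(b_len)), id=f"g{i}")
            for i, n in enumerate(a_lengths)
        ]

    def test_direct_binning(self):
        graphs = self._graphs([3, 3, 4, 12])
        panel = panel_from_labels([[1, 1, 1]] * 4)
        groups = majority_groups(panel, [1] * 4, [1] * 4, k=3)
        table = phase_length_table(groups, graphs)
        row = table.loc[("A", "visual_agreement")]
        np.testing.assert_allclose(row.to_numpy(), [0.50, 0.25, 0.0, 0.25])

    def test_rows_of_nonempty_groups_sum_to_one(self, rng):
        graphs, labels = generate_dataset(200, SynthConfig(seed=9, effect_prob=0.4))
        panel = simulate_panel(graphs, labels, [RaterModel(0.1, 0.1)] * 5, rng)
        truth = np.asarray(labels).astype(int)
        groups = majority_groups(panel, truth, truth, k=4)
        table = phase_length_table(groups, graphs)
        sums = table.sum(axis=1, skipna=False)
        for value in sums.dropna():
            assert value == pytest.approx(1.0)

    def test_empty_group_is_undefined(self):
        graphs = self._graphs([3, 4])
        panel = panel_from_labels([[1, 1, 1], [1, 1, 1]])
        groups = majority_groups(panel, [1, 1], [1, 1], k=3)
        table = phase_length_table(groups, graphs)
        assert table.loc[("A", "visual_disagreement")].isna().all()
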