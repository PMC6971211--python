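import numpy as np
import pytest
from scipy import stats

from connlearn.connectome import Connectome
from connlearn.edge_filtering import edge_anova, percentile_filter, report_frame
from connlearn.synthetic import edge_effect_cohort
from connlearn.atlas import load_atlas


def _conns(weight_stacks, run):
    out = []
    for s, W in enumerate(weight_stacks):
        out.append(Connectome(weights=W, meta={"subject_id": f"s{s}", "run": run}))
    return out


def _random_symmetric(rng, n, loc=0.3, scale=0.1):
    W = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    W[iu] = rng.normal(loc, scale, size=len(iu[0]))
    return W + W.T


class TestEdgeAnova:
    def test_identical_runs_give_null_f(self):
        rng = np.random.default_rng(0)
        W = [_random_symmetric(rng, 6) for _ in range(4)]
        rep = edge_anova(_conns(W, 1), _conns(W, 2))
        assert (rep.table["F"] == 0).all()
        assert (rep.table["p"] == 1).all()

    def test_constant_edges_flagged_degenerate(self):
        base = _random_symmetric(np.random.default_rng(1), 5)
        rep = edge_anova(_conns([base] * 3, 1), _conns([base] * 3, 2))
        assert rep.table["degenerate"].all()
        assert (rep.table["p"] == 1).all() and (rep.table["tukey_p"] == 1).all()

    def test_matches_closed_form_anova_on_one_edge(self):
        rng = np.random.default_rng(1)
        a = [_random_symmetric(rng, 4) for _ in range(6)]
        b = [_random_symmetric(rng, 4) for _ in range(6)]
        for W in b:
            W[0, 1] += 1.0
            W[1, 0] += 1.0
        rep = edge_anova(_conns(a, 1), _conns(b, 2))
        row = rep.table[(rep.table.roi_i == 1) & (rep.table.roi_j == 2)].iloc[0]
        x = np.array([W[0, 1] for W in a])
        y = np.array([W[0, 1] for W in b])
        f_ref, p_ref = stats.f_oneway(x, y)
        assert row["F"] == pytest.approx(f_ref, abs=1e-10)
        assert row["p"] == pytest.approx(p_ref, abs=1e-10)
        assert row["p"] < 0.05

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a = [_random_symmetric(rng, 5) for _ in range(8)]
        b = [_random_symmetric(rng, 5) for _ in range(8)]
        rep = edge_anova(_conns(a, 1), _conns(b, 2))
        x = np.stack([W[np.triu_indices(5, 1)] for W in a])
        y = np.stack([W[np.triu_indices(5, 1)] for W in b])
        t, p_t = stats.ttest_ind(y, x, axis=0)
        assert np.allclose(rep.table["F"], t**2, atol=1e-10)
        assert np.allclose(rep.table["p"], p_t, atol=1e-10)
        # Tukey with two groups collapses to the pooled t test
        assert np.allclose(rep.table["tukey_p"], p_t, atol=1e-7)

    def test_needs_two_subjects_per_run(self):
        rng = np.random.default_rng(3)
        W = [_random_symmetric(rng, 4)]
        with pytest.raises(ValueError):
            edge_anova(_conns(W, 1), _conns(W, 2))


class TestPercentileFilter:
    def test_null_cohort_selects_almost_nothing(self):
        rng = np.random.default_rng(4)
        a = [_random_symmetric(rng, 12) for _ in range(10)]
        b = [_random_symmetric(rng, 12) for _ in range(10)]
        rep = percentile_filter(edge_anova(_conns(a, 1), _conns(b, 2)))
        m = len(rep.table)
        selected = len(rep.selected_positive) + len(rep.selected_negative)
        # each tail selects edges that are both beyond the 5% percentile and
        # Tukey-significant (~2% per side under the null); binomial slack
        bound = 0.05 * m + 3 * np.sqrt(0.05 * m * 0.95)
        assert selected <= bound

    def test_planted_edges_recovered(self):
        run1, run2, pos, neg = edge_effect_cohort(effect_sd=4.0, seed=5)
        rep = percentile_filter(edge_anova(run1, run2))
        assert set(pos) <= set(rep.selected_positive)
        assert set(neg) <= set(rep.selected_negative)

    def test_degenerate_distribution_selects_nothing(self):
        rng = np.random.default_rng(6)
        base = _random_symmetric(rng, 5)
        rep = percentile_filter(edge_anova(_conns([base] * 4, 1), _conns([base] * 4, 2)))
        assert rep.selected_positive == [] and rep.selected_negative == []

    def test_sign_consistency_and_disjointness(self):
        run1, run2, _, _ = edge_effect_cohort(effect_sd=2.0, seed=7)
        rep = percentile_filter(edge_anova(run1, run2))
        table = rep.table.set_index(["roi_i", "roi_j"])
        for i, j in rep.selected_positive:
            assert table.loc[(i + 1, j + 1), "diff"] > 0
            assert table.loc[(i + 1, j + 1), "tukey_p"] < rep.alpha
        for i, j in rep.selected_negative:
            assert table.loc[(i + 1, j + 1), "diff"] < 0
        assert not set(rep.selected_positive) & set(rep.selected_negative)


def test_planted_precision_recall():
    """Mean recovery of 4 strengthened + 3 weakened edges at a 1.5-SD effect."""
    precisions, recalls = [], []
    for seed in range(5):
        run1, run2, pos, neg = edge_effect_cohort(seed=seed)
        rep = percentile_filter(edge_anova(run1, run2))
        tp = len(set(rep.selected_positive) & set(pos)) + len(set(rep.selected_negative) & set(neg))
        selected = len(rep.selected_positive) + len(rep.selected_negative)
        precisions.append(tp / selected if selected else 0.0)
        recalls.append(tp / (len(pos) + len(neg)))
    assert np.mean(precisions) >= 0.8
    assert np.mean(recalls) >= 0.8


def test_report_frame_with_atlas_names():
    run1, run2, _, _ = edge_effect_cohort(n_rois=10, seed=8)
    rep = percentile_filter(edge_anova(run1, run2))
    frame = report_frame(rep, atlas=load_atlas("FSL"))
    assert {"name_i", "name_j", "selected"} <= set(frame.columns)
    assert frame.loc[0, "name_i"] == "Frontal Pole Right"
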