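"""mRMR ranking and 0.632+ bootstrap AUC selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voiradiomics as vr
from voiradiomics.selection import combine_632plus, mutual_information_bits


def make_table(rng, n=60):
    labels = np.repeat([0, 1], n // 2)
    df = pd.DataFrame({
        "strong": labels + 0.3 * rng.normal(size=n),
        "weak": 0.5 * labels + 1.2 * rng.normal(size=n),
        "noise1": rng.normal(size=n),
        "noise2": rng.normal(size=n),
    })
    return df, labels


class TestMrmr:
    def test_label_copy_ranked_first(self, rng):
        df, labels = make_table(rng)
        df["oracle"] = labels.astype(float)
        order = vr.mrmr_rank(df, labels, m=3)
        assert order[0] == "oracle"

    def test_redundant_copy_demoted(self, rng):
        """With {A, copy-of-A, B}: A first (most relevant), then B
        (independent), the copy last — redundancy outweighs relevance."""
        n = 30
        labels = np.repeat([0, 1], n // 2)
        a = labels + 0.2 * rng.normal(size=n)
        b = 0.7 * labels + 1.0 * rng.normal(size=n)
        df = pd.DataFrame({"A": a, "A_copy": a.copy(), "B": b})
        order = vr.mrmr_rank(df, labels, m=3)
        assert order == ["A", "B", "A_copy"]

    def test_permuted_labels_have_near_zero_relevance(self, rng):
        n = 200
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        x = rng.normal(size=n)
        from voiradiomics.selection import _discretize_3level
        mi = mutual_information_bits(_discretize_3level(x), labels)
        assert mi < 0.05

    def test_fewer_features_than_requested_warns(self, rng):
        df, labels = make_table(rng)
        with pytest.warns(UserWarning, match="available"):
            order = vr.mrmr_rank(df, labels, m=100)
        assert len(order) == 4


class TestBootstrap632Plus:
    def test_no_overfitting_fixed_point(self):
        """AUC_app == AUC_boot == 0.8 -> R = 0, w = 0.632, estimate 0.8."""
        assert combine_632plus(0.8, 0.8) == pytest.approx(0.8)

    def test_maximal_overfitting(self):
        """AUC_app 0.9, AUC_boot 0.5 -> R = 1, w = 1, estimate 0.5."""
        assert combine_632plus(0.9, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("app,boot", [(0.9, 0.7), (0.7, 0.75), (0.55, 0.4),
                                          (0.45, 0.3), (1.0, 0.5)])
    def test_estimate_is_convex_combination(self, app, boot):
        est = combine_632plus(app, boot)
        prime = max(boot, 0.5)
        assert min(prime, app) - 1e-12 <= est <= max(prime, app) + 1e-12

    @given(app=st.floats(0.0, 1.0), boot=st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_estimate_bounded_for_all_auc_pairs(self, app, boot):
        """For any apparent/bootstrap AUC pair the 0.632+ estimate stays
        between the apparent AUC and max(bootstrap AUC, 0.5)."""
        est = combine_632plus(app, boot)
        prime = max(boot, 0.5)
        assert min(prime, app) - 1e-9 <= est <= max(prime, app) + 1e-9

    def test_separable_subset_scores_high(self, rng):
        df, labels = make_table(rng)
        cfg = vr.SelectionConfig(shortlist_size=4, final_size=2, n_bootstrap=100, seed=3)
        score = vr.bootstrap_auc_632plus(df[["strong"]].to_numpy(), labels, cfg)
        assert score > 0.9

    def test_label_independent_feature_near_half(self, rng):
        n = 200
        labels = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 1))
        cfg = vr.SelectionConfig(shortlist_size=1, final_size=1, n_bootstrap=200, seed=4)
        score = vr.bootstrap_auc_632plus(x, labels, cfg)
        assert 0.45 <= score <= 0.6


class TestRankTopFeatures:
    def test_perfect_feature_chosen_first_with_high_score(self, rng):
        df, labels = make_table(rng)
        df["perfect"] = labels * 10.0
        cfg = vr.SelectionConfig(shortlist_size=5, final_size=2, n_bootstrap=100, seed=1)
        res = vr.rank_top_features(list(df.columns), df, labels, cfg)
        assert res.ranked[0] == "perfect"
        assert res.step_scores[0] > 0.95

    @pytest.mark.parametrize("mode", ["stepwise", "univariate"])
    def test_same_seed_reproduces_result(self, mode, rng):
        df, labels = make_table(rng)
        cfg = vr.SelectionConfig(shortlist_size=4, final_size=3, n_bootstrap=60,
                                 ranking_mode=mode, seed=9)
        a = vr.rank_top_features(list(df.columns), df, labels, cfg)
        b = vr.rank_top_features(list(df.columns), df, labels, cfg)
        assert a.ranked == b.ranked
        assert a.step_scores == b.step_scores

    def test_permuted_labels_scores_near_half(self, rng):
        n = 200
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        df = pd.DataFrame(rng.normal(size=(n, 6)),
                          columns=[f"f{i}" for i in range(6)])
        cfg = vr.SelectionConfig(shortlist_size=6, final_size=3, n_bootstrap=200,
                                 ranking_mode="univariate", seed=2)
        res = vr.rank_top_features(list(df.columns), df, labels, cfg)
        assert all(s <= 0.58 for s in res.step_scores)

    def test_ranked_subset_of_shortlist_and_overlap_metric(self, rng):
        df, labels = make_table(rng)
        cfg = vr.SelectionConfig(shortlist_size=4, final_size=2, n_bootstrap=60, seed=5)
        res = vr.rank_top_features(list(df.columns), df, labels, cfg)
        assert set(res.ranked) <= set(res.shortlist)
        assert res.overlap_with(res) == 1.0
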