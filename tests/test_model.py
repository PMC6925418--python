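"""Incremental random-forest modeling, evaluation and transfer."""

import numpy as np
import pandas as pd
import pytest

import voiradiomics as vr


def feature_table(rng, n=60, n_noise=6, effect=2.0, val_frac=0.25):
    labels = np.repeat([0, 1], n // 2)
    cols = {"informative": effect * labels + rng.normal(size=n)}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(size=n)
    df = pd.DataFrame(cols, index=[f"s{i:03d}" for i in range(n)])
    df["label"] = labels
    split = np.array(["training"] * n, dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        split[rng.choice(idx, size=int(val_frac * len(idx)), replace=False)] = "validation"
    df["split"] = split
    return df


def small_cfg(seed, final=4):
    return vr.SelectionConfig(shortlist_size=7, final_size=final, n_bootstrap=60,
                              ranking_mode="univariate", seed=seed)


def test_single_informative_feature_keeps_k_small(rng):
    """When only one feature carries signal the CV trace is ~flat in k and
    the chosen model stays parsimonious."""
    chosen = []
    for seed in range(3):
        r = np.random.default_rng(seed)
        df = feature_table(r)
        res = vr.RadiomicsModel.from_dataframe(
            df, selection=small_cfg(seed), spec=vr.ModelSpec(seed=seed)).fit()
        assert res.features[0] == "informative" or "informative" in res.features[:2]
        chosen.append(res.chosen_k)
    assert all(k <= 5 for k in chosen)


def test_permuted_labels_cv_aucs_near_half(rng):
    n = 200
    labels = np.asarray(np.repeat([0, 1], n // 2))
    df = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)],
                      index=[f"s{i}" for i in range(n)])
    df["label"] = rng.permutation(labels)
    df["split"] = "training"
    res = vr.RadiomicsModel.from_dataframe(
        df, selection=small_cfg(1, final=3), spec=vr.ModelSpec(seed=1)).fit()
    assert all(0.35 <= a <= 0.65 for a in res.cv_auc_trace)


def test_same_seed_reproduces_fit(rng):
    df = feature_table(rng)
    fits = [
        vr.RadiomicsModel.from_dataframe(df, selection=small_cfg(3),
                                         spec=vr.ModelSpec(seed=3)).fit()
        for _ in range(2)
    ]
    assert fits[0].chosen_k == fits[1].chosen_k
    assert fits[0].features == fits[1].features
    assert fits[0].cv_auc_trace == fits[1].cv_auc_trace


def test_evaluation_report_fields_consistent(rng):
    df = feature_table(rng, effect=3.0)
    res = vr.RadiomicsModel.from_dataframe(
        df, selection=small_cfg(5), spec=vr.ModelSpec(seed=5)).fit()
    val = df[df["split"] == "validation"]
    row = res.evaluate(val)
    assert 0 <= row.ci_low <= row.auc <= row.ci_high <= 1
    assert all(0 <= v <= 1 for v in (row.sensitivity, row.specificity, row.accuracy))
    assert row.k == res.chosen_k == len(res.features)
    # strong effect: the model should clearly beat chance on held-out data
    assert row.auc > 0.8


def test_one_class_validation_rejected(rng):
    df = feature_table(rng)
    res = vr.RadiomicsModel.from_dataframe(
        df, selection=small_cfg(7), spec=vr.ModelSpec(seed=7)).fit()
    val = df[(df["split"] == "validation") & (df["label"] == 1)]
    with pytest.raises(ValueError, match="both classes"):
        res.evaluate(val)


def test_summary_mentions_key_quantities(rng):
    df = feature_table(rng)
    res = vr.RadiomicsModel.from_dataframe(
        df, selection=small_cfg(11), spec=vr.ModelSpec(seed=11)).fit()
    text = res.summary()
    assert "chosen k" in text and "150 trees" in text
    assert res.features[0] in text


def test_transfer_matrix_diagonal_matches_evaluation(rng):
    """The transfer matrix diagonal equals each model's own validation AUC;
    shape is variants x variants."""
    tables = {v: feature_table(np.random.default_rng(i), effect=2.5)
              for i, v in enumerate(["baseline", "erosion", "dilation3"])}
    results = vr.fit_variant_models(tables, selection=small_cfg(2),
                                    spec=vr.ModelSpec(seed=2))
    val_tables = {v: t[t["split"] == "validation"] for v, t in tables.items()}
    mat = vr.transfer_matrix(results, val_tables)
    assert mat.shape == (3, 3)
    for v in tables:
        own = results[v].evaluate(val_tables[v])
        assert mat.loc[v, v] == pytest.approx(own.auc)
    assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()


def test_transfer_requires_matching_feature_schema(rng):
    tables = {v: feature_table(np.random.default_rng(3), effect=2.5)
              for v in ["baseline", "erosion"]}
    results = vr.fit_variant_models(tables, selection=small_cfg(4),
                                    spec=vr.ModelSpec(seed=4))
    broken = tables["erosion"].drop(columns=[results["baseline"].features[0]])
    with pytest.raises(KeyError, match="lacks model features"):
        results["baseline"].predict_proba(broken)


def test_training_and_validation_subjects_disjoint(rng):
    """Fold hygiene: the fitted model only ever sees training-split subjects;
    validation ids never enter the design matrix."""
    df = feature_table(rng)
    model = vr.RadiomicsModel.from_dataframe(df)
    val_ids = set(df[df["split"] == "validation"].index)
    assert set(model.exog.index).isdisjoint(val_ids)
    assert len(model.exog) + len(val_ids) == len(df)


def test_tiny_cohort_reduces_folds_with_warning(rng):
    df = feature_table(rng, n=12, val_frac=0.0)
    with pytest.warns(UserWarning, match="reducing CV folds"):
        res = vr.RadiomicsModel.from_dataframe(
            df, selection=small_cfg(6, final=2), spec=vr.ModelSpec(seed=6)).fit()
    assert res.chosen_k >= 1
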