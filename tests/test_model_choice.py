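"""ABC-rf forest behaviour on toy reference tables and real simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from steppeabc import (
    build_model,
    build_reference_table,
    classification_error_by_pod,
    classify_observed,
    gof_projections,
    train_classifier,
)
from steppeabc.demography import PriorSpec
from steppeabc.model_choice import MODEL_COLUMN, ModelChoiceError, ReferenceTable


# ------------------------------------------------------------- toy tables
def separable_table(n_per_model=2000, seed=0, gap=2.0) -> ReferenceTable:
    """Two 'models' whose statistic distributions do not overlap."""
    rng = np.random.default_rng(seed)
    rows = []
    for m, lo in (("A", 0.0), ("B", 1.0 + gap)):
        s1 = rng.uniform(lo, lo + 1.0, n_per_model)
        s2 = rng.normal(lo, 0.3, n_per_model)
        for a, b in zip(s1, s2):
            rows.append({"model": m, "theta": rng.uniform(), "s1": a, "s2": b})
    df = pd.DataFrame(rows)
    return ReferenceTable(
        data=df, stat_columns=("s1", "s2"), param_columns=("theta",)
    )


def identical_table(n_per_model=2000, seed=1) -> ReferenceTable:
    """Two labels over one and the same generating distribution."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in ("A", "B"):
        for _ in range(n_per_model):
            rows.append(
                {"model": m, "theta": rng.uniform(), "s1": rng.normal(), "s2": rng.normal()}
            )
    df = pd.DataFrame(rows)
    return ReferenceTable(
        data=df, stat_columns=("s1", "s2"), param_columns=("theta",)
    )


# ------------------------------------------------------------ classifier
def test_separable_models_are_perfectly_classified():
    table = separable_table()
    forest = train_classifier(table, n_trees=500, seed=0)
    assert forest.prior_error_rate < 0.01
    obs = pd.Series({"s1": 0.5, "s2": 0.0})  # squarely inside model A
    res = classify_observed(forest, obs)
    assert res.selected_model == "A"
    assert res.votes["A"] >= 0.95 * 500
    assert res.posterior_probability >= 0.95
    assert sum(res.votes.values()) == 500


def test_training_row_is_assigned_to_its_own_model():
    table = separable_table(n_per_model=500)
    forest = train_classifier(table, n_trees=200, seed=3)
    row = table.data[table.data[MODEL_COLUMN] == "B"].iloc[7]
    res = classify_observed(forest, row)
    assert res.selected_model == "B"


def test_indistinguishable_models_sit_at_chance():
    table = identical_table()
    forest = train_classifier(table, n_trees=500, seed=2)
    assert abs(forest.prior_error_rate - 0.5) < 0.05
    obs = pd.Series({"s1": 0.1, "s2": -0.2})
    res = classify_observed(forest, obs)
    assert abs(res.posterior_probability - 0.5) <= 0.1


def test_single_tree_forest_warns():
    table = separable_table(n_per_model=100)
    with pytest.warns(UserWarning, match="n_trees=1"):
        forest = train_classifier(table, n_trees=1, seed=0)
    res = classify_observed(forest, pd.Series({"s1": 0.5, "s2": 0.0}))
    assert set(res.votes.values()) <= {0, 1}


def test_fewer_than_two_models_rejected():
    table = separable_table(n_per_model=50)
    only_a = table.restrict(["A"])
    with pytest.raises(ModelChoiceError, match=">= 2 models"):
        train_classifier(only_a, n_trees=10, seed=0)


def test_confusion_matrix_bookkeeping():
    table = separable_table(n_per_model=300)
    forest = train_classifier(table, n_trees=100, seed=5)
    report = classification_error_by_pod(forest)
    counts = forest.oob_valid.sum()
    assert report.confusion.to_numpy().sum() == counts
    # row sums equal the per-model POD counts that had OOB predictions
    for m in ("A", "B"):
        n_m = int(np.sum((forest.y == m) & forest.oob_valid))
        assert report.confusion.loc[m].sum() == n_m
    assert report.global_error < 0.05


def test_votes_invariant_to_table_row_order():
    table = separable_table(n_per_model=400, seed=9)
    shuffled = ReferenceTable(
        data=table.data.sample(frac=1.0, random_state=4).reset_index(drop=True),
        stat_columns=table.stat_columns,
        param_columns=table.param_columns,
    )
    obs = pd.Series({"s1": 0.4, "s2": 0.1})
    r1 = classify_observed(train_classifier(table, 100, seed=7), obs)
    r2 = classify_observed(train_classifier(shuffled, 100, seed=7), obs)
    assert r1.votes == r2.votes
    assert r1.posterior_probability == r2.posterior_probability


# -------------------------------------------------------- reference table
def test_reference_table_counts_and_determinism(default_cfg, tmp_path):
    priors = PriorSpec.from_config(default_cfg["priors"])
    models = [build_model(m, default_cfg) for m in default_cfg["models"]]
    t1 = build_reference_table(models, priors, 10, seed=0, locus=default_cfg["locus"])
    assert len(t1.data) == 50
    assert all((t1.data[MODEL_COLUMN] == m.name).sum() == 10 for m in models)
    # byte-identical export under the same seed
    t2 = build_reference_table(models, priors, 10, seed=0, locus=default_cfg["locus"])
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    t1.to_csv(p1)
    t2.to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()
    # no missing entries after imputation
    assert not t1.data[list(t1.stat_columns)].isna().any().any()


def test_reference_table_resumable_in_chunks(default_cfg):
    priors = PriorSpec.from_config(default_cfg["priors"])
    models = [build_model("NOMIG", default_cfg), build_model("MIG2", default_cfg)]
    full = build_reference_table(models, priors, 6, seed=3, locus=default_cfg["locus"])
    c1 = build_reference_table(models, priors, 6, seed=3, locus=default_cfg["locus"],
                               row_range=(0, 3))
    c2 = build_reference_table(models, priors, 6, seed=3, locus=default_cfg["locus"],
                               row_range=(3, 6))
    merged = pd.concat(
        [
            c1.rows_for_model(m.name).iloc[0:3].assign()
            for m in models
        ]
    )
    # chunk rows coincide with the corresponding full-table rows
    for m in models:
        got = pd.concat([c1.rows_for_model(m.name), c2.rows_for_model(m.name)])
        want = full.rows_for_model(m.name)
        assert np.allclose(
            got[list(full.stat_columns)].to_numpy(dtype=float),
            want[list(full.stat_columns)].to_numpy(dtype=float),
        )


def test_mig2_table_marginal_matches_prior(default_cfg):
    """The m2 marginal of MIG2 reference rows reproduces its uniform prior
    (KS p > 0.01); checked at table scale and at n = 10,000 on the draw
    stream that feeds the table."""
    from steppeabc.demography import sample_parameters

    priors = PriorSpec.from_config(default_cfg["priors"])
    model = build_model("MIG2", default_cfg)
    table = build_reference_table([model], priors, 2000, seed=8,
                                  locus=default_cfg["locus"])
    m2 = table.data["m2"].to_numpy()
    assert sps.kstest(m2, "uniform").pvalue > 0.01
    rng = np.random.default_rng(13)
    draws = np.array([sample_parameters(model, priors, rng)["m2"] for _ in range(10_000)])
    assert sps.kstest(draws, "uniform").pvalue > 0.01


# ------------------------------------------------------------ projections
def test_lda_separates_shifted_classes_with_sign_convention():
    table = separable_table(n_per_model=500, seed=21)
    obs = pd.Series({"s1": 0.5, "s2": 0.0})
    proj = gof_projections(table, obs)
    scores = proj.lda_rows
    mean_a = scores.loc[scores[MODEL_COLUMN] == "A", "LD1"].mean()
    mean_b = scores.loc[scores[MODEL_COLUMN] == "B", "LD1"].mean()
    assert mean_a < 0 < mean_b  # first-listed class on the negative side
    assert proj.lda_obs[0] < 0  # the observation lies with model A


def test_lda_axis_count_is_models_minus_one():
    rng = np.random.default_rng(33)
    rows = []
    for k, m in enumerate(("A", "B", "C")):
        for _ in range(300):
            rows.append(
                {
                    "model": m,
                    "s1": rng.normal(k, 1.0),
                    "s2": rng.normal(-k, 1.0),
                    "s3": rng.normal(0, 1.0),
                }
            )
    table = ReferenceTable(
        data=pd.DataFrame(rows), stat_columns=("s1", "s2", "s3"), param_columns=()
    )
    proj = gof_projections(table, pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0}))
    lda_cols = [c for c in proj.lda_rows.columns if c.startswith("LD")]
    assert len(lda_cols) == 2


def test_lda_axis_matches_generalized_eigenproblem():
    """The leading discriminant direction agrees with an independent dense
    solve of S_b v = lambda S_w v on the z-scored statistics."""
    from scipy.linalg import eigh

    table = separable_table(n_per_model=800, seed=55, gap=0.5)
    obs = pd.Series({"s1": 0.5, "s2": 0.0})
    proj = gof_projections(table, obs)
    axis = proj.lda_axes[0]
    axis = axis / np.linalg.norm(axis)

    X = table.data[["s1", "s2"]].to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    y = table.data[MODEL_COLUMN].to_numpy()
    mu = Z.mean(axis=0)
    Sw = np.zeros((2, 2))
    Sb = np.zeros((2, 2))
    for m in ("A", "B"):
        Zm = Z[y == m]
        mu_m = Zm.mean(axis=0)
        Sw += (Zm - mu_m).T @ (Zm - mu_m)
        Sb += len(Zm) * np.outer(mu_m - mu, mu_m - mu)
    vals, vecs = eigh(Sb, Sw)
    lead = vecs[:, np.argmax(vals)]
    lead = lead / np.linalg.norm(lead)
    assert min(np.linalg.norm(axis - lead), np.linalg.norm(axis + lead)) < 1e-8


def test_projection_deterministic_given_table():
    table = separable_table(n_per_model=200, seed=77)
    obs = pd.Series({"s1": 0.2, "s2": 0.1})
    p1 = gof_projections(table, obs)
    p2 = gof_projections(table, obs)
    assert np.allclose(p1.lda_obs, p2.lda_obs)
    assert np.allclose(p1.pca_obs, p2.pca_obs)
    assert np.allclose(
        p1.pca_rows.drop(columns=MODEL_COLUMN), p2.pca_rows.drop(columns=MODEL_COLUMN)
    )
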