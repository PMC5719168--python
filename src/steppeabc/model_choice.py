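"""ABC random-forest model choice on prior-predictive reference tables.

The reference table holds one row per simulated dataset: the generating
model label, its parameter draw and the summary-statistic vector.  A
classification random forest maps summary vectors to model labels; the
selected model for an observed vector is the one with most tree votes, and
its posterior probability is estimated, following the ABC-rf recipe, as
1 minus the prediction of a regression forest trained on the out-of-bag
misclassification indicator of the reference table.

Goodness of fit of the winning model is assessed by projecting the observed
vector into the LDA and PCA spaces of the (z-scored) reference table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import MutationParams, mutate, simulate_genealogy
from .demography import DemographicModel, PriorSpec, sample_parameters
from .sumstats import impute_summary_table, summarize, summary_layout

MODEL_COLUMN = "model"

#: forest hyperparameters beyond n_trees, fixed and recorded in manifests;
#: classification uses the standard sqrt(p) feature subsampling, the error
#: regression forest the usual regression defaults (p/3 features, leaves of
#: at least 5 rows so leaf means estimate the local error rate)
FOREST_DEFAULTS = {"max_features": "sqrt", "min_samples_leaf": 1}
ERROR_FOREST_DEFAULTS = {"max_features": 1.0 / 3.0}
#: error-forest leaves hold at least this fraction of the table (floor 5
#: rows) so each leaf mean is a stable local misclassification-rate
#: estimate rather than a memorised indicator
ERROR_FOREST_LEAF_FRACTION = 0.02


class ModelChoiceError(ValueError):
    pass


@dataclass
class ReferenceTable:
    """(model label, parameter draw, summary vector) rows plus provenance."""

    data: pd.DataFrame
    stat_columns: tuple[str, ...]
    param_columns: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def models(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.data[MODEL_COLUMN]:
            seen.setdefault(m, None)
        return tuple(seen)

    def rows_for_model(self, name: str) -> pd.DataFrame:
        return self.data[self.data[MODEL_COLUMN] == name]

    def restrict(self, models: Sequence[str]) -> "ReferenceTable":
        """Sub-table for a head-to-head comparison (e.g. MIG2 vs MIG12)."""
        keep = self.data[MODEL_COLUMN].isin(list(models))
        return ReferenceTable(
            data=self.data[keep].reset_index(drop=True),
            stat_columns=self.stat_columns,
            param_columns=self.param_columns,
            provenance={**self.provenance, "restricted_to": list(models)},
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_frames(
        cls,
        model_labels: Sequence[str],
        params: pd.DataFrame,
        stats: pd.DataFrame,
        provenance: dict | None = None,
    ) -> "ReferenceTable":
        stats = impute_summary_table(stats)
        data = pd.concat(
            [pd.Series(list(model_labels), name=MODEL_COLUMN), params, stats], axis=1
        )
        return cls(
            data=data,
            stat_columns=tuple(stats.columns),
            param_columns=tuple(params.columns),
            provenance=provenance or {},
        )


def simulate_row(
    model: DemographicModel,
    priors: PriorSpec,
    locus: Mapping,
    seed_seq: np.random.SeedSequence,
) -> tuple[dict[str, float], pd.Series]:
    """One prior-predictive simulation: draw -> genealogy -> alignment ->
    summary vector."""
    s_draw, s_tree, s_mut = seed_seq.spawn(3)
    draw = sample_parameters(model, priors, np.random.default_rng(s_draw))
    tree = simulate_genealogy(model, draw, np.random.default_rng(s_tree))
    mp = MutationParams(
        locus_length=int(locus["length"]),
        mu_per_site=draw["mu"],
        ts_tv_ratio=float(locus["kappa"]),
        base_frequencies=tuple(locus["base_frequencies"]),
    )
    aln = mutate(tree, mp, np.random.default_rng(s_mut))
    pops = [p.name for p in model.populations]
    return draw.as_dict(), summarize(aln, pops)


def build_reference_table(
    models: Sequence[DemographicModel],
    priors: PriorSpec,
    n_per_model: int,
    seed: int,
    locus: Mapping,
    row_range: tuple[int, int] | None = None,
) -> ReferenceTable:
    """Prior-predictive reference table: ``n_per_model`` rows per model.

    Every row is seeded independently from ``(seed, model_index, row_index)``
    so the build is reproducible and resumable in chunks: ``row_range``
    restricts the build to rows ``[start, stop)`` of each model, and
    concatenating chunk tables reproduces the full table byte for byte.
    """
    if n_per_model < 1:
        raise ModelChoiceError("n_per_model must be >= 1")
    start, stop = row_range if row_range is not None else (0, n_per_model)
    labels: list[str] = []
    param_rows: list[dict[str, float]] = []
    stat_rows: list[pd.Series] = []
    for m_idx, model in enumerate(models):
        for row in range(start, stop):
            ss = np.random.SeedSequence([seed, m_idx, row])
            pvals, stats = simulate_row(model, priors, locus, ss)
            labels.append(model.name)
            param_rows.append(pvals)
            stat_rows.append(stats)
    params = pd.DataFrame(param_rows)
    stats = pd.DataFrame(stat_rows).reset_index(drop=True)
    return ReferenceTable.from_frames(
        labels,
        params,
        stats,
        provenance={
            "seed": seed,
            "n_per_model": n_per_model,
            "row_range": [start, stop],
            "models": [m.name for m in models],
            "forest_defaults": dict(FOREST_DEFAULTS),
        },
    )


@dataclass
class ForestModel:
    """A trained ABC-rf classifier with retained out-of-bag predictions."""

    classifier: RandomForestClassifier
    stat_columns: tuple[str, ...]
    class_order: tuple[str, ...]  # documented tie-break order
    X: np.ndarray
    y: np.ndarray  # true labels
    oob_predictions: np.ndarray  # OOB-predicted labels per row
    oob_valid: np.ndarray  # rows with at least one OOB tree
    n_trees: int
    seed: int
    _error_forest: RandomForestRegressor | None = None

    @property
    def prior_error_rate(self) -> float:
        """Global out-of-bag misclassification rate (PODs = table rows)."""
        ok = self.oob_valid
        return float(np.mean(self.oob_predictions[ok] != self.y[ok]))

    def error_forest(self) -> RandomForestRegressor:
        """Regression forest on the OOB misclassification indicator."""
        if self._error_forest is None:
            ok = self.oob_valid
            miss = (self.oob_predictions[ok] != self.y[ok]).astype(float)
            leaf = max(5, int(np.ceil(ERROR_FOREST_LEAF_FRACTION * ok.sum())))
            reg = RandomForestRegressor(
                n_estimators=self.n_trees,
                random_state=self.seed + 1,
                min_samples_leaf=leaf,
                **ERROR_FOREST_DEFAULTS,
            )
            reg.fit(self.X[ok], miss)
            self._error_forest = reg
        return self._error_forest


@dataclass
class ModelChoiceResult:
    votes: dict[str, int]
    selected_model: str
    posterior_probability: float
    prior_error_rate: float
    n_trees: int
    seed: int

    def to_series(self) -> pd.Series:
        out = {f"votes_{m}": v for m, v in self.votes.items()}
        out.update(
            selected_model=self.selected_model,
            posterior_probability=self.posterior_probability,
            prior_error_rate=self.prior_error_rate,
            n_trees=self.n_trees,
        )
        return pd.Series(out)


def train_classifier(
    table: ReferenceTable, n_trees: int, seed: int
) -> ForestModel:
    """Train the classification forest (with out-of-bag bookkeeping)."""
    models = table.models
    if len(models) < 2:
        raise ModelChoiceError("need >= 2 models in the reference table")
    if n_trees == 1:
        warnings.warn(
            "n_trees=1: votes will be degenerate (0 or 1 per model)",
            stacklevel=2,
        )
    # canonical row order (model label, then stat values) so that votes and
    # posterior probabilities are invariant to the table's row order
    data = table.data.sort_values(
        by=[MODEL_COLUMN, *table.stat_columns], kind="mergesort"
    ).reset_index(drop=True)
    X = data[list(table.stat_columns)].to_numpy(dtype=float)
    if np.all(X.std(axis=0) == 0):
        raise ModelChoiceError("degenerate reference table: constant statistics")
    y = data[MODEL_COLUMN].to_numpy()
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=False,
        bootstrap=True,
        random_state=seed,
        **FOREST_DEFAULTS,
    )
    clf.fit(X, y)

    # out-of-bag predictions by hand so they exist even for tiny forests
    n = len(y)
    n_classes = len(clf.classes_)
    oob_votes = np.zeros((n, n_classes), dtype=np.int64)
    for est in clf.estimators_:
        unsampled = _unsampled_indices(est, n)
        if len(unsampled) == 0:
            continue
        pred = est.predict(X[unsampled]).astype(int)
        oob_votes[unsampled, pred] += 1
    oob_valid = oob_votes.sum(axis=1) > 0
    oob_pred_idx = oob_votes.argmax(axis=1)
    oob_predictions = clf.classes_[oob_pred_idx]
    return ForestModel(
        classifier=clf,
        stat_columns=table.stat_columns,
        class_order=tuple(m for m in models),
        X=X,
        y=y,
        oob_predictions=oob_predictions,
        oob_valid=oob_valid,
        n_trees=n_trees,
        seed=seed,
    )


def _unsampled_indices(estimator, n_samples: int) -> np.ndarray:
    import inspect

    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    # the private helpers grew a sample_weight argument in newer sklearn
    if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
        n_boot = _get_n_samples_bootstrap(n_samples, None, None)
        return _generate_unsampled_indices(
            estimator.random_state, n_samples, n_boot, None
        )
    n_boot = _get_n_samples_bootstrap(n_samples, None)
    return _generate_unsampled_indices(estimator.random_state, n_samples, n_boot)


def classify_observed(forest: ForestModel, obs: pd.Series) -> ModelChoiceResult:
    """Vote counts, selected model and ABC-rf posterior probability."""
    x = _layout_vector(forest, obs)
    clf = forest.classifier
    tree_preds = np.array(
        [est.predict(x.reshape(1, -1))[0] for est in clf.estimators_], dtype=int
    )
    counts = np.bincount(tree_preds, minlength=len(clf.classes_))
    votes = {str(c): int(v) for c, v in zip(clf.classes_, counts)}
    best = max(counts)
    tied = [str(c) for c, v in zip(clf.classes_, counts) if v == best]
    if len(tied) > 1:
        warnings.warn(
            f"vote tie among {tied}; breaking by documented model order",
            stacklevel=2,
        )
        selected = next(m for m in forest.class_order if m in tied)
    else:
        selected = tied[0]
    err = float(forest.error_forest().predict(x.reshape(1, -1))[0])
    posterior = float(np.clip(1.0 - err, 0.0, 1.0))
    return ModelChoiceResult(
        votes=votes,
        selected_model=selected,
        posterior_probability=posterior,
        prior_error_rate=forest.prior_error_rate,
        n_trees=forest.n_trees,
        seed=forest.seed,
    )


def _layout_vector(forest: ForestModel, obs: pd.Series) -> np.ndarray:
    missing = [c for c in forest.stat_columns if c not in obs.index]
    if missing:
        raise ModelChoiceError(f"observed vector lacks statistics: {missing}")
    return obs[list(forest.stat_columns)].to_numpy(dtype=float)


@dataclass
class PodErrorReport:
    """Classification error with the reference table's rows as PODs."""

    global_error: float
    confusion: pd.DataFrame  # rows: true model, columns: OOB-predicted

    @property
    def per_model_error(self) -> pd.Series:
        diag = pd.Series(np.diag(self.confusion), index=self.confusion.index)
        totals = self.confusion.sum(axis=1)
        return 1.0 - diag / totals


def classification_error_by_pod(forest: ForestModel) -> PodErrorReport:
    """Out-of-bag confusion matrix and global misclassification rate."""
    ok = forest.oob_valid
    y, pred = forest.y[ok], forest.oob_predictions[ok]
    labels = list(forest.class_order)
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y, pred):
        conf.loc[t, p] += 1
    return PodErrorReport(
        global_error=float(np.mean(pred != y)), confusion=conf
    )


@dataclass
class GofProjections:
    """LDA / PCA coordinates for reference rows and the observed point."""

    lda_rows: pd.DataFrame  # n_rows x (n_models - 1), plus 'model' column
    lda_obs: np.ndarray
    pca_rows: pd.DataFrame
    pca_obs: np.ndarray
    pca_explained_variance_ratio: np.ndarray
    lda_axes: np.ndarray  # axes as rows, in z-scored stat space


def gof_projections(
    table: ReferenceTable, obs: pd.Series, n_pca: int = 2
) -> GofProjections:
    """Project reference rows and the observed vector by LDA and PCA.

    Statistics are z-scored by the table's mean/SD (zero-variance columns
    dropped).  Each LDA axis is sign-fixed so the first-listed model has a
    negative mean score.
    """
    models = table.models
    if len(models) < 2:
        raise ModelChoiceError("need >= 2 models for projections")
    X = table.data[list(table.stat_columns)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    mean = X.mean(axis=0)
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    obs_vec = obs[list(table.stat_columns)].to_numpy(dtype=float)
    z_obs = (obs_vec[keep] - mean[keep]) / sd[keep]
    y = table.data[MODEL_COLUMN].to_numpy()

    n_axes = len(models) - 1
    lda = LinearDiscriminantAnalysis(n_components=n_axes)
    with warnings.catch_warnings():
        # collinear z-scored stats are expected; LDA's lstsq handles them
        warnings.simplefilter("ignore")
        lda_scores = lda.fit_transform(Z, y)
    lda_obs = lda.transform(z_obs.reshape(1, -1))[0]
    axes = lda.scalings_.T[:n_axes]
    first = models[0]
    for k in range(lda_scores.shape[1]):
        if lda_scores[y == first, k].mean() > 0:
            lda_scores[:, k] *= -1
            lda_obs[k] *= -1
            axes[k] *= -1

    pca = PCA(n_components=min(n_pca, Z.shape[1]))
    pca_scores = pca.fit_transform(Z)
    pca_obs = pca.transform(z_obs.reshape(1, -1))[0]

    lda_rows = pd.DataFrame(
        lda_scores, columns=[f"LD{k+1}" for k in range(lda_scores.shape[1])]
    )
    lda_rows[MODEL_COLUMN] = y
    pca_rows = pd.DataFrame(
        pca_scores, columns=[f"PC{k+1}" for k in range(pca_scores.shape[1])]
    )
    pca_rows[MODEL_COLUMN] = y
    return GofProjections(
        lda_rows=lda_rows,
        lda_obs=lda_obs,
        pca_rows=pca_rows,
        pca_obs=pca_obs,
        pca_explained_variance_ratio=pca.explained_variance_ratio_,
        lda_axes=axes,
    )
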