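"""Trend summaries, regression and feature ablation.

The analysis stage mirrors the study design of the dataset it models:
relative energies are recomputed from single-point energies per ring-count
group; per-feature distributions of a property are summarized (optionally
restricted to the largest ring count to remove size dependence, with an
odd/even split for the B-N separation feature); and a gradient-boosted
tree regressor is trained on the six-component feature encoding alone,
with a 75:25 train/test split, 5-fold cross-validation on the training
portion, and a leave-one-feature-out ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold, train_test_split

from bnpah.features import FEATURE_COLUMNS
from bnpah.synthetic import HARTREE_TO_KCAL

logger = logging.getLogger(__name__)


def compute_e_rel(df: pd.DataFrame, group_col: str = "n_rings") -> pd.DataFrame:
    """Relative energy per ring-count group, from single-point energies.

    ``e_rel = (spe - min spe of the group) * 627.5095`` with ``spe`` in
    Hartree, so every group's most stable isomer sits at exactly zero.
    Returns a copy with the ``e_rel`` column (re)written.
    """
    out = df.copy()
    e_rel = np.empty(len(out), dtype=float)
    for key, idx in out.groupby(group_col).indices.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empties
            logger.warning("empty group %s skipped", key)
            continue
        spe = out["spe"].to_numpy()[idx]
        e_rel[idx] = (spe - spe.min()) * HARTREE_TO_KCAL
    out["e_rel"] = e_rel
    return out


@dataclass(frozen=True)
class TrendSummary:
    feature: str
    property: str
    table: pd.DataFrame  # one row per feature level (x parity where used)
    restricted_to_n_rings: int | None = None


def trend_summary(
    df: pd.DataFrame,
    feature: str,
    prop: str,
    restrict_to_n_rings: int | None = None,
    parity_split: bool | None = None,
) -> TrendSummary:
    """Per-level distribution statistics of ``prop`` against ``feature``.

    ``restrict_to_n_rings`` keeps only isomers of one size (the convention
    used to remove size dependence from the positional features).  For the
    B-N separation feature an odd/even parity column is added by default,
    exposing the zigzag between the two resonance series.
    """
    if feature not in df.columns:
        raise ValueError(f"unknown feature {feature!r}")
    if prop not in df.columns:
        raise ValueError(f"unknown property {prop!r}")
    data = df
    if restrict_to_n_rings is not None:
        data = data[data["n_rings"] == restrict_to_n_rings]
    if parity_split is None:
        parity_split = feature == "n_SP"

    keys = [feature] + (["parity"] if parity_split else [])
    data = data.copy()
    if parity_split:
        data["parity"] = np.where(data[feature] % 2 == 0, "even", "odd")
    stats = (
        data.groupby(keys)[prop]
        .agg(
            count="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            min="min",
            max="max",
        )
        .reset_index()
    )
    assert stats["count"].sum() == len(data)
    return TrendSummary(
        feature=feature,
        property=prop,
        table=stats,
        restricted_to_n_rings=restrict_to_n_rings,
    )


@dataclass
class RegressionReport:
    target: str
    test_mae: float
    test_r2: float
    cv_mae: list[float]
    cv_r2: list[float]
    train_fraction: float
    seed: int
    feature_importances: dict[str, float]
    ablation: dict[str, dict[str, float]] = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _make_model(seed: int, **overrides):
    from lightgbm import LGBMRegressor

    params = dict(random_state=seed, n_jobs=1, verbose=-1)
    params.update(overrides)
    return LGBMRegressor(**params)


def _safe_r2(y_true, y_pred) -> float:
    if np.allclose(np.var(y_true), 0.0):
        return 0.0  # R^2 undefined for a constant target; report 0 explicitly
    return float(r2_score(y_true, y_pred))


def train_and_evaluate(
    df: pd.DataFrame,
    target: str,
    feature_columns: list[str] | None = None,
    test_fraction: float = 0.25,
    folds: int = 5,
    seed: int = 0,
    model_factory=None,
) -> RegressionReport:
    """Fit a regressor on the structural features and report its accuracy.

    A random (non-stratified) 75:25 train/test split; K-fold CV metrics are
    computed on the training portion only; test MAE/R^2 on the held-out
    quarter.  Deterministic for a fixed seed.
    """
    feature_columns = feature_columns or FEATURE_COLUMNS
    if not np.issubdtype(df[target].dtype, np.number):
        raise ValueError(f"target {target!r} is not numeric")
    if df[feature_columns].isna().any().any() or df[target].isna().any():
        raise ValueError("missing values in features or target")

    X = df[feature_columns].astype(float)
    y = df[target].to_numpy(dtype=float)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_fraction, random_state=seed
    )

    factory = model_factory or (lambda: _make_model(seed))

    cv_mae, cv_r2 = [], []
    for train_idx, val_idx in KFold(
        n_splits=folds, shuffle=True, random_state=seed
    ).split(X_train):
        m = factory()
        m.fit(X_train.iloc[train_idx], y_train[train_idx])
        pred = m.predict(X_train.iloc[val_idx])
        cv_mae.append(float(mean_absolute_error(y_train[val_idx], pred)))
        cv_r2.append(_safe_r2(y_train[val_idx], pred))

    model = factory()
    model.fit(X_train, y_train)
    pred = model.predict(X_test)

    importances = {}
    raw = getattr(model, "feature_importances_", None)
    if raw is not None:
        total = raw.sum() or 1.0
        importances = {c: float(v) / total for c, v in zip(feature_columns, raw)}

    return RegressionReport(
        target=target,
        test_mae=float(mean_absolute_error(y_test, pred)),
        test_r2=_safe_r2(y_test, pred),
        cv_mae=cv_mae,
        cv_r2=cv_r2,
        train_fraction=1.0 - test_fraction,
        seed=seed,
        feature_importances=importances,
        model_params={
            k: v
            for k, v in getattr(model, "get_params", dict)().items()
            if isinstance(v, (int, float, str, bool, type(None)))
        },
    )


def ablation_study(
    df: pd.DataFrame,
    target: str,
    feature_columns: list[str] | None = None,
    seed: int = 0,
    **kwargs,
) -> RegressionReport:
    """Leave-one-feature-out retraining.

    The returned report is the full-feature baseline; its ``ablation``
    table maps each dropped feature to the resulting test MAE/R^2 and the
    MAE increase relative to the baseline.
    """
    feature_columns = feature_columns or FEATURE_COLUMNS
    baseline = train_and_evaluate(
        df, target, feature_columns=feature_columns, seed=seed, **kwargs
    )
    for drop in feature_columns:
        remaining = [c for c in feature_columns if c != drop]
        rep = train_and_evaluate(
            df, target, feature_columns=remaining, seed=seed, **kwargs
        )
        baseline.ablation[drop] = {
            "test_mae": rep.test_mae,
            "test_r2": rep.test_r2,
            "delta_mae": rep.test_mae - baseline.test_mae,
        }
    return baseline


def most_important_feature(report: RegressionReport) -> str:
    """Feature whose removal degrades MAE the most (ablation ranking)."""
    if not report.ablation:
        raise ValueError("report carries no ablation table")
    return max(report.ablation, key=lambda k: report.ablation[k]["delta_mae"])
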