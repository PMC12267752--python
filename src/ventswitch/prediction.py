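"""LASSO failure-prediction models with nested cross-validated AUC.

Two L1-penalized logistic models predict first-switch failure: model 1 from
pre-switch windowed-LOCF variables only, model 2 additionally from Δ3h
change variables, restricted to patients still in assisted mode 3 h after
the attempt.  Missing values are median-imputed with paired missingness
indicators; standardization and imputation are learned on training folds
only.  The reported AUC is computed exclusively on held-out outer-fold
predictions (outer 5-fold, penalty chosen by inner 5-fold cross-validation,
both stratified by outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import VarianceThreshold
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


@dataclass
class DesignMatrix:
    X: pd.DataFrame  # raw feature values, NaN for missing
    y: np.ndarray  # 1 = failure
    model_id: int
    feature_names: list[str]
    stay_ids: np.ndarray


@dataclass
class CVResult:
    model_id: int
    auc: float
    auc_se: float
    fold_aucs: list[float]
    fold_assignments: np.ndarray
    coefficients: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "auc": self.auc,
            "auc_se": self.auc_se,
            "fold_aucs": self.fold_aucs,
            "coefficients": self.coefficients,
        }


def build_design(
    features: pd.DataFrame,
    outcomes: pd.Series,
    deltas: pd.DataFrame | None = None,
    model_id: int = 1,
    retained_stays: np.ndarray | list | None = None,
) -> DesignMatrix:
    """Assemble the design matrix for model 1 (pre-switch) or 2 (+Δ3h).

    ``features``/``deltas`` are wide matrices with a ``stay_id`` column and
    one column per variable (``__time`` companion columns are dropped);
    ``outcomes`` maps stay_id → 'success'/'failure'.  Model 2 restricts rows
    to ``retained_stays`` (the 3 h survivors) and appends the Δ columns.
    """
    feat = features[[c for c in features.columns if not c.endswith("__time") and c != "anchor_time"]]
    feat = feat.set_index("stay_id")
    if model_id == 2:
        if deltas is None:
            raise ValueError("model 2 requires delta features")
        d = deltas[[c for c in deltas.columns if c.startswith("delta_") or c == "stay_id"]]
        feat = feat.join(d.set_index("stay_id"), how="inner")
        if retained_stays is not None:
            feat = feat.loc[feat.index.isin(list(retained_stays))]
    feat = feat.dropna(axis=1, how="all")
    y = (outcomes.reindex(feat.index) == "failure").to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; cannot build a prediction design")
    return DesignMatrix(
        X=feat.reset_index(drop=True),
        y=y,
        model_id=model_id,
        feature_names=list(feat.columns),
        stay_ids=feat.index.to_numpy(),
    )


def _make_pipeline(seed: int, inner_folds: int, Cs) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", add_indicator=True)),
            ("drop_constant", VarianceThreshold(0.0)),
            ("scale", StandardScaler()),
            (
                "lasso",
                LogisticRegressionCV(
                    l1_ratios=(1.0,),  # pure L1 penalty
                    solver="liblinear",
                    Cs=np.asarray(Cs),
                    cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
                    scoring="roc_auc",
                    max_iter=2000,
                    refit=True,
                    random_state=seed,
                    use_legacy_attributes=False,
                ),
            ),
        ]
    )


def fit_lasso_cv(
    design: DesignMatrix,
    folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    Cs=np.logspace(-2.5, 1.0, 8),
) -> CVResult:
    """Nested cross-validated L1 logistic regression.

    The outer loop provides held-out predictions (never used in fitting);
    the inner loop picks the penalty.  AUC is computed on the pooled
    held-out predictions; ``auc_se`` is the SD of per-fold AUCs over
    sqrt(folds).  Deterministic given the seed.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    if len(y) <= folds:
        raise ValueError("need more rows than outer folds")
    outer = StratifiedKFold(folds, shuffle=True, random_state=seed)
    held_out = np.full(len(y), np.nan)
    assignments = np.full(len(y), -1)
    fold_aucs = []
    coefficients = []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        pipe = _make_pipeline(seed + f, inner_folds, Cs)
        pipe.fit(X[tr], y[tr])
        held_out[te] = pipe.predict_proba(X[te])[:, 1]
        assignments[te] = f
        fold_aucs.append(float(roc_auc_score(y[te], held_out[te])))
        lasso = pipe.named_steps["lasso"]
        support = pipe.named_steps["drop_constant"].get_support()
        names = _expanded_names(pipe.named_steps["impute"], design.feature_names)
        kept = [n for n, s in zip(names, support) if s]
        coefficients.append(
            {n: float(c) for n, c in zip(kept, lasso.coef_[0]) if c != 0.0}
        )
    assert not np.isnan(held_out).any()
    auc = float(roc_auc_score(y, held_out))
    return CVResult(
        model_id=design.model_id,
        auc=auc,
        auc_se=float(np.std(fold_aucs, ddof=1) / np.sqrt(folds)),
        fold_aucs=fold_aucs,
        fold_assignments=assignments,
        coefficients=coefficients,
    )


def _expanded_names(imputer: SimpleImputer, names: list[str]) -> list[str]:
    out = list(names)
    if imputer.indicator_ is not None:
        out += [f"{names[j]}__missing" for j in imputer.indicator_.features_]
    return out


def group_contribution(
    design: DesignMatrix,
    groups: dict[str, list[str]],
    folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """ΔAUC attribution per variable group (gas exchange / ventilatory / ...).

    ΔAUC = full-model cross-validated AUC minus the AUC of the model
    refitted without the group's columns, using the same fold seed so fold
    assignments match.  ``groups`` must partition the feature columns.
    """
    all_cols = [c for cols in groups.values() for c in cols]
    unknown = set(all_cols) - set(design.feature_names)
    if unknown:
        raise ValueError(f"unknown columns in groups: {sorted(unknown)}")
    if not all_cols:
        raise ValueError("groups cover no columns")
    full = fit_lasso_cv(design, folds=folds, inner_folds=inner_folds, seed=seed)
    rows = []
    for name, cols in groups.items():
        keep = [c for c in design.feature_names if c not in cols]
        if not keep:
            raise ValueError(f"group {name!r} removes every feature")
        sub = DesignMatrix(
            X=design.X[keep],
            y=design.y,
            model_id=design.model_id,
            feature_names=keep,
            stay_ids=design.stay_ids,
        )
        res = fit_lasso_cv(sub, folds=folds, inner_folds=inner_folds, seed=seed)
        rows.append({"group": name, "auc_without": res.auc, "delta_auc": full.auc - res.auc})
    out = pd.DataFrame(rows)
    out.attrs["full_auc"] = full.auc
    return out


def bayes_auc(true_probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """AUC of the generator's true failure probabilities against realized outcomes.

    This is the Bayes-optimal discrimination attainable on the cohort and
    serves as the oracle target for the fitted models.
    """
    return float(roc_auc_score(np.asarray(outcomes, dtype=int), np.asarray(true_probabilities, dtype=float)))
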