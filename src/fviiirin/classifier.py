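"""Ensemble prediction of mutant activity from network centralities.

Alanine mutants are labelled High (> 50% of wild-type chromogenic
activity) or Low (< 50%); exactly 50% is assigned Low by default
(conservative, configurable).  Three member classifiers — an RBF-kernel
support-vector machine, Gaussian naive Bayes and gradient-boosted trees —
are trained on per-residue centrality features with stratified 10-fold
cross-validation, member hyperparameters chosen by mean out-of-fold
Cohen's Kappa (AUC tie-break).  The ensemble combines members by the
median of their predicted High-class probabilities, and predictions whose
median falls inside a flag band (default [0.4, 0.6]) are flagged as not
clearly harmless or detrimental.

Feature normalisation is fit on training folds only and applied to the
held-out fold, so there is no leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .structure import ResidueKey

logger = logging.getLogger(__name__)

HIGH, LOW = "High", "Low"
ACTIVITY_SPLIT_PCT = 50.0
DEFAULT_FLAG_BAND = (0.4, 0.6)
DEFAULT_FOLDS = 10
MEMBER_NAMES = ("svm", "naive_bayes", "xgboost")

#: scaled-down hyperparameter grids (fast enough for routine runs)
DEFAULT_SVM_GAMMA_GRID = tuple(np.round(np.arange(0.05, 1.5001, 0.05), 10))
DEFAULT_XGB_DEPTH_GRID = tuple(range(1, 26, 2))
DEFAULT_XGB_ETA_GRID = (0.1, 0.3, 0.5)
DEFAULT_XGB_LAMBDA_GRID = (0.0, 0.5, 1.0)

#: grids at the full published granularity (--full-grid)
FULL_SVM_GAMMA_GRID = tuple(np.round(np.arange(0.01, 1.5001, 0.01), 10))
FULL_XGB_DEPTH_GRID = tuple(range(1, 26))
FULL_XGB_ETA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 10))
FULL_XGB_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 10))

XGB_N_ESTIMATORS = 50


@dataclass(frozen=True)
class MutantRecord:
    """One mutant construct and its measured activity."""

    residue_key: ResidueKey
    substitution: str
    chromogenic_pct: float
    secretion_pct: float
    tie_rule: str = "low"  # label for records at exactly 50%

    def __post_init__(self):
        if self.chromogenic_pct < 0 or self.secretion_pct < 0:
            raise ValueError("activity percentages must be >= 0")

    @property
    def label(self) -> str:
        if self.chromogenic_pct > ACTIVITY_SPLIT_PCT:
            return HIGH
        if self.chromogenic_pct < ACTIVITY_SPLIT_PCT:
            return LOW
        return HIGH if self.tie_rule == "high" else LOW


@dataclass
class FeatureTable:
    """Feature matrix + labels for resolvable mutants.

    ``x`` holds raw (unnormalised) feature columns; normalisation choice is
    recorded and applied inside model pipelines on training folds only.
    """

    x: pd.DataFrame
    y: pd.Series  # 1 = High, 0 = Low
    normalization: str = "zscore"  # or "minmax"

    def __len__(self) -> int:
        return len(self.x)

    def scaler(self):
        return StandardScaler() if self.normalization == "zscore" else MinMaxScaler()


def build_feature_table(t: pd.DataFrame, mutants: Sequence[MutantRecord],
                        features: Sequence[str],
                        normalization: str = "zscore",
                        on_constant: str = "error") -> FeatureTable:
    """Join mutants to centrality rows; unresolvable or incomplete rows drop.

    A zero-variance feature column raises (default) or is dropped with a
    warning when ``on_constant="drop"``.
    """
    rows, labels, index = [], [], []
    n_unresolved = 0
    for m in mutants:
        if m.residue_key not in t.index:
            n_unresolved += 1
            logger.info("mutant at %s not resolvable to a network node; dropped",
                        m.residue_key.label())
            continue
        rows.append(t.loc[m.residue_key, list(features)])
        labels.append(1 if m.label == HIGH else 0)
        index.append(m.residue_key)
    if n_unresolved:
        logger.warning("build_feature_table: %d unresolvable mutants dropped",
                       n_unresolved)
    if not rows:
        raise ValueError("no resolvable mutants")
    x = pd.DataFrame(rows, index=pd.Index(index), columns=list(features),
                     dtype=float)
    y = pd.Series(labels, index=x.index, name="label")
    # missing-value rule: drop examples with any missing attribute
    complete = ~x.isna().any(axis=1)
    if (~complete).any():
        logger.warning("build_feature_table: %d rows with missing attributes "
                       "removed", int((~complete).sum()))
        x, y = x[complete], y[complete]
    if not len(x):
        raise ValueError("no complete-feature mutants")
    for col in x.columns:
        if x[col].nunique() <= 1:
            if on_constant == "drop":
                logger.warning("constant feature %r dropped", col)
                x = x.drop(columns=[col])
            else:
                raise ValueError(f"feature {col!r} has zero variance")
    if not x.shape[1]:
        raise ValueError("no informative features left")
    return FeatureTable(x=x, y=y, normalization=normalization)


# ---------------------------------------------------------------------------
# members and grids


def _make_member(name: str, params: dict, ft: FeatureTable, seed: int):
    if name == "svm":
        model = SVC(kernel="rbf", gamma=params["gamma"], probability=True,
                    random_state=seed)
    elif name == "naive_bayes":
        model = GaussianNB()
    elif name == "xgboost":
        model = XGBClassifier(
            n_estimators=XGB_N_ESTIMATORS, max_depth=params["max_depth"],
            learning_rate=params["eta"], reg_lambda=params["reg_lambda"],
            objective="binary:logistic", eval_metric="logloss",
            n_jobs=1, random_state=seed, verbosity=0,
        )
    else:
        raise ValueError(f"unknown member {name!r}")
    return Pipeline([("scale", ft.scaler()), ("model", model)])


def member_grids(full_grid: bool = False,
                 svm_gamma_grid: Optional[Sequence[float]] = None,
                 xgb_depth_grid: Optional[Sequence[int]] = None,
                 xgb_eta_grid: Optional[Sequence[float]] = None,
                 xgb_lambda_grid: Optional[Sequence[float]] = None,
                 ) -> Dict[str, List[dict]]:
    """Hyperparameter grids per member (scaled-down by default)."""
    gammas = svm_gamma_grid or (FULL_SVM_GAMMA_GRID if full_grid
                                else DEFAULT_SVM_GAMMA_GRID)
    depths = xgb_depth_grid or (FULL_XGB_DEPTH_GRID if full_grid
                                else DEFAULT_XGB_DEPTH_GRID)
    etas = xgb_eta_grid or (FULL_XGB_ETA_GRID if full_grid
                            else DEFAULT_XGB_ETA_GRID)
    lambdas = xgb_lambda_grid or (FULL_XGB_LAMBDA_GRID if full_grid
                                  else DEFAULT_XGB_LAMBDA_GRID)
    return {
        "svm": [{"gamma": float(g)} for g in gammas],
        "naive_bayes": [{}],
        "xgboost": [{"max_depth": int(d), "eta": float(e), "reg_lambda": float(l)}
                    for d in depths for e in etas for l in lambdas],
    }


def _oof_probabilities(ft: FeatureTable, name: str, params: dict,
                       splits: List[Tuple[np.ndarray, np.ndarray]],
                       seed: int) -> np.ndarray:
    """Out-of-fold P(High) for one member configuration."""
    probs = np.empty(len(ft))
    x, y = ft.x.to_numpy(), ft.y.to_numpy()
    for train_idx, test_idx in splits:
        pipe = _make_member(name, params, ft, seed)
        pipe.fit(x[train_idx], y[train_idx])
        p = pipe.predict_proba(x[test_idx])
        high_col = list(pipe.named_steps["model"].classes_).index(1)
        probs[test_idx] = p[:, high_col]
    return probs


@dataclass
class TrainedEnsemble:
    members: Dict[str, Pipeline]
    chosen_params: Dict[str, dict]
    oof_probabilities: pd.DataFrame  # one column per member + "median"
    fold_metrics: pd.DataFrame
    fold_assignment: np.ndarray
    seed: int
    feature_names: List[str]


def train_members(ft: FeatureTable, folds: int = DEFAULT_FOLDS,
                  seed: int = 0, full_grid: bool = False,
                  **grid_overrides) -> TrainedEnsemble:
    """Grid-search the three members and fit them on the full table.

    Hyperparameters are selected per member by mean out-of-fold Kappa over
    the same stratified folds (AUC as tie-break); every source of
    randomness derives from ``seed``.  The returned ensemble carries the
    members refit on all rows plus the out-of-fold probabilities of the
    selected configurations, from which honest cross-validated ensemble
    metrics follow.
    """
    if len(ft) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} instances for {folds} folds")
    classes = set(ft.y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    x, y = ft.x.to_numpy(), ft.y.to_numpy()
    splits = list(skf.split(x, y))
    for _, test_idx in splits:
        if len(set(y[test_idx])) < 2:
            logger.warning("a fold has a single class; metrics may degenerate")

    grids = member_grids(full_grid=full_grid, **grid_overrides)
    chosen: Dict[str, dict] = {}
    oof: Dict[str, np.ndarray] = {}
    for name, configs in grids.items():
        best = None
        for params in configs:
            probs = _oof_probabilities(ft, name, params, splits, seed)
            pred = (probs >= 0.5).astype(int)
            kappa = cohen_kappa_score(y, pred)
            auc = roc_auc_score(y, probs)
            score = (kappa, auc)
            if best is None or score > best[0]:
                best = (score, params, probs)
        chosen[name] = best[1]
        oof[name] = best[2]
        logger.info("member %s: chose %s (kappa=%.3f, auc=%.3f)", name,
                    best[1], best[0][0], best[0][1])

    oof_df = pd.DataFrame(oof, index=ft.x.index)
    oof_df["median"] = oof_df[list(MEMBER_NAMES)].median(axis=1)

    fold_assignment = np.empty(len(ft), dtype=int)
    rows = []
    for k, (_, test_idx) in enumerate(splits):
        fold_assignment[test_idx] = k
        med = oof_df["median"].to_numpy()[test_idx]
        pred = (med >= 0.5).astype(int)
        truth = y[test_idx]
        acc = float((pred == truth).mean())
        kap = cohen_kappa_score(truth, pred) if len(set(truth)) > 1 else np.nan
        rows.append({"fold": k, "n": len(test_idx), "accuracy": acc,
                     "kappa": kap})
    fold_metrics = pd.DataFrame(rows)

    members = {}
    for name in MEMBER_NAMES:
        pipe = _make_member(name, chosen[name], ft, seed)
        pipe.fit(ft.x, ft.y)  # DataFrame fit records the feature schema
        members[name] = pipe
    return TrainedEnsemble(members=members, chosen_params=chosen,
                           oof_probabilities=oof_df,
                           fold_metrics=fold_metrics,
                           fold_assignment=fold_assignment, seed=seed,
                           feature_names=list(ft.x.columns))


# ---------------------------------------------------------------------------
# ensemble prediction and evaluation


def ensemble_predict(members: Mapping[str, Pipeline], x: pd.DataFrame,
                     flag_band: Tuple[float, float] = DEFAULT_FLAG_BAND
                     ) -> pd.DataFrame:
    """Median-of-members probability, label and uncertainty flag per row."""
    lo, hi = flag_band
    if not (0 < lo < hi < 1):
        raise ValueError("flag band must sit strictly inside (0, 1)")
    probs = {}
    for name, pipe in members.items():
        expected = getattr(pipe, "feature_names_in_", None)
        if expected is not None and list(expected) != list(x.columns):
            raise ValueError(
                f"feature schema mismatch: member {name} trained on "
                f"{list(expected)}, got {list(x.columns)}")
        p = pipe.predict_proba(x)
        high_col = list(pipe.named_steps["model"].classes_).index(1)
        probs[name] = p[:, high_col]
    out = pd.DataFrame(probs, index=x.index)
    med = out.median(axis=1)
    out["median_probability"] = med
    out["predicted_label"] = np.where(med >= 0.5, HIGH, LOW)
    out["flagged"] = (med >= lo) & (med <= hi)
    return out


def median_prediction_frame(oof: pd.DataFrame,
                            flag_band: Tuple[float, float] = DEFAULT_FLAG_BAND
                            ) -> pd.DataFrame:
    """Label/flag frame from an out-of-fold probability table."""
    lo, hi = flag_band
    med = oof["median"]
    return pd.DataFrame({
        "median_probability": med,
        "predicted_label": np.where(med >= 0.5, HIGH, LOW),
        "flagged": (med >= lo) & (med <= hi),
    }, index=oof.index)


def evaluate(median_probability: Sequence[float], flagged: Sequence[bool],
             truth: Sequence[int]) -> dict:
    """Accuracy (overall and on unflagged rows), Cohen's Kappa and AUC.

    ``truth`` is 1 for High, 0 for Low.  With every row flagged, the
    unflagged accuracy is reported as None.
    """
    p = np.asarray(median_probability, dtype=float)
    f = np.asarray(flagged, dtype=bool)
    t = np.asarray(truth, dtype=int)
    if len(t) < 2 or len(set(t.tolist())) < 2:
        raise ValueError("need >= 2 instances with both classes in truth")
    pred = (p >= 0.5).astype(int)
    out = {
        "accuracy": float((pred == t).mean()),
        "kappa": float(cohen_kappa_score(t, pred)),
        "auc": float(roc_auc_score(t, p)),
        "flagged_fraction": float(f.mean()),
    }
    if f.all():
        out["accuracy_unflagged"] = None
    else:
        out["accuracy_unflagged"] = float((pred[~f] == t[~f]).mean())
    return out


def read_mutant_csv(path, tie_rule: str = "low") -> List[MutantRecord]:
    """Read a mutant activity CSV (chain, position, wt_aa, mut_aa,
    chromogenic_pct, secretion_pct)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        key = ResidueKey(str(row["chain"]), int(row["position"]), "",
                         str(row["wt_aa"]).upper())
        records.append(MutantRecord(
            residue_key=key, substitution=str(row["mut_aa"]).upper(),
            chromogenic_pct=float(row["chromogenic_pct"]),
            secretion_pct=float(row["secretion_pct"]), tie_rule=tie_rule))
    return records
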