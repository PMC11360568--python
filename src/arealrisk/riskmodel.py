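"""Characterizing primary-cluster membership with classifier models.

Units are described by neighborhood features — Kroll-weighted
socioeconomic composites (education, occupation, income), shares of four
conservative milieus, household size, population density, dentists per
1000 inhabitants, and the mean incidence of the other diseases — and
labeled by membership in the primary scan cluster. The training split is
rebalanced with ROSE (smoothed-bootstrap oversampling), five classifier
families are fit (logistic regression, decision tree, random forest,
RBF-kernel SVM, single-hidden-layer neural network), evaluated with the
confusion-matrix metric family plus ROC/PR areas, and the selected model
is probed with permutation variable importance: the mean increase in
RMSE loss (predicted probability vs 0/1 label) when one feature column is
shuffled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

MODEL_ORDER = ["LR", "DT", "RF", "SVM", "NN"]

KROLL_WEIGHTS = {
    "education": {"no_school": -0.33, "university": 0.66},
    "occupation": {"unemployment": -0.61, "purchasing_power": 0.27, "employment": 0.50},
    "income": {"debtor": -0.41, "net_income": 0.52},
}

FEATURE_COLUMNS = [
    "education",
    "occupation",
    "income",
    "conservative_upscale",
    "nostalgic_middle",
    "precarious",
    "traditional",
    "inhabitants_per_household",
    "inhabitants_per_km2",
    "dentists_per_1000",
    "incidence_other_diseases",
]

__all__ = [
    "ModelConfig",
    "EvalReport",
    "ses_dimensions",
    "burden_other_diseases",
    "build_feature_table",
    "split_train_test",
    "rose_oversample",
    "train_classifiers",
    "evaluate",
    "select_best",
    "permutation_importance",
]


@dataclass
class ModelConfig:
    """Classifier settings: SVM tuning grid, network width, seeds."""

    svm_cost_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    svm_cv_folds: int = 5
    nn_hidden: int = 5
    rf_trees: int = 500
    seed: int = 0
    threshold: float = 0.5


@dataclass
class EvalReport:
    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    specificity: float
    precision: float
    recall: float
    NPV: float
    PPV: float
    f1: float
    roc_auc: float
    pr_auc: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero-variance raw variable: {col.name!r}")
    return (col - col.mean()) / sd


def ses_dimensions(raw: pd.DataFrame) -> pd.DataFrame:
    """Kroll-weighted socioeconomic composites from raw unit covariates.

    Each raw variable is z-standardized across units, then combined:
    education = -0.33 z(no_school) + 0.66 z(university);
    occupation = -0.61 z(unemployment) + 0.27 z(purchasing_power)
                 + 0.50 z(employment);
    income = -0.41 z(debtor) + 0.52 z(net_income).
    Higher scores mean higher status.
    """
    out = {}
    for dim, weights in KROLL_WEIGHTS.items():
        missing = set(weights) - set(raw.columns)
        if missing:
            raise ValueError(f"missing raw variables for {dim}: {sorted(missing)}")
        acc = sum(w * _zscore(raw[var]) for var, w in weights.items())
        out[dim] = acc
    return pd.DataFrame(out, index=raw.index)


def burden_other_diseases(rates: pd.DataFrame, disease: str) -> pd.Series:
    """Mean raw incidence rate of the other diseases, per unit.

    ``rates`` is a long table with columns unit_id, disease, rate.
    """
    diseases = sorted(rates["disease"].unique())
    if disease not in diseases:
        raise ValueError(f"disease {disease!r} not present in rate table")
    others = [d for d in diseases if d != disease]
    if not others:
        raise ValueError("need at least two diseases to compute the burden feature")
    wide = rates.pivot_table(index="unit_id", columns="disease", values="rate")
    if wide[others].isna().any().any():
        raise ValueError("missing rates for some unit/disease pairs")
    return wide[others].mean(axis=1).rename("incidence_other_diseases")


def build_feature_table(
    raw_covariates: pd.DataFrame,
    rates: pd.DataFrame,
    disease: str,
    cluster_members: set[str],
) -> pd.DataFrame:
    """Assemble the per-unit feature matrix plus the cluster-membership label."""
    ses = ses_dimensions(raw_covariates)
    burden = burden_other_diseases(rates, disease)
    passthrough = [
        "conservative_upscale",
        "nostalgic_middle",
        "precarious",
        "traditional",
        "inhabitants_per_household",
        "inhabitants_per_km2",
        "dentists_per_1000",
    ]
    feats = pd.concat(
        [ses, raw_covariates[passthrough], burden.reindex(raw_covariates.index)],
        axis=1,
    )
    feats["label"] = [uid in cluster_members for uid in feats.index]
    return feats


def split_train_test(
    table: pd.DataFrame, train_frac: float = 0.8, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded, label-stratified train/test partition (default 80/20)."""
    rng = np.random.default_rng(seed)
    train_idx: list = []
    for _, grp in table.groupby("label"):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        train_idx.extend(idx[:n_train])
    train = table.loc[sorted(train_idx, key=list(table.index).index)]
    test = table.loc[~table.index.isin(train_idx)]
    return train, test


def rose_oversample(
    X: pd.DataFrame, y: pd.Series, seed: int | None = None, *, shrink: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """ROSE smoothed-bootstrap oversampling to a balanced training set.

    Each synthetic record picks a class with probability 1/2, draws a seed
    record uniformly within that class, and adds Gaussian noise with
    per-feature bandwidth h_j = shrink * sigma_j * (4 / ((d+2) n_class))^(1/(d+4))
    (the multivariate Silverman rule on the class subsample). The output
    has the original number of rows and an expected 1:1 class ratio.
    """
    y = y.astype(bool)
    classes = [False, True]
    if y.nunique() < 2:
        raise ValueError("both classes must be present for ROSE balancing")
    rng = np.random.default_rng(seed)
    n, d = X.shape
    Xv = X.to_numpy(dtype=float)
    rows = np.empty((n, d))
    labels = rng.random(n) < 0.5
    for cls in classes:
        take = np.flatnonzero(labels == cls)
        src = np.flatnonzero(y.to_numpy() == cls)
        n_cls = src.size
        sigma = Xv[src].std(axis=0, ddof=1) if n_cls > 1 else np.zeros(d)
        h = shrink * sigma * (4.0 / ((d + 2) * n_cls)) ** (1.0 / (d + 4))
        picks = src[rng.integers(0, n_cls, size=take.size)]
        rows[take] = Xv[picks] + rng.standard_normal((take.size, d)) * h
    Xb = pd.DataFrame(rows, columns=X.columns)
    yb = pd.Series(labels, name=y.name)
    return Xb, yb


def _make_models(cfg: ModelConfig) -> dict[str, object]:
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("clf", est)])
    svm = GridSearchCV(
        scaled(SVC(kernel="rbf", probability=True, random_state=cfg.seed)),
        param_grid={
            "clf__C": list(cfg.svm_cost_grid),
            "clf__gamma": list(cfg.svm_gamma_grid),
        },
        cv=cfg.svm_cv_folds,
        n_jobs=1,
    )
    return {
        "LR": scaled(LogisticRegression(max_iter=1000, random_state=cfg.seed)),
        "DT": DecisionTreeClassifier(criterion="entropy", random_state=cfg.seed),
        "RF": RandomForestClassifier(
            n_estimators=cfg.rf_trees, random_state=cfg.seed, n_jobs=1
        ),
        "SVM": svm,
        "NN": scaled(
            MLPClassifier(
                hidden_layer_sizes=(cfg.nn_hidden,),
                activation="logistic",
                max_iter=2000,
                random_state=cfg.seed,
            )
        ),
    }


def train_classifiers(
    X: pd.DataFrame, y: pd.Series, cfg: ModelConfig | None = None
) -> dict[str, object]:
    """Fit the five classifier families on a (balanced) training set.

    Returns fitted models keyed LR/DT/RF/SVM/NN; a model that fails to
    converge is logged and dropped, the rest proceed.
    """
    cfg = cfg or ModelConfig()
    fitted = {}
    for name, model in _make_models(cfg).items():
        try:
            model.fit(X.to_numpy(dtype=float), y.to_numpy(dtype=int))
            fitted[name] = model
        except Exception as err:  # keep the pipeline alive per model
            logger.warning("model %s failed to fit: %s", name, err)
    if not fitted:
        raise RuntimeError("no classifier could be fitted")
    return fitted


def _scores(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def evaluate(model, X: pd.DataFrame, y: pd.Series, threshold: float = 0.5) -> EvalReport:
    """Confusion-matrix metrics at the probability threshold plus ROC/PR areas.

    Undefined ratios (zero denominators) are reported as NaN, never
    silently zero.
    """
    if len(X) == 0:
        raise ValueError("test set is empty")
    yv = y.astype(bool).to_numpy()
    p = _scores(model, X.to_numpy(dtype=float))
    pred = p > threshold
    TP = int(np.sum(pred & yv))
    TN = int(np.sum(~pred & ~yv))
    FP = int(np.sum(pred & ~yv))
    FN = int(np.sum(~pred & yv))

    def ratio(a: int, b: int) -> float:
        return a / b if b > 0 else float("nan")

    precision = ratio(TP, TP + FP)
    recall = ratio(TP, TP + FN)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0 and np.isfinite(precision) and np.isfinite(recall)
        else float("nan")
    )
    both = yv.any() and (~yv).any()
    return EvalReport(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        accuracy=ratio(TP + TN, TP + TN + FP + FN),
        specificity=ratio(TN, TN + FP),
        precision=precision,
        recall=recall,
        NPV=ratio(TN, TN + FN),
        PPV=ratio(TP, TP + FP),
        f1=f1,
        roc_auc=float(roc_auc_score(yv, p)) if both else float("nan"),
        pr_auc=float(average_precision_score(yv, p)) if both else float("nan"),
    )


def select_best(reports: dict[str, EvalReport]) -> str:
    """Pick the model maximizing (accuracy + F1)/2.

    Ties break by roc_auc, then pr_auc, then the fixed LR/DT/RF/SVM/NN
    order.
    """

    def keyfun(name: str):
        r = reports[name]
        idx = (r.accuracy + r.f1) / 2 if np.isfinite(r.f1) else -np.inf
        return (
            idx,
            r.roc_auc if np.isfinite(r.roc_auc) else -np.inf,
            r.pr_auc if np.isfinite(r.pr_auc) else -np.inf,
            -MODEL_ORDER.index(name),
        )

    names = [m for m in MODEL_ORDER if m in reports]
    return max(names, key=keyfun)


def _rmse(p: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((p - y) ** 2)))


def _logloss(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: pd.Series,
    nperm: int = 10,
    seed: int | None = None,
    *,
    loss: str = "rmse",
) -> pd.DataFrame:
    """Model-agnostic permutation variable importance.

    Baseline loss L0 is the RMSE between predicted class-1 probability and
    the 0/1 label (log-loss via ``loss="logloss"``). For each variable the
    column is shuffled nperm times (seeded; the permutation schedule is
    independent of the model) and vip_diff = mean(L*j - L0). Negative
    values are retained. Returns a frame with columns variable, vip_diff,
    baseline, and perm_1..perm_nperm.
    """
    loss_fn = {"rmse": _rmse, "logloss": _logloss}[loss]
    yv = y.astype(float).to_numpy()
    Xv = X.to_numpy(dtype=float)
    L0 = loss_fn(_scores(model, Xv), yv)
    rng = np.random.default_rng(seed)
    # one shared permutation schedule per repetition, applied column-wise
    perms = [rng.permutation(len(X)) for _ in range(nperm)]
    rows = []
    for j, var in enumerate(X.columns):
        diffs = []
        for perm in perms:
            Xp = Xv.copy()
            Xp[:, j] = Xv[perm, j]
            diffs.append(loss_fn(_scores(model, Xp), yv) - L0)
        rows.append(
            {
                "variable": var,
                "vip_diff": float(np.mean(diffs)),
                "baseline": L0,
                **{f"perm_{k+1}": d for k, d in enumerate(diffs)},
            }
        )
    return pd.DataFrame(rows).sort_values("vip_diff", ascending=False, ignore_index=True)
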