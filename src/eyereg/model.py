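"""Degeneration-class probabilities, the IREG regularity index, and the
model-building pipeline.

The classifier is a five-class multinomial logit with the fully
degenerate class (4) as the reference category.  For feature triple
(DISTM, DISTSKEW, LOGNNVAR) the linear predictors are

    a_i = independent_i + distm_i*DISTM + distskew_i*DISTSKEW
          + lognnvar_i*LOGNNVAR,      i = 0..3,

class probabilities follow the softmax with implicit zero predictor for
class 4, and the regularity index is the probability-weighted ordinal
mean

    IREG = (4*PP_0 + 3*PP_1 + 2*PP_2 + PP_3) / 4  in [0, 1],

1 meaning wild-type regularity and 0 complete degeneration.

Model (re)building follows a statsmodels-style Model/Results split:
:class:`RegularityModel` wraps a feature table and exposes the pipeline
steps (correlation pruning, ANOVA screening, PCA-based class
assignment, stepwise selection, multinomial fitting);
:meth:`RegularityModel.fit` returns a :class:`RegularityResults`
carrying coefficients, standard errors, diagnostics and prediction
methods.  :func:`builtin_results` loads the shipped coefficients.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES, ModelFeatures

MODEL_VARS = ["DISTM", "DISTSKEW", "LOGNNVAR"]
CLASS_LABELS = [0, 1, 2, 3, 4]
PARAM_COLUMNS = ["independent", "distm", "distskew", "lognnvar"]


# ---------------------------------------------------------------------------
# parameters / probabilities / IREG
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """4x4 coefficient matrix of the five-class logit (class 4 reference).

    ``coefficients`` rows are classes 0..3, columns
    (independent, distm, distskew, lognnvar); class 4 carries the
    implicit all-zero row, so the model has exactly 16 free parameters.
    """

    coefficients: np.ndarray
    version: str = "builtin"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4, 4):
            raise ValueError("coefficient matrix must be 4x4 (classes 0-3 x "
                             "intercept + 3 slopes)")

    @property
    def n_free(self) -> int:
        return self.coefficients.size

    def as_frame(self) -> pd.DataFrame:
        """Coefficients in the published layout, including the zero row."""
        full = np.vstack([self.coefficients, np.zeros(4)])
        return pd.DataFrame(full, index=pd.Index(CLASS_LABELS, name="class"),
                            columns=PARAM_COLUMNS)

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        payload = json.loads(Path(path).read_text())
        rows = [
            [payload["coefficients"][str(i)][c] for c in PARAM_COLUMNS]
            for i in range(4)
        ]
        return cls(np.asarray(rows), version=str(payload.get("version", "?")))


def builtin_parameters() -> ModelParameters:
    """The shipped coefficient matrix of the built-in classifier."""
    ref = importlib.resources.files("eyereg.data") / "coefficients_v1.json"
    with importlib.resources.as_file(ref) as path:
        return ModelParameters.from_json(path)


@dataclass
class ClassProbabilities:
    """The five degeneration-class probabilities PP_0..PP_4."""

    pp: np.ndarray

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("need exactly 5 class probabilities")
        if (self.pp < -1e-9).any() or abs(self.pp.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must form a simplex")


@dataclass
class IregScore:
    """The regularity index in [0, 1]."""

    ireg: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.ireg <= 1 + 1e-12):
            raise ValueError("IREG must lie in [0, 1]")
        self.ireg = float(min(max(self.ireg, 0.0), 1.0))


def _as_triple(features) -> np.ndarray:
    if isinstance(features, ModelFeatures):
        return features.as_array()
    arr = np.asarray(features, dtype=float).reshape(3)
    return arr


def linear_predictors(features, params: ModelParameters | None = None) -> np.ndarray:
    """The four linear predictors a_0..a_3 for one feature triple."""
    params = params or builtin_parameters()
    x = _as_triple(features)
    if not np.isfinite(x).all():
        raise ValueError("model features must be finite")
    return params.coefficients[:, 0] + params.coefficients[:, 1:] @ x


def class_probabilities(features, params: ModelParameters | None = None) -> ClassProbabilities:
    """Five class probabilities via the overflow-safe softmax.

    PP_i = exp(a_i) / (sum_j exp(a_j) + 1) for i = 0..3 and
    PP_4 = 1 / (sum_j exp(a_j) + 1); the class-4 predictor is the
    implicit zero.  Computed with max-subtraction so extreme predictors
    cannot overflow.
    """
    a = np.append(linear_predictors(features, params), 0.0)
    a -= a.max()
    e = np.exp(a)
    return ClassProbabilities(e / e.sum())


def ireg(pp: ClassProbabilities | np.ndarray) -> IregScore:
    """Probability-weighted regularity index (4,3,2,1,0 weights over 4)."""
    p = pp.pp if isinstance(pp, ClassProbabilities) else np.asarray(pp, float)
    return IregScore(float((4 * p[0] + 3 * p[1] + 2 * p[2] + p[3]) / 4.0))


def ireg_from_features(features, params: ModelParameters | None = None) -> float:
    """Convenience: feature triple -> IREG in one call."""
    return ireg(class_probabilities(features, params)).ireg


# ---------------------------------------------------------------------------
# training table
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Per-image feature rows with optional group labels and classes.

    ``data`` holds the 18 feature columns (mnemonic names); ``group``
    (optional) an external grouping such as genotype; ``cls`` the
    assigned degeneration class 0-4; ``train`` the split flag.
    """

    data: pd.DataFrame
    group: pd.Series | None = None
    cls: pd.Series | None = None
    train: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")
        if self.cls is not None and not set(self.cls.unique()) <= set(CLASS_LABELS):
            raise ValueError("class labels must be in 0..4")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def prune_correlated(data: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy elimination of highly correlated variables.

    While any pair of remaining variables has |Pearson r| above the
    threshold, the member of the worst pair with the larger mean
    absolute correlation to all remaining variables is dropped.  Ties
    are broken by column order, so the procedure is deterministic.
    Constant columns are dropped first with a warning.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 rows for correlation pruning")
    cols = list(data.columns)
    const = [c for c in cols if data[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant columns before pruning: {const}")
        cols = [c for c in cols if c not in const]
    while True:
        corr = data[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = cols[i], cols[j]
        mean_a = corr.loc[a].mean()
        mean_b = corr.loc[b].mean()
        drop = a if mean_a > mean_b else b if mean_b > mean_a else max(
            (a, b), key=cols.index)
        cols.remove(drop)
        if len(cols) == 1:
            break
    return cols


def anova_screen(data: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way ANOVA per variable against the group labels.

    Returns the published report layout: between/within/total sum of
    squares, degrees of freedom (k-1, N-k, N-1), mean squares, F ratio
    (between MS over within MS) and its upper-tail p-value.
    """
    groups = pd.Series(groups).reset_index(drop=True)
    data = data.reset_index(drop=True)
    uniq = groups.unique()
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 rows")
    n = len(data)
    k = len(uniq)
    rows = []
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        grand = x.mean()
        ss_b = sum(((x[groups == g].mean() - grand) ** 2) * (groups == g).sum()
                   for g in uniq)
        ss_w = sum(((x[groups == g] - x[groups == g].mean()) ** 2).sum()
                   for g in uniq)
        ms_b = ss_b / (k - 1)
        ms_w = ss_w / (n - k)
        f = np.inf if ms_w == 0 and ms_b > 0 else (0.0 if ms_b == 0 else ms_b / ms_w)
        p = 0.0 if np.isinf(f) else float(sps.f.sf(f, k - 1, n - k))
        rows.append({"variable": col, "ss_between": ss_b, "ss_within": ss_w,
                     "ss_total": ss_b + ss_w, "df_between": k - 1,
                     "df_within": n - k, "ms_between": ms_b, "ms_within": ms_w,
                     "F": f, "p": p})
    return pd.DataFrame(rows).set_index("variable")


def pca_cluster(data: pd.DataFrame, n_classes: int = 5,
                random_state: int = 0,
                orient_by: str = "DISTM") -> tuple[pd.Series, np.ndarray]:
    """Assign ordered degeneration classes from first-principal-component scores.

    Variables are z-scored (correlation-matrix PCA); PC1 scores are
    clustered 1-D with k-means (k-means++ seeding at a fixed state),
    clusters ordered along PC1 and relabelled so class 0 is the regular
    end — the end with the lower mean of ``orient_by`` (cell-centroid
    distance rises with disorder).  Returns the labels and the
    explained-variance fractions of all components.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if len(data) < n_classes:
        raise ValueError("fewer rows than requested classes")
    z = (data - data.mean()) / data.std(ddof=1).replace(0.0, 1.0)
    # higher moments are undefined for sparsely occupied grids; treat
    # missing entries as neutral (column mean) rather than dropping rows
    z = z.fillna(0.0)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    pc1 = scores[:, 0]
    if n_classes == 1:
        return (pd.Series(np.zeros(len(data), dtype=int), index=data.index),
                pca.explained_variance_ratio_)
    if len(np.unique(pc1)) < n_classes:
        raise ValueError("fewer distinct PC1 scores than classes")
    km = KMeans(n_clusters=n_classes, n_init=10, random_state=random_state)
    raw = km.fit_predict(pc1.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(n_classes, dtype=int)
    relabel[order] = np.arange(n_classes)
    labels = relabel[raw]
    if orient_by in data.columns:
        lo = data.loc[labels == 0, orient_by].mean()
        hi = data.loc[labels == n_classes - 1, orient_by].mean()
        if lo > hi:  # regular end must be class 0
            labels = (n_classes - 1) - labels
    return (pd.Series(labels, index=data.index),
            pca.explained_variance_ratio_)


def _mnlogit_fit(X: np.ndarray, y: np.ndarray):
    """Fit a multinomial logit with class 4 as reference via statsmodels.

    Classes are relabelled (c + 1) mod 5 so the reference category (the
    lowest label, 0 after relabelling) is the fully degenerate class;
    equation j of the fit then corresponds to original class j - 1.
    """
    import statsmodels.api as sm

    y_ref4 = (np.asarray(y, dtype=int) + 1) % 5
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.MNLogit(y_ref4, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=200, disp=False)
        if not np.isfinite(np.asarray(res.params)).all():
            # Newton diverges on (quasi-)separated data; the gradient
            # methods walk along the separating direction instead
            res = model.fit(method="lbfgs", maxiter=500, disp=False)
    return res


def fit_multinomial(table: TrainingTable, selected_vars: list[str] | None = None
                    ) -> "RegularityResults":
    """Maximum-likelihood multinomial logit on the training split.

    Requires all five classes in the training rows; evaluates held-out
    accuracy on the test split when one is defined.  Perfect or quasi-
    perfect separation is flagged (coefficients are still reported).
    """
    selected_vars = selected_vars or MODEL_VARS
    if not selected_vars:
        raise ValueError("selected_vars must be non-empty")
    if table.cls is None:
        raise ValueError("training table has no class labels")
    train_mask = (table.train if table.train is not None
                  else pd.Series(True, index=table.data.index))
    y = table.cls[train_mask].to_numpy(dtype=int)
    if set(np.unique(y)) != set(CLASS_LABELS):
        raise ValueError("all 5 classes must be represented in the training split")
    X = table.data.loc[train_mask, selected_vars].to_numpy(dtype=float)
    res = _mnlogit_fit(X, y)

    p = len(selected_vars)
    coef = np.zeros((4, p + 1))
    bse = np.zeros((4, p + 1))
    # statsmodels params: (k_vars, n_eq); equation j -> original class j-1... see _mnlogit_fit
    params = np.asarray(res.params)
    try:
        errs = np.asarray(res.bse)
    except (ValueError, np.linalg.LinAlgError):
        # singular Hessian (separated data): no finite standard errors
        errs = np.full_like(params, np.nan)
    for eq in range(4):
        coef[eq, :] = params[:, eq]
        bse[eq, :] = errs[:, eq]

    # separation heuristics: runaway coefficients or standard errors far
    # beyond anything a finite-MLE multinomial on these features yields
    separated = bool(
        not np.isfinite(coef).all() or not np.isfinite(bse).all()
        or np.abs(coef).max() > 150.0 or bse.max() > 50.0
        or not res.mle_retvals.get("converged", True))
    if separated:
        warnings.warn("possible (quasi-)separation: very large coefficients "
                      "or non-converged fit; interpret with caution")

    accuracy = None
    if table.train is not None and (~table.train).any():
        Xt = table.data.loc[~table.train, selected_vars].to_numpy(dtype=float)
        yt = table.cls[~table.train].to_numpy(dtype=int)
        acc_pred = _predict_classes(coef, Xt)
        accuracy = float((acc_pred == yt).mean())

    return RegularityResults(
        coef=coef, bse=bse, var_names=list(selected_vars),
        llf=float(res.llf), n_obs=int(len(y)), converged=not separated,
        separation_flag=separated, holdout_accuracy=accuracy,
    )


def _predict_classes(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    a = coef[:, 0][None, :] + X @ coef[:, 1:].T  # (n, 4)
    a5 = np.concatenate([a, np.zeros((len(X), 1))], axis=1)
    return np.argmax(a5, axis=1)


def stepwise_select(table: TrainingTable, candidate_vars: list[str],
                    p_enter: float = 0.05, p_remove: float = 0.10) -> list[str]:
    """Forward stepwise selection on the multinomial likelihood.

    At each step the candidate with the smallest likelihood-ratio
    p-value below ``p_enter`` joins the model; after each entry,
    included variables whose LR p-value has risen above ``p_remove``
    are removed.  Deterministic given the table.
    """
    if len(candidate_vars) < 1:
        raise ValueError("need at least one candidate")
    if table.cls is None:
        raise ValueError("training table has no class labels")
    train_mask = (table.train if table.train is not None
                  else pd.Series(True, index=table.data.index))
    y = table.cls[train_mask].to_numpy(dtype=int)
    df_per_var = len(np.unique(y)) - 1

    def llf_for(varlist: list[str]) -> float:
        if not varlist:
            # intercept-only log-likelihood
            counts = np.bincount((y + 1) % 5, minlength=5)
            pr = counts / counts.sum()
            return float(np.sum(counts[counts > 0] * np.log(pr[counts > 0])))
        X = table.data.loc[train_mask, varlist].to_numpy(dtype=float)
        return float(_mnlogit_fit(X, y).llf)

    selected: list[str] = []
    ll_cur = llf_for(selected)
    while True:
        remaining = [v for v in candidate_vars if v not in selected]
        if not remaining:
            break
        best_v, best_p, best_ll = None, 1.0, ll_cur
        for v in remaining:
            ll_new = llf_for(selected + [v])
            lr = max(0.0, 2 * (ll_new - ll_cur))
            p = float(sps.chi2.sf(lr, df_per_var))
            if p < best_p or (p == best_p and best_v is None):
                best_v, best_p, best_ll = v, p, ll_new
        if best_v is None or best_p >= p_enter:
            break
        selected.append(best_v)
        ll_cur = best_ll
        # backward pass
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for v in list(selected):
                rest = [s for s in selected if s != v]
                ll_rest = llf_for(rest)
                lr = max(0.0, 2 * (ll_cur - ll_rest))
                p = float(sps.chi2.sf(lr, df_per_var))
                if p > p_remove:
                    selected.remove(v)
                    ll_cur = ll_rest
                    changed = True
                    break
    if not selected:
        warnings.warn("no candidate passed the entry threshold")
    return selected


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class RegularityModel:
    """Multinomial regularity classifier built from a feature table.

    Parameters
    ----------
    table
        A :class:`TrainingTable` (or a DataFrame with the 18 feature
        columns, optionally ``group``/``class``/``train`` columns).

    The pipeline methods mirror the model-development procedure:
    :meth:`prune` (correlation pruning), :meth:`screen` (per-variable
    ANOVA), :meth:`assign_classes` (PC1 clustering into five ordered
    classes), :meth:`select` (stepwise variable selection) and
    :meth:`fit` (multinomial logit, class 4 reference).
    """

    def __init__(self, table: TrainingTable):
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegularityModel":
        group = df["group"] if "group" in df else None
        cls_col = df["class"] if "class" in df else None
        train = df["train"].astype(bool) if "train" in df else None
        data = df[FEATURE_NAMES]
        return cls(TrainingTable(data=data, group=group, cls=cls_col, train=train))

    def prune(self, threshold: float = 0.9) -> list[str]:
        return prune_correlated(self.table.data, threshold)

    def screen(self, variables: list[str] | None = None) -> pd.DataFrame:
        if self.table.cls is None and self.table.group is None:
            raise ValueError("no grouping available for ANOVA")
        groups = self.table.cls if self.table.cls is not None else self.table.group
        cols = variables or list(self.table.data.columns)
        return anova_screen(self.table.data[cols], groups)

    def assign_classes(self, variables: list[str] | None = None,
                       n_classes: int = 5, random_state: int = 0) -> pd.Series:
        cols = variables or self.prune()
        labels, evr = pca_cluster(self.table.data[cols], n_classes, random_state)
        self.table.cls = labels
        self.explained_variance_ratio_ = evr
        return labels

    def split(self, train_fraction: float = 0.7, seed: int = 0) -> pd.Series:
        """Random train/test division, stratification-free, reproducible."""
        rng = np.random.default_rng(seed)
        n = len(self.table)
        idx = rng.permutation(n)
        flags = np.zeros(n, dtype=bool)
        flags[idx[: int(round(train_fraction * n))]] = True
        self.table.train = pd.Series(flags, index=self.table.data.index)
        return self.table.train

    def select(self, candidate_vars: list[str] | None = None,
               p_enter: float = 0.05, p_remove: float = 0.10) -> list[str]:
        cands = candidate_vars or self.prune()
        return stepwise_select(self.table, cands, p_enter, p_remove)

    def fit(self, selected_vars: list[str] | None = None) -> "RegularityResults":
        return fit_multinomial(self.table, selected_vars or MODEL_VARS)


@dataclass
class RegularityResults:
    """Fitted (or built-in) regularity classifier.

    ``coef`` is the 4 x (1 + p) coefficient matrix (classes 0..3 vs
    reference class 4; first column the intercept), ``bse`` the matching
    standard errors (zero for the built-in coefficients, whose errors
    were not published).
    """

    coef: np.ndarray
    bse: np.ndarray
    var_names: list[str] = field(default_factory=lambda: list(MODEL_VARS))
    llf: float = float("nan")
    n_obs: int = 0
    converged: bool = True
    separation_flag: bool = False
    holdout_accuracy: float | None = None
    version: str = "fitted"

    @classmethod
    def from_parameters(cls, params: ModelParameters) -> "RegularityResults":
        return cls(coef=params.coefficients.copy(),
                   bse=np.zeros_like(params.coefficients),
                   version=params.version)

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients in the published layout (5 rows, zero reference row)."""
        return ModelParameters(self.coef, self.version).as_frame()

    def to_parameters(self) -> ModelParameters:
        return ModelParameters(self.coef.copy(), version=self.version)

    def predict_proba(self, features) -> np.ndarray:
        """Class probabilities for one triple or an (n, 3) array."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        a = self.coef[:, 0][None, :] + X @ self.coef[:, 1:].T
        a5 = np.concatenate([a, np.zeros((len(X), 1))], axis=1)
        a5 -= a5.max(axis=1, keepdims=True)
        e = np.exp(a5)
        return e / e.sum(axis=1, keepdims=True)

    def predict_ireg(self, features) -> np.ndarray:
        """IREG for one feature triple or an (n, 3) array."""
        p = self.predict_proba(features)
        return (4 * p[:, 0] + 3 * p[:, 1] + 2 * p[:, 2] + p[:, 3]) / 4.0

    def summary(self) -> str:
        """Human-readable coefficient table with uncertainties."""
        lines = ["Regularity classifier (multinomial logit, reference class 4)",
                 f"  n_obs: {self.n_obs}   log-likelihood: {self.llf:.3f}"
                 if self.n_obs else f"  coefficients: {self.version}"]
        if self.holdout_accuracy is not None:
            lines.append(f"  held-out accuracy: {self.holdout_accuracy:.3f}")
        if self.separation_flag:
            lines.append("  WARNING: possible separation; estimates unstable")
        hdr = ["class"] + ["independent"] + self.var_names
        lines.append("  " + "  ".join(f"{h:>12}" for h in hdr))
        for i in range(4):
            row = [f"{i:>12}"] + [f"{v:12.3f}" for v in self.coef[i]]
            lines.append("  " + "  ".join(row))
            if self.bse.any():
                se = [" " * 12] + [f"({s:10.3f})" for s in self.bse[i]]
                lines.append("  " + "  ".join(se))
        lines.append("  " + "  ".join([f"{4:>12}"] + [f"{0.0:12.3f}"] *
                                      (len(self.var_names) + 1)))
        return "\n".join(lines)


def builtin_results() -> RegularityResults:
    """The shipped classifier as a ready-to-use results object."""
    return RegularityResults.from_parameters(builtin_parameters())


# ---------------------------------------------------------------------------
# robustness and group statistics
# ---------------------------------------------------------------------------

def robustness_check(table: TrainingTable, n_splits: int = 3, seed: int = 0,
                     train_fraction: float = 0.7,
                     selected_vars: list[str] | None = None) -> pd.DataFrame:
    """Refit across random train/test divisions and compare group IREG.

    Returns one row per (split, group) with the group's mean IREG; the
    across-split spread of each group's mean quantifies the dependence
    of the index on the particular training set.  With ``n_splits`` = 1
    the dispersion is undefined (single fit).
    """
    if table.cls is None:
        raise ValueError("assign classes before the robustness check")
    groups = table.group if table.group is not None else table.cls
    selected_vars = selected_vars or MODEL_VARS
    rows = []
    rng = np.random.default_rng(seed)
    n = len(table)
    for s in range(n_splits):
        split_seed = int(rng.integers(0, 2**31 - 1))
        model = RegularityModel(TrainingTable(
            data=table.data, group=table.group, cls=table.cls))
        model.split(train_fraction, seed=split_seed)
        res = model.fit(selected_vars)
        iregs = res.predict_ireg(table.data[selected_vars].to_numpy(dtype=float))
        for g in pd.Series(groups).unique():
            sel = (pd.Series(groups).to_numpy() == g)
            rows.append({"split": s, "group": g,
                         "mean_ireg": float(iregs[sel].mean())})
    return pd.DataFrame(rows)


def dispersion_summary(per_split: pd.DataFrame) -> dict:
    """Across-split and between-group dispersion of mean IREG."""
    pivot = per_split.pivot(index="group", columns="split", values="mean_ireg")
    across = float((pivot.max(axis=1) - pivot.min(axis=1)).max())
    grand = pivot.mean(axis=1)
    between = float(grand.max() - grand.min())
    return {"max_across_split_diff": across if pivot.shape[1] > 1 else float("nan"),
            "between_group_diff": between}


def compare_groups(ireg_values: dict[str, np.ndarray],
                   adjust: str = "none") -> dict:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc z tests.

    Dunn's z uses the rank-sum statistic with tie correction;
    ``adjust`` is one of none / bonferroni / holm.  Pairs are flagged
    significant at p < 0.05 after adjustment.
    """
    names = list(ireg_values)
    samples = [np.asarray(ireg_values[g], dtype=float) for g in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(samples)
    if np.all(all_vals == all_vals[0]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*samples)

    # Dunn's test
    n_tot = len(all_vals)
    ranks = sps.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_tot - 1))
    splits = np.cumsum([len(s) for s in samples])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = {g: r.mean() for g, r in zip(names, group_ranks)}
    sizes = {g: len(ireg_values[g]) for g in names}
    pairs = []
    raw_ps = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            var = (n_tot * (n_tot + 1) / 12.0 - tie_term) * \
                  (1.0 / sizes[gi] + 1.0 / sizes[gj])
            z = 0.0 if var == 0 else (mean_ranks[gi] - mean_ranks[gj]) / np.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
            pairs.append({"a": gi, "b": gj, "z": float(z), "p": p})
            raw_ps.append(p)
    m = len(raw_ps)
    if adjust == "bonferroni":
        adj = [min(1.0, p * m) for p in raw_ps]
    elif adjust == "holm":
        order = np.argsort(raw_ps)
        adj = [0.0] * m
        running = 0.0
        for k, oi in enumerate(order):
            running = max(running, min(1.0, (m - k) * raw_ps[oi]))
            adj[oi] = running
    elif adjust == "none":
        adj = list(raw_ps)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for pair, ap in zip(pairs, adj):
        pair["p_adjusted"] = ap
        pair["significant"] = ap < 0.05
    return {"H": float(h), "p": float(p_omni), "pairwise": pairs}
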