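"""Feature screening, stratification, group tests and the correlation network.

Seven candidate biophoton parameters per sample (A, B, C, I0, Iw, T, CPS;
the strength indicators geometry-normalized) are screened for
stress-discriminative value with cross-validated L1-penalized (LASSO)
logistic regression, choosing the penalty by the minimum-CV-deviance and
one-standard-error rules.  Group separation is visualized with PCA on the
selected parameters; group differences use the two-tailed unpaired
Student's t-test (P <= 0.05); relationships between photon parameters and
quality endpoints are summarized as a Spearman correlation network whose
edges carry rho, P and sign (solid/dotted in the conventional rendering).
A simple pharmacopoeial rule classifies group quality by indirubin content
(standard: >= 0.02%).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .core import InsufficientDataError

__all__ = [
    "FEATURE_COLUMNS",
    "ScreeningResult",
    "TTestResult",
    "CorrelationNetwork",
    "lasso_screen",
    "pca_stratify",
    "group_ttest",
    "spearman_rho_p",
    "spearman_network",
    "classify_quality",
]

#: canonical candidate-parameter columns of a feature table
FEATURE_COLUMNS = ("A", "B", "C", "I0", "Iw", "T", "CPS")


# ---------------------------------------------------------------------------
# LASSO screening


@dataclass
class ScreeningResult:
    """Cross-validated LASSO path with penalty selections.

    ``cv_mean``/``cv_se`` hold the CV loss (binomial deviance or MSE) per
    penalty; coefficient tables are on the standardized scale with the
    original-scale equivalents alongside.
    """

    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    coef_path: pd.DataFrame            # rows = lambdas, cols = features (standardized scale)
    coefficients_min: pd.DataFrame     # feature, coef_std, coef_raw
    coefficients_1se: pd.DataFrame
    selected_min: list
    selected_1se: list
    feature_names: list
    family: str = "binomial"

    def __post_init__(self) -> None:
        assert self.lambda_1se >= self.lambda_min


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_l1(X, y, lam, family):
    n = X.shape[0]
    if family == "binomial":
        model = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam),
                                   solver="liblinear", tol=1e-8, max_iter=5000,
                                   random_state=0)
        model.fit(X, y)
        return model.coef_.ravel(), float(model.intercept_[0])
    model = Lasso(alpha=lam, tol=1e-10, max_iter=100000)
    model.fit(X, y)
    return model.coef_.ravel(), float(model.intercept_)


def lasso_screen(
    table: pd.DataFrame,
    response: np.ndarray | pd.Series,
    k_folds: int = 10,
    seed: int = 0,
    feature_columns: tuple | None = None,
    family: str = "binomial",
    n_lambda: int = 60,
    lambda_min_ratio: float = 1e-3,
) -> ScreeningResult:
    """Screen discriminative features with cross-validated LASSO.

    Features are standardized internally (mean 0, SD 1 with n in the
    denominator, so a univariate Gaussian fit reduces to the classical
    soft-threshold form).  The penalty grid is log-spaced from the smallest
    lambda that zeroes every coefficient down to ``lambda_min_ratio`` times
    it; stratified k-fold CV scores each lambda by held-out binomial
    deviance (or MSE for the Gaussian variant).  ``lambda_min`` minimizes
    the mean CV loss and ``lambda_1se`` is the largest penalty within one
    standard error of that minimum — the parsimonious 1-SE choice.
    """
    if feature_columns is None:
        feature_columns = [c for c in table.columns
                           if c in FEATURE_COLUMNS or
                           (c not in ("sample_id", "group") and
                            pd.api.types.is_numeric_dtype(table[c]))]
    X_raw = table[list(feature_columns)].to_numpy(dtype=float)
    y = np.asarray(response)
    if family == "binomial":
        classes = np.unique(y)
        if classes.size != 2:
            raise InsufficientDataError("binary response required for binomial screening")
        y = (y == classes[1]).astype(float)
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise InsufficientDataError("need at least 2 samples per class")

    # drop constant features with a warning
    sd = X_raw.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_columns, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        feature_columns = [f for f, k in zip(feature_columns, keep) if k]
        X_raw, sd = X_raw[:, keep], sd[keep]
    if X_raw.shape[1] == 0:
        raise InsufficientDataError("no non-constant features to screen")

    mean = X_raw.mean(axis=0)
    X = (X_raw - mean) / sd
    n = X.shape[0]

    # glmnet-style lambda_max: smallest penalty with an all-zero solution
    resid0 = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ resid0)) / n)
    lam_max = max(lam_max, 1e-10)
    lambdas = np.geomspace(lam_max * 1.001, lam_max * lambda_min_ratio, n_lambda)

    if family == "binomial":
        k_eff = min(k_folds, int(min((y == 0).sum(), (y == 1).sum())))
    else:
        k_eff = min(k_folds, n)
    if k_eff < k_folds:
        warnings.warn(f"reducing CV folds from {k_folds} to {k_eff} "
                      "(limited by class size)", stacklevel=2)
    splitter = (StratifiedKFold(k_eff, shuffle=True, random_state=seed)
                if family == "binomial"
                else KFold(k_eff, shuffle=True, random_state=seed))
    folds = list(splitter.split(X, y))
    losses = np.empty((len(folds), n_lambda))
    for i, (tr, te) in enumerate(folds):
        for j, lam in enumerate(lambdas):
            coef, icpt = _fit_l1(X[tr], y[tr], lam, family)
            eta = X[te] @ coef + icpt
            if family == "binomial":
                losses[i, j] = _binomial_deviance(y[te], 1.0 / (1.0 + np.exp(-eta)))
            else:
                losses[i, j] = float(np.mean((y[te] - eta) ** 2))

    cv_mean = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / math.sqrt(len(folds))
    j_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[j_min])
    within = cv_mean <= cv_mean[j_min] + cv_se[j_min]
    lambda_1se = float(lambdas[within].max())

    coef_path = np.array([_fit_l1(X, y, lam, family)[0] for lam in lambdas])

    def _coef_table(lam):
        coef_std, _ = _fit_l1(X, y, lam, family)
        coef_raw = coef_std / sd
        return pd.DataFrame({"feature": feature_columns,
                             "coef_std": coef_std, "coef_raw": coef_raw})

    tab_min = _coef_table(lambda_min)
    tab_1se = _coef_table(lambda_1se)
    nz = lambda t: [f for f, c in zip(t.feature, t.coef_std) if abs(c) > 1e-8]
    return ScreeningResult(
        lambda_path=lambdas, cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=lambda_min, lambda_1se=lambda_1se,
        coef_path=pd.DataFrame(coef_path, columns=feature_columns),
        coefficients_min=tab_min, coefficients_1se=tab_1se,
        selected_min=nz(tab_min), selected_1se=nz(tab_1se),
        feature_names=list(feature_columns), family=family,
    )


# ---------------------------------------------------------------------------
# PCA stratification


def pca_stratify(table: pd.DataFrame, features: tuple, n_components: int | None = None):
    """Centered-and-scaled PCA on a feature subset.

    Returns (scores, explained) where ``scores`` is a per-sample data frame
    of component scores (with any sample_id/group columns carried through)
    and ``explained`` the explained-variance fractions.
    """
    features = list(features)
    if len(features) < 2:
        raise InsufficientDataError("need at least 2 features for PCA")
    X = table[features].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise InsufficientDataError("need at least 3 samples for PCA")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature in PCA input")
    Z = (X - X.mean(axis=0)) / sd
    k = n_components or min(Z.shape)
    pca = PCA(n_components=min(k, *Z.shape))
    scores = pca.fit_transform(Z)
    out = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
                       index=table.index)
    for col in ("sample_id", "group"):
        if col in table.columns:
            out.insert(0, col, table[col])
    return out, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Group tests


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


def group_ttest(x, y, equal_var: bool = True) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance by default;
    Welch with ``equal_var=False``).

    Degenerate convention: zero pooled variance with equal means gives
    t = 0, P = 1 (no evidence against equality); with unequal means the
    difference is infinitely many SEs, t = +/-inf, P = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need at least 2 values per group")
    if equal_var:
        df = x.size + y.size - 2
    else:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = ((vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
              if vx + vy > 0 else x.size + y.size - 2)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, float(df), 1.0)
        return TTestResult(math.copysign(float("inf"), x.mean() - y.mean()), float(df), 0.0)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


# ---------------------------------------------------------------------------
# Spearman correlation network


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom if denom > 0 else float("nan")


def spearman_rho_p(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided P value.

    For n <= ``exact_max_n`` the P value is an exact permutation test —
    the fraction of all n! pairings whose |rho| is at least the observed
    |rho|; larger samples use the asymptotic t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise InsufficientDataError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        norm_x = math.sqrt(float(rxc @ rxc))
        norm_y = math.sqrt(float(ryc @ ryc))
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = (perms @ rxc) / (norm_x * norm_y)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


@dataclass
class CorrelationNetwork:
    """Parameter-endpoint association network.

    ``edges`` lists every tested pair with rho, P, sign and an
    ``included`` flag (P <= threshold); ``graph`` holds only the included
    edges, with node ``kind`` attributes (parameter vs endpoint) and edge
    attributes rho, p, sign and abs_rho — sign drives the solid (positive)
    versus dotted (negative) line convention, |rho| the line width.
    """

    edges: pd.DataFrame
    graph: nx.Graph
    threshold: float = 0.05

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def edge_list(self) -> pd.DataFrame:
        cols = ["source", "target", "rho", "p", "sign"]
        return self.edges.loc[self.edges["included"], cols].reset_index(drop=True)


def spearman_network(
    parameters: pd.DataFrame,
    endpoints: pd.DataFrame,
    threshold: float = 0.05,
) -> CorrelationNetwork:
    """Build the Spearman network between photon parameters and endpoints.

    Both inputs are per-sample numeric data frames aligned on their index;
    every parameter-endpoint pair is tested and pairs with P <= threshold
    become edges.  Constant columns are skipped with a warning.
    """
    idx = parameters.index.intersection(endpoints.index)
    if idx.size < 4:
        raise InsufficientDataError("need at least 4 aligned samples")
    P = parameters.loc[idx]
    E = endpoints.loc[idx]
    rows = []
    for pcol in P.columns:
        for ecol in E.columns:
            pair = pd.concat([P[pcol], E[ecol]], axis=1).dropna()
            if pair.shape[0] < 4:
                warnings.warn(f"skipping {pcol}~{ecol}: fewer than 4 paired values",
                              stacklevel=2)
                continue
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                warnings.warn(f"skipping {pcol}~{ecol}: constant vector", stacklevel=2)
                continue
            rho, p = spearman_rho_p(x, y)
            rows.append({"source": pcol, "target": ecol, "rho": rho, "p": p,
                         "sign": int(np.sign(rho)), "n": pair.shape[0],
                         "included": p <= threshold})
    edges = pd.DataFrame(rows)
    g = nx.Graph()
    for c in P.columns:
        g.add_node(c, kind="parameter")
    for c in E.columns:
        g.add_node(c, kind="endpoint")
    for r in rows:
        if r["included"]:
            g.add_edge(r["source"], r["target"], rho=r["rho"], p=r["p"],
                       sign=r["sign"], abs_rho=abs(r["rho"]))
    return CorrelationNetwork(edges=edges, graph=g, threshold=threshold)


# ---------------------------------------------------------------------------
# Quality classification


def classify_quality(
    content_table: pd.DataFrame,
    threshold: float = 0.02,
    column: str = "indirubin",
) -> pd.DataFrame:
    """Pharmacopoeial pass/fail on indirubin content (% w/w).

    A group passes iff its content is at or above the standard (the
    boundary value itself passes).  Input may be per-group or per-sample;
    if a ``group`` column is present, group means are classified.
    """
    if column not in content_table.columns:
        raise KeyError(f"missing {column!r} column")
    df = content_table
    if "group" in df.columns:
        df = df.groupby("group", sort=False)[column].mean().reset_index()
    if (df[column] < 0).any():
        raise ValueError("contents must be non-negative")
    out = df.copy()
    out["passes"] = out[column] >= threshold
    return out
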