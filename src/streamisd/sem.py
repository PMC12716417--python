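"""Piecewise path analysis of trait, flow and land-use effects on the ISD exponent.

The causal hypothesis is layered: land use alters flow regimes, altered flow
filters community traits, and traits set the size-spectrum exponent ``b``.
Each endogenous variable gets its own linear submodel ("piecewise" SEM); the
fixed effects entering each submodel are chosen by bidirectional stepwise
AIC with natural control variables (drainage area, ecoregion) always
retained.  Global fit is judged by Shipley's test of directed separation:
every conditional-independence claim implied by the missing edges is tested,
and the claim p-values are pooled with Fisher's C,

    C = -2 * sum(ln p_i)  ~  chi-square with 2k df under the model,

so a *non*-significant C indicates the data are consistent with the modelled
structure.  Standardized direct effects are the path coefficients; indirect
effects sum the coefficient products over all directed paths; total = direct
+ indirect.

All variables enter standardized (z-scored after optional log transforms),
so coefficients are comparable across paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "standardize_table",
    "stepwise_aic_select",
    "Submodel",
    "PathModel",
    "assemble_path_model",
    "directed_separation_tests",
    "fishers_c",
    "decompose_effects",
    "PiecewisePathModel",
]

_P_FLOOR = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# variable preparation


def standardize_table(
    raw: pd.DataFrame,
    categorical: tuple[str, ...] = (),
    skew_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normality transforms plus z-scoring.

    Numeric columns with ``|skewness| > skew_threshold`` are log-transformed
    (``log(x+1)`` when zeros are present, ``log(x)`` otherwise) and every
    numeric column is then z-scored to mean 0, SD 1.  Categorical columns
    pass through untouched.  Constant columns, or negative values in a
    column slated for the log, are errors.

    Returns the transformed frame and a per-column report
    (column, skewness, transform, mean, sd).
    """
    out = raw.copy()
    report = []
    for col in raw.columns:
        if col in categorical:
            report.append({"column": col, "skewness": np.nan, "transform": "categorical",
                           "mean": np.nan, "sd": np.nan})
            continue
        x = raw[col].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"missing values in column {col!r}")
        sd0 = x.std()
        if sd0 == 0:
            raise ValueError(f"column {col!r} is constant")
        skew = float(stats.skew(x))
        transform = "none"
        if abs(skew) > skew_threshold:
            if np.any(x < 0):
                raise ValueError(
                    f"column {col!r} is skewed ({skew:.2f}) but has negative values; "
                    "log transform undefined"
                )
            if np.any(x == 0):
                x = np.log1p(x)
                transform = "log1p"
            else:
                x = np.log(x)
                transform = "log"
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError(f"column {col!r} constant after transform")
        out[col] = (x - mu) / sd
        report.append({"column": col, "skewness": skew, "transform": transform,
                       "mean": mu, "sd": sd})
    return out, pd.DataFrame(report)


def expand_categoricals(
    frame: pd.DataFrame, categorical: tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-code categorical columns (first level alphabetically = reference).

    Returns the expanded frame and a map term -> dummy column names.
    """
    groups: dict[str, list[str]] = {}
    out = frame.copy()
    for col in categorical:
        levels = sorted(map(str, frame[col].unique()))
        dummies = []
        for lev in levels[1:]:
            name = f"{col}_{lev}"
            out[name] = (frame[col].astype(str) == lev).astype(float)
            dummies.append(name)
        groups[col] = dummies
        out = out.drop(columns=[col])
    return out, groups


# ---------------------------------------------------------------------------
# OLS machinery (shared by selection, submodels and d-sep tests)


def _design(frame: pd.DataFrame, terms: list[str], groups: dict[str, list[str]]) -> tuple[np.ndarray, list[str]]:
    cols: list[str] = []
    for t in terms:
        cols.extend(groups.get(t, [t]))
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in cols])
    return X, cols


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ beta
    return beta, resid, float(resid @ resid)


def _aic(n: int, rss: float, n_coef: int) -> float:
    # Gaussian profile AIC; parameter count = coefficients (incl intercept)
    # + error variance, kept consistent across all compared models
    return n * np.log(max(rss, 1e-300) / n) + 2 * (n_coef + 1)


def fit_submodel(
    frame: pd.DataFrame, response: str, terms: list[str], groups: dict[str, list[str]]
) -> "Submodel":
    """OLS of ``response`` on ``terms`` with coefficient t-tests and R^2."""
    y = frame[response].to_numpy(float)
    X, cols = _design(frame, terms, groups)
    try:
        beta, resid, rss = _ols(X, y)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for {response!r}; columns: {cols}"
        ) from None
    n, p = X.shape
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    names = ["(intercept)"] + cols
    return Submodel(
        response=response,
        terms=list(terms),
        columns=cols,
        coefficients=dict(zip(names, map(float, beta))),
        pvalues=dict(zip(names, map(float, pvals))),
        r2=float(r2),
        aic=_aic(n, rss, p),
        rss=rss,
        resid=resid,
    )


def stepwise_aic_select(
    frame: pd.DataFrame,
    response: str,
    candidates: list[str],
    forced: list[str] = (),
    groups: dict[str, list[str]] | None = None,
) -> list[str]:
    """Bidirectional stepwise AIC selection with forced terms.

    Runs the greedy bidirectional search from two starting models — the full
    model (forced + all candidates) and the forced-only model — repeatedly
    applying the single drop or add that most reduces
    ``AIC = n ln(RSS/n) + 2p`` until no move improves it, and keeps the
    endpoint with the lower AIC (the two-start walk escapes the occasional
    single-move local optimum of a one-start search).  Forced terms are never
    dropped.  Deterministic: ties go to the earliest move in candidate
    order, and to the full-model start between runs.
    """
    groups = groups or {}
    forced = list(forced)
    candidates = list(candidates)
    if set(forced) & set(candidates):
        raise ValueError("forced and candidate terms must be disjoint")
    y = frame[response].to_numpy(float)
    n = len(frame)

    def aic_of(terms: list[str]) -> float:
        X, _ = _design(frame, terms, groups)
        try:
            _, _, rss = _ols(X, y)
        except np.linalg.LinAlgError:
            return np.inf  # exactly collinear candidate set: never selectable
        return _aic(n, rss, X.shape[1])

    def walk(start: list[str]) -> tuple[list[str], float]:
        current, current_aic = start, aic_of(start)
        while True:
            best_move, best_aic = None, current_aic - 1e-10
            for t in candidates:
                if t in current:
                    trial = [u for u in current if u != t]
                else:
                    trial = current + [t]
                a = aic_of(trial)
                if a < best_aic:
                    best_move, best_aic = trial, a
            if best_move is None:
                return current, current_aic
            current, current_aic = best_move, best_aic

    full, full_aic = walk(forced + candidates)
    lean, lean_aic = walk(list(forced))
    current = full if full_aic <= lean_aic else lean
    # keep stable ordering: forced first, then candidates in given order
    return forced + [t for t in candidates if t in current]


# ---------------------------------------------------------------------------
# the path model


@dataclass
class Submodel:
    response: str
    terms: list[str]
    columns: list[str]
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    aic: float
    rss: float
    resid: np.ndarray


@dataclass
class PathModel:
    """Fitted piecewise path model: DAG of standardized submodels."""

    nodes: list[str]  # topological order, exogenous first
    exogenous: list[str]
    edges: list[tuple[str, str, float, float]]  # (from, to, coef, p)
    correlated_errors: list[tuple[str, str, float]]
    submodels: dict[str, Submodel]
    groups: dict[str, list[str]] = field(default_factory=dict)
    fisher_c: tuple[float, int, float] | None = None

    def edge_coef(self, u: str, v: str) -> float | None:
        for a, b, c, _ in self.edges:
            if a == u and b == v:
                return c
        return None

    def adjacent(self, u: str, v: str) -> bool:
        return any((a == u and b == v) or (a == v and b == u) for a, b, *_ in self.edges)

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "coefficient": c, "p_value": p, "edge_type": "directed"}
            for a, b, c, p in self.edges
        ]
        rows += [
            {"from": a, "to": b, "coefficient": r, "p_value": np.nan, "edge_type": "correlated"}
            for a, b, r in self.correlated_errors
        ]
        return pd.DataFrame(rows, columns=["from", "to", "coefficient", "p_value", "edge_type"])


def assemble_path_model(
    frame: pd.DataFrame,
    layers: list[tuple[str, list[str], list[str]]],
    groups: dict[str, list[str]] | None = None,
    correlated_error_pairs: list[tuple[str, str]] = (),
    select: bool = True,
) -> PathModel:
    """Fit the piecewise model layer by layer.

    Parameters
    ----------
    layers : list of (response, candidates, forced)
        One entry per endogenous node, in causal order (upstream responses
        last or first — order does not affect the result).  Candidates are
        subject to stepwise AIC; forced terms are always kept.
    correlated_error_pairs : pairs of endogenous variables whose errors are
        allowed to covary (residual Pearson r is reported; the pair is
        exempt from directed-separation testing).
    select : bool
        When False, skip selection and keep every candidate (saturated
        within layers).
    """
    groups = dict(groups or {})
    import networkx as nx

    responses = [resp for resp, _, _ in layers]
    submodels: dict[str, Submodel] = {}
    edges: list[tuple[str, str, float, float]] = []
    g = nx.DiGraph()
    all_vars: list[str] = []

    def note(v: str) -> None:
        if v not in all_vars:
            all_vars.append(v)

    for resp, cands, forced in layers:
        note(resp)
        for t in list(cands) + list(forced):
            note(t)
        terms = (
            stepwise_aic_select(frame, resp, list(cands), list(forced), groups)
            if select
            else list(forced) + list(cands)
        )
        sm = fit_submodel(frame, resp, terms, groups)
        submodels[resp] = sm
        for t in terms:
            if t in groups:  # categorical control: kept in submodel, no edge
                continue
            edges.append((t, resp, sm.coefficients[t], sm.pvalues[t]))
            g.add_edge(t, resp)

    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("selected paths form a cycle")

    # topological order: exogenous (never a response) first, in first-seen
    # order, then responses in layer order reversed to causal flow
    exogenous = [v for v in all_vars if v not in responses and v not in groups]
    causal_order = exogenous + [r for r in reversed(responses)]

    corr_edges = []
    for a, b in correlated_error_pairs:
        ra = submodels[a].resid if a in submodels else frame[a].to_numpy(float)
        rb = submodels[b].resid if b in submodels else frame[b].to_numpy(float)
        r = float(np.corrcoef(ra, rb)[0, 1])
        corr_edges.append((a, b, r))

    return PathModel(
        nodes=causal_order,
        exogenous=exogenous,
        edges=edges,
        correlated_errors=corr_edges,
        submodels=submodels,
        groups=groups,
    )


def directed_separation_tests(
    model: PathModel, frame: pd.DataFrame
) -> list[tuple[str, float]]:
    """Independence claims implied by the missing edges, with p-values.

    The basis set holds every ordered pair (u, v) with v endogenous, u
    earlier in the causal order, no directed edge between them in either
    direction, and no correlated-error edge joining them.  Each claim is
    tested by regressing v on u plus v's parents: the claim's p-value is the
    t-test on u's coefficient (partial F-test when u is categorical).
    """
    corr_pairs = {frozenset((a, b)) for a, b, _ in model.correlated_errors}
    claims: list[tuple[str, float]] = []
    order = model.nodes
    for v in order:
        if v not in model.submodels:
            continue  # exogenous: covariance unconstrained by the model
        parents = model.submodels[v].terms
        for u in order[: order.index(v)]:
            if u == v or model.adjacent(u, v) or frozenset((u, v)) in corr_pairs:
                continue
            p = _claim_pvalue(frame, v, u, parents, model.groups)
            claims.append((f"{v} ~ {u} | {{{', '.join(parents) or ''}}}", max(p, _P_FLOOR)))
    return claims


def _claim_pvalue(frame, v, u, parents, groups) -> float:
    y = frame[v].to_numpy(float)
    base_terms = [t for t in parents if t != u]
    if u in groups:  # partial F-test for a categorical claim variable
        X0, _ = _design(frame, base_terms, groups)
        X1, _ = _design(frame, base_terms + [u], groups)
        _, _, rss0 = _ols(X0, y)
        _, _, rss1 = _ols(X1, y)
        q = X1.shape[1] - X0.shape[1]
        dof = len(y) - X1.shape[1]
        f = ((rss0 - rss1) / q) / (rss1 / dof)
        return float(stats.f.sf(f, q, dof))
    sm = fit_submodel(frame, v, base_terms + [u], groups)
    return sm.pvalues[u]


def fishers_c(pvalues) -> tuple[float, int, float]:
    """Pool independence-claim p-values: C = -2 sum(ln p), df = 2k.

    An empty claim list is the saturated case: C = 0, df = 0, and the fit is
    accepted by convention (p = 1).  Zero p-values are an error — floor them
    at machine epsilon upstream.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zeros at machine epsilon")
    c = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return c, df, float(stats.chi2.sf(c, df))


def decompose_effects(model: PathModel, response: str) -> pd.DataFrame:
    """Standardized direct, indirect and total effects on ``response``.

    direct(X) is the coefficient of the edge X -> response (0 if absent);
    indirect(X) sums, over every directed path X -> ... -> response of
    length >= 2, the product of the path's standardized coefficients
    (correlated-error edges are never traversed); total = direct + indirect.
    """
    children: dict[str, list[tuple[str, float]]] = {}
    for a, b, c, _ in model.edges:
        children.setdefault(a, []).append((b, c))

    memo: dict[str, float] = {response: 1.0}

    def total_from(u: str) -> float:
        # sum of coefficient products over all directed u -> response paths
        if u in memo:
            return memo[u]
        memo[u] = sum(c * total_from(w) for w, c in children.get(u, []))
        return memo[u]

    rows = []
    for u in model.nodes:
        if u == response:
            continue
        direct = model.edge_coef(u, response) or 0.0
        total = total_from(u)
        rows.append({"predictor": u, "direct": direct, "indirect": total - direct,
                     "total": total})
    return pd.DataFrame(rows, columns=["predictor", "direct", "indirect", "total"])


# ---------------------------------------------------------------------------
# estimator facade


class PiecewisePathModel(BaseEstimator):
    """Piecewise path model of the ISD exponent (sklearn-style estimator).

    ``fit`` takes a standardized site-level frame and runs the three-stage
    selection: fixed effects on the exponent, then on each trait, then on
    each flow variable, always forcing the control terms; the selected
    submodels are combined with correlated errors among every pair of trait
    and flow variables, directed-separation claims are tested and pooled
    with Fisher's C, and effects on the response are decomposed.

    Parameters
    ----------
    response : name of the exponent column (default ``"b"``).
    traits, flows, landuse : lists of column names per layer.
    controls : numeric control terms, always retained (e.g. drainage area).
    categorical_controls : categorical control terms (dummy-coded, always
        retained, reported unstandardized).
    select : set False to fit the saturated within-layer model.

    Attributes
    ----------
    model_ : PathModel
    fisher_c_ : (C, df, p)
    effects_ : DataFrame of direct/indirect/total effects on the response.
    """

    def __init__(self, response: str = "b", traits: list[str] = (), flows: list[str] = (),
                 landuse: list[str] = (), controls: list[str] = (),
                 categorical_controls: list[str] = (), select: bool = True):
        self.response = response
        self.traits = traits
        self.flows = flows
        self.landuse = landuse
        self.controls = controls
        self.categorical_controls = categorical_controls
        self.select = select

    def fit(self, X: pd.DataFrame, y=None):
        traits, flows, landuse = map(list, (self.traits, self.flows, self.landuse))
        controls = list(self.controls)
        frame, groups = expand_categoricals(X, tuple(self.categorical_controls))
        forced = controls + list(self.categorical_controls)
        layers = [(self.response, traits + flows + landuse, forced)]
        layers += [(t, flows + landuse, forced) for t in traits]
        layers += [(f, landuse, forced) for f in flows]
        endo_pairs = list(itertools.combinations(traits + flows, 2))
        model = assemble_path_model(frame, layers, groups, endo_pairs, select=self.select)
        claims = directed_separation_tests(model, frame)
        model.fisher_c = fishers_c([p for _, p in claims])
        self.model_ = model
        self.frame_ = frame
        self.claims_ = claims
        self.fisher_c_ = model.fisher_c
        self.effects_ = decompose_effects(model, self.response)
        return self

    def summary(self) -> dict:
        m = self.model_
        c, df, p = m.fisher_c
        return {
            "fisher_c": {"C": c, "df": df, "p": p},
            "submodels": {
                r: {"terms": s.terms, "r2": s.r2, "aic": s.aic}
                for r, s in m.submodels.items()
            },
            "n_claims": len(self.claims_),
            "edges": m.to_edge_list().to_dict(orient="records"),
        }
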