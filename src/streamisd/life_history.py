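"""Life-history strategy affinities for stream fishes.

Winemiller's trilateral model places fish life histories on a continuum
between three endpoints:

* **periodic** — large, highly fecund, late-maturing seasonal spawners;
* **opportunistic** — small, rapidly maturing, serially spawning colonisers;
* **equilibrium** — moderate fecundity with heavy parental investment.

Each species is given convex affinity weights on the three endpoints by
(1) building a Gower dissimilarity matrix over reproductive traits (age at
maturity, fecundity, spawning-season duration, ordinal parental care),
(2) embedding it in two dimensions with nonmetric multidimensional scaling
(NMDS), and (3) fitting a 3-archetype archetypal analysis to the ordination
scores.  Affinities are each species' barycentric weights on the fitted
archetypes; archetypes are labelled by their affinity-weighted trait means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import smacof
from sklearn.utils import check_random_state

__all__ = [
    "PARENTAL_CARE_CODES",
    "recode_parental_care",
    "gower_dissimilarity",
    "NMDS",
    "OrdinationResult",
    "ArchetypalAnalysis",
    "assign_endpoint_labels",
    "affinity_redundancy_filter",
    "impute_traits",
    "life_history_affinities",
]

# ordinal recoding of reproductive mode; increasing parental investment
PARENTAL_CARE_CODES = {
    "nonguarder": 1,
    "brood hider": 2,
    "substrate chooser": 3,
    "guarders/bearers": 4,
}

TRAIT_VARIABLES = ("age_maturity", "log10_fecundity", "spawning_season", "parental_care")


def recode_parental_care(mode: str) -> int:
    """Map a reproductive-mode category to its ordinal care code (1-4)."""
    key = str(mode).strip().lower()
    try:
        return PARENTAL_CARE_CODES[key]
    except KeyError:
        raise ValueError(
            f"unknown reproductive mode {mode!r}; expected one of {sorted(PARENTAL_CARE_CODES)}"
        ) from None


def gower_dissimilarity(traits: pd.DataFrame, variables: list[str]) -> np.ndarray:
    """Gower dissimilarity: mean over variables of range-scaled absolute difference.

    All variables are treated as interval-scaled (ordinal parental care is
    assumed already recoded to 1-4).  A variable with zero range is an error
    because its scaling is undefined.
    """
    if len(traits) < 2:
        raise ValueError("need at least two species")
    n = len(traits)
    d = np.zeros((n, n))
    for v in variables:
        x = traits[v].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"missing values in variable {v!r}")
        rng = x.max() - x.min()
        if rng == 0:
            raise ValueError(f"variable {v!r} has zero range")
        d += np.abs(x[:, None] - x[None, :]) / rng
    return d / len(variables)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray  # species x n_dim
    stress: float  # stress-1, in [0, 1]


class NMDS(BaseEstimator, TransformerMixin):
    """Nonmetric multidimensional scaling of a precomputed dissimilarity matrix.

    Thin estimator over :func:`sklearn.manifold.smacof` in nonmetric mode
    (isotonic regression on dissimilarity ranks, stress-1 reported), keeping
    the best of ``n_starts`` random initialisations.  Deterministic for a
    fixed ``random_state``.
    """

    def __init__(self, n_components: int = 2, n_starts: int = 20, max_iter: int = 500,
                 eps: float = 1e-8, random_state=None):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("expected a square dissimilarity matrix")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        coords, stress = smacof(
            D,
            metric=False,
            n_components=self.n_components,
            n_init=self.n_starts,
            max_iter=self.max_iter,
            eps=self.eps,
            random_state=self.random_state,
            normalized_stress=True,
        )
        if not np.all(np.isfinite(coords)):
            raise RuntimeError("NMDS failed to converge in every start")
        self.embedding_ = coords
        self.stress_ = float(stress)
        return coords

    @property
    def result_(self) -> OrdinationResult:
        return OrdinationResult(self.embedding_, self.stress_)


def _simplex_lstsq(A: np.ndarray, targets: np.ndarray, penalty: float) -> np.ndarray:
    """Row-wise ``min ||A w - t||`` with ``w >= 0, sum w = 1``.

    Classic NNLS trick: append a heavily weighted row enforcing the sum
    constraint, then renormalise.
    """
    k = A.shape[1]
    Aa = np.vstack([A, penalty * np.ones((1, k))])
    out = np.empty((targets.shape[0], k))
    for i, t in enumerate(targets):
        w, _ = nnls(Aa, np.append(t, penalty))
        s = w.sum()
        out[i] = w / s if s > 0 else np.full(k, 1.0 / k)
    return out


class ArchetypalAnalysis(BaseEstimator, TransformerMixin):
    """Archetypal analysis by alternating simplex-constrained least squares.

    Finds ``k`` archetypes ``Z`` (convex combinations of the data) and convex
    affinity weights ``A`` minimising ``||X - A Z||_F^2``.  Initialised from
    the ``k`` points with the largest pairwise spread (greedy farthest-point)
    plus random restarts; the best residual sum of squares wins.

    Attributes
    ----------
    archetypes_ : (k, d) array
    affinities_ : (n, k) array, rows on the simplex
    rss_ : float
    """

    def __init__(self, n_archetypes: int = 3, n_restarts: int = 10, max_iter: int = 200,
                 tol: float = 1e-10, random_state=None):
        self.n_archetypes = n_archetypes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, k = X.shape[0], self.n_archetypes
        if n <= k:
            raise ValueError(f"need more than {k} points, got {n}")
        rng = check_random_state(self.random_state)
        penalty = 200.0 * max(1.0, float(np.abs(X).max()))

        inits = [self._farthest_point_init(X)]
        for _ in range(max(self.n_restarts - 1, 0)):
            inits.append(rng.choice(n, size=k, replace=False))

        best = None
        for idx in inits:
            Z, A, rss = self._als(X, X[np.asarray(idx)].copy(), penalty)
            if best is None or rss < best[2] - 1e-12:
                best = (Z, A, rss)
        Z, A, rss = best
        self.archetypes_ = Z
        self.affinities_ = A
        self.rss_ = rss
        return A

    def transform(self, X):
        """Convex weights reconstructing new points from the fitted archetypes."""
        X = np.asarray(X, dtype=float)
        penalty = 200.0 * max(1.0, float(np.abs(X).max()), float(np.abs(self.archetypes_).max()))
        return _simplex_lstsq(self.archetypes_.T, X, penalty)

    def _als(self, X, Z, penalty):
        rss_prev = np.inf
        A = _simplex_lstsq(Z.T, X, penalty)
        for _ in range(self.max_iter):
            # unconstrained optimal archetypes, then projection onto the
            # convex hull of the data (archetypes stay mixtures of points)
            Zls, *_ = np.linalg.lstsq(A, X, rcond=None)
            B = _simplex_lstsq(X.T, Zls, penalty)
            Z = B @ X
            A = _simplex_lstsq(Z.T, X, penalty)
            rss = float(((X - A @ Z) ** 2).sum())
            if rss_prev - rss < self.tol * max(rss_prev, 1.0):
                rss_prev = rss
                break
            rss_prev = rss
        return Z, A, rss_prev

    @staticmethod
    def _farthest_point_init(X):
        d = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        idx = [int(i), int(j)]
        while len(idx) < 3:
            rest = d[:, idx].min(axis=1)
            rest[idx] = -1
            idx.append(int(np.argmax(rest)))
        return np.array(idx)


def assign_endpoint_labels(
    archetypes: np.ndarray, affinities: np.ndarray, traits: pd.DataFrame
) -> pd.DataFrame:
    """Label the three archetypes as periodic / equilibrium / opportunistic.

    The archetype with the highest affinity-weighted mean fecundity is
    periodic; the highest affinity-weighted mean parental care is
    equilibrium; the remaining one is opportunistic.  If fecundity and care
    both peak at the same archetype the assignment is ambiguous and an error
    reporting the weighted trait means is raised; an exact tie between the
    remaining two goes to the lower weighted age at maturity (opportunistic).
    Returns a species x {equilibrium, periodic, opportunistic} table.
    """
    A = np.asarray(affinities, dtype=float)
    k = A.shape[1]
    if k != 3:
        raise ValueError("endpoint labelling requires exactly 3 archetypes")

    def wmean(col: str) -> np.ndarray:
        t = traits[col].to_numpy(dtype=float)
        w = A.sum(axis=0)
        return (A * t[:, None]).sum(axis=0) / np.where(w > 0, w, 1.0)

    fec_col = "log10_fecundity" if "log10_fecundity" in traits.columns else "fecundity"
    fec, care, age = wmean(fec_col), wmean("parental_care"), wmean("age_maturity")
    periodic = int(np.argmax(fec))
    care_masked = care.copy()
    care_masked[periodic] = -np.inf
    equilibrium = int(np.argmax(care_masked))
    if int(np.argmax(care)) == periodic and not np.isclose(care[periodic], care[equilibrium]):
        raise ValueError(
            "ambiguous archetype labels: fecundity and parental care both peak at "
            f"archetype {periodic}; weighted means fecundity={fec}, care={care}, age={age}"
        )
    remaining = [j for j in range(3) if j not in (periodic, equilibrium)]
    opportunistic = remaining[0]
    order = {"equilibrium": equilibrium, "periodic": periodic, "opportunistic": opportunistic}
    out = pd.DataFrame(
        {name: A[:, j] for name, j in order.items()},
        index=traits.index if len(traits) == len(A) else None,
    )
    if "species" in traits.columns:
        out.insert(0, "species", traits["species"].to_numpy())
    return out[["species", "equilibrium", "periodic", "opportunistic"] if "species" in out else
               ["equilibrium", "periodic", "opportunistic"]]


def affinity_redundancy_filter(
    cwm_affinities: pd.DataFrame, r_thresh: float = 0.7
) -> list[str]:
    """Drop redundant community-level affinity axes.

    Pairwise Pearson correlations among the three CWM affinity axes are
    computed; from each pair with ``|r| > r_thresh`` one axis is dropped,
    preferring to keep periodic and opportunistic (the two axes carrying the
    life-history hypotheses).  Returns the retained axis names.
    """
    axes = ["equilibrium", "periodic", "opportunistic"]
    missing = [a for a in axes if a not in cwm_affinities.columns]
    if missing:
        raise ValueError(f"missing affinity axes: {missing}")
    if len(cwm_affinities) < 3:
        raise ValueError("need at least three sites")
    for a in axes:
        if cwm_affinities[a].std(ddof=0) < 1e-12:
            raise ValueError(f"affinity axis {a!r} is constant across sites")
    corr = cwm_affinities[axes].corr()
    keep_priority = {"periodic": 0, "opportunistic": 1, "equilibrium": 2}
    retained = list(axes)
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                if abs(corr.loc[a, b]) > r_thresh:
                    drop = max(a, b, key=lambda v: keep_priority[v])
                    retained.remove(drop)
                    changed = True
                    break
            if changed:
                break
    return sorted(retained, key=lambda v: keep_priority[v])


def impute_traits(traits: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing continuous traits by genus mean, then global mean.

    Genus is the first whitespace-separated token of the species name.
    Returns the completed table and a report of imputed cells
    (species, column, method, value).
    """
    out = traits.copy()
    genus = out["species"].astype(str).str.split().str[0]
    report = []
    for c in columns:
        vals = out[c]
        if vals.isna().any():
            genus_mean = vals.groupby(genus).transform("mean")
            global_mean = vals.mean()
            for idx in out.index[vals.isna()]:
                if not np.isnan(genus_mean.loc[idx]):
                    fill, how = genus_mean.loc[idx], "genus_mean"
                else:
                    fill, how = global_mean, "global_mean"
                out.loc[idx, c] = fill
                report.append(
                    {"species": out.loc[idx, "species"], "column": c, "method": how, "value": fill}
                )
    return out, pd.DataFrame(report, columns=["species", "column", "method", "value"])


def life_history_affinities(
    traits: pd.DataFrame,
    seed: int | None = 0,
    n_starts: int = 20,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Species trait table -> labelled endpoint affinities.

    Expects columns species, age_maturity, fecundity, spawning_season and
    either ``parental_care`` (ordinal 1-4) or ``reproductive_mode``
    (categorical, recoded here).  Fecundity is log10-transformed before the
    Gower matrix — spawner output spans orders of magnitude and would
    otherwise dominate the range scaling.

    Returns the affinity table plus a diagnostics dict (stress, archetype
    coordinates, ordination scores).
    """
    df = traits.copy()
    if "parental_care" not in df.columns:
        df["parental_care"] = df["reproductive_mode"].map(recode_parental_care)
    df, imputation = impute_traits(
        df, ["age_maturity", "fecundity", "spawning_season", "trophic_level", "ct_max"]
        if {"trophic_level", "ct_max"} <= set(df.columns)
        else ["age_maturity", "fecundity", "spawning_season"]
    )
    df["log10_fecundity"] = np.log10(df["fecundity"].astype(float))
    D = gower_dissimilarity(df, list(TRAIT_VARIABLES))
    seeds = np.random.SeedSequence(seed).generate_state(2)
    nmds = NMDS(n_starts=n_starts, random_state=int(seeds[0]) % (2**31))
    coords = nmds.fit_transform(D)
    aa = ArchetypalAnalysis(n_restarts=n_restarts, random_state=int(seeds[1]) % (2**31))
    affinities = aa.fit_transform(coords)
    labelled = assign_endpoint_labels(aa.archetypes_, affinities, df)
    diagnostics = {
        "stress": nmds.stress_,
        "archetypes": aa.archetypes_,
        "coordinates": coords,
        "rss": aa.rss_,
        "imputation": imputation,
    }
    return labelled, diagnostics
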