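"""Synthetic stream-fish study with known ground truth at every layer.

The generator emulates the causal structure the pipeline is built to
recover:

    land use  ->  flow-alteration severity  ->  community traits  ->  ISD b
                                                            (individual masses)

All latent site-level variables live on a standardized (mean 0, SD 1) scale
so the planted coefficients are directly comparable with the standardized
path coefficients the pipeline estimates.  Endogenous residual SDs are set
to ``sqrt(1 - explained variance)`` (times a configurable ``noise_scale``),
keeping every latent at unit variance.

Observable layers are then realised so that the pipeline's own readers and
stages reproduce the latents:

* land-use percentages and drainage areas are lognormal, so the pipeline's
  skewness-gated log transform linearises them back to the planted latents;
* flow severities are quantized to whole years and expanded into annual
  observed/expected records whose classify -> proportion round trip is exact;
* community-weighted trait targets are realised by softmax abundance weights
  over a species pool built from noisy convex mixtures of three planted
  life-history archetypes;
* the site exponent is a planted linear function of the realised
  (abundance-weighted, standardized) traits, and individual body masses are
  inverse-CDF draws from the bounded power law with that exponent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .isd import PLBParams, plb_sample
from .life_history import PARENTAL_CARE_CODES

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "EDGE_SIGNS",
    "simulate_truth",
    "simulate_study",
    "simulate",
]

# Planted causal diagram: sign of every path coefficient.  Traits carry the
# life-history hypotheses (periodic up, opportunistic down); flow shapes
# traits; land use shapes flow.  b has no direct flow or land-use parents.
EDGE_SIGNS: dict[tuple[str, str], int] = {
    ("pct_crop", "low_flow_magnitude_diminished"): +1,
    ("pct_crop", "high_flow_timing_later"): +1,
    ("pct_crop", "high_flow_frequency_inflated"): -1,
    ("pct_developed", "high_flow_frequency_inflated"): +1,
    ("pct_developed", "high_flow_timing_later"): +1,
    ("low_flow_magnitude_diminished", "cwm_opportunistic"): +1,
    ("low_flow_magnitude_diminished", "cwm_ctmax"): +1,
    ("high_flow_frequency_inflated", "cwm_periodic"): +1,
    ("high_flow_frequency_inflated", "cwm_trophic"): +1,
    ("high_flow_timing_later", "cwm_opportunistic"): +1,
    ("high_flow_timing_later", "cwm_trophic"): -1,
    ("cwm_periodic", "b"): +1,
    ("cwm_opportunistic", "b"): -1,
    ("cwm_trophic", "b"): +1,
    ("cwm_ctmax", "b"): -1,
}

LANDUSE_VARS = ("pct_crop", "pct_developed")
FLOW_VARS = (
    "low_flow_magnitude_diminished",
    "high_flow_frequency_inflated",
    "high_flow_timing_later",
)
TRAIT_VARS = ("cwm_periodic", "cwm_opportunistic", "cwm_trophic", "cwm_ctmax")

# metric name / planted direction / O-E geometry per flow variable
_FLOW_METRICS = {
    "low_flow_magnitude_diminished": ("low_flow_magnitude", "magnitude", "diminished"),
    "high_flow_frequency_inflated": ("high_flow_frequency", "frequency", "inflated"),
    "high_flow_timing_later": ("high_flow_timing", "timing", "later"),
}

# archetype trait profiles: [equilibrium, periodic, opportunistic]
# rows: age at maturity (yr), log10 fecundity (eggs/yr), spawning season
# (months), parental care (ordinal), trophic level, CTmax (deg C)
_ARCHETYPE_TRAITS = pd.DataFrame(
    {
        "equilibrium": [4.0, 2.3, 4.0, 4.0, 3.5, 30.0],
        "periodic": [8.0, 5.0, 2.0, 1.0, 3.2, 33.0],
        "opportunistic": [1.0, 3.0, 9.0, 1.0, 2.8, 36.0],
    },
    index=["age_maturity", "log10_fecundity", "spawning_season", "parental_care",
           "trophic_level", "ct_max"],
)

ECOREGIONS = ("northern", "southern", "central", "western")


@dataclass
class SyntheticConfig:
    """Study-condition knobs of the generator (defaults are the study design)."""

    n_sites: int = 500
    n_species: int = 120
    years: int = 40              # annual flow records per gage, 1980-2019
    start_year: int = 1980
    individuals_per_site: int = 500
    noise_scale: float = 1.0     # 0 => noise-free endogenous layers
    coef_low: float = 0.2        # |standardized path coefficient| range
    coef_high: float = 0.4
    x_min: float = 1.0           # PLB bounds, g
    x_max: float = 1000.0
    b_mean: float = -1.43        # marginal exponent location/spread
    b_sd: float = 0.30
    weight_temperature: float = 0.5   # kernel width of site abundance weights
    target_scale: float = 0.7    # pulls kernel targets into the dense pool region
    trait_noise: float = 0.10    # reproductive-trait noise, fraction of archetype range
    trophic_noise_sd: float = 0.4   # species trophic level varies within a strategy
    ctmax_noise_sd: float = 3.0     # deg C; thermal tolerance varies within a strategy
    severity_base: float = 0.40  # severity = base + scale * latent, then quantized
    severity_scale: float = 0.13
    dirichlet_alpha: float = 0.8  # concentration of species archetype mixtures
    include_repeat_samples: bool = True  # older duplicate samples for 3 sites
    include_duration_metric: bool = True


@dataclass
class SyntheticTruth:
    """Ground truth: planted coefficients plus every latent realisation."""

    path_coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    site_b: np.ndarray
    species_archetype_mixture: np.ndarray  # n_species x 3 (eq, per, opp)
    seed: int
    site_table: pd.DataFrame = field(repr=False, default=None)
    species_table: pd.DataFrame = field(repr=False, default=None)
    counts: np.ndarray = field(repr=False, default=None)  # n_sites x n_species
    config: SyntheticConfig = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "path_coefficients": {f"{a}->{b}": c for (a, b), c in self.path_coefficients.items()},
                "noise_sd": self.noise_sd,
                "site_b": self.site_b.tolist(),
                "species_archetype_mixture": self.species_archetype_mixture.tolist(),
                "config": asdict(self.config) if self.config else None,
            },
            indent=1,
        )


@dataclass
class SyntheticStudy:
    """All pipeline input tables plus the truth that generated them."""

    individuals: pd.DataFrame
    abundance: pd.DataFrame
    species_traits: pd.DataFrame
    flow_records: pd.DataFrame
    sites: pd.DataFrame
    gages: pd.DataFrame
    site_gage_candidates: pd.DataFrame
    truth: SyntheticTruth

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("individuals", "abundance", "species_traits", "flow_records",
                     "sites", "gages", "site_gage_candidates"):
            getattr(self, name).to_csv(d / f"{name}.csv", index=False)
        (d / "truth.json").write_text(self.truth.to_json())


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_truth(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Draw planted coefficients and realise every latent layer.

    Deterministic under ``seed``.  Raises if a drawn coefficient set implies
    an explained variance >= 1 for any endogenous latent (infeasible on the
    standardized scale).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    coefs: dict[tuple[str, str], float] = {}
    for edge, sign in EDGE_SIGNS.items():
        coefs[edge] = sign * rng.uniform(cfg.coef_low, cfg.coef_high)

    n = cfg.n_sites
    site = pd.DataFrame({"site_id": [f"S{i:04d}" for i in range(n)]})

    # --- exogenous layer -------------------------------------------------
    z_crop = _standardize(rng.normal(size=n))
    z_dev = _standardize(rng.normal(size=n))
    site["pct_crop"] = np.minimum(np.exp(2.5 + 0.7 * z_crop), 95.0)
    site["pct_developed"] = np.minimum(np.exp(1.8 + 0.7 * z_dev), 95.0)
    site["drainage_area_km2"] = np.exp(6.0 + 1.5 * rng.normal(size=n))
    site["ecoregion"] = rng.choice(ECOREGIONS, size=n)
    latent = {"pct_crop": z_crop, "pct_developed": z_dev}

    noise_sd: dict[str, float] = {}

    def realise(var: str, parents: list[str]) -> np.ndarray:
        c = np.array([coefs[(p, var)] for p in parents])
        Z = np.column_stack([latent[p] for p in parents])
        explained = float(c @ np.atleast_2d(np.cov(Z, rowvar=False, ddof=0)) @ c)
        if explained >= 1.0 and cfg.noise_scale > 0:
            raise ValueError(
                f"infeasible config: {var} would need explained variance {explained:.2f} >= 1"
            )
        sd = cfg.noise_scale * np.sqrt(max(1.0 - explained, 0.0))
        noise_sd[var] = float(sd)
        return Z @ c + sd * rng.normal(size=n)

    # --- flow layer: latent -> quantized severity -> back to z-scale ----
    for var in FLOW_VARS:
        parents = [p for (p, v) in EDGE_SIGNS if v == var]
        raw = realise(var, parents)
        sev = np.clip(cfg.severity_base + cfg.severity_scale * raw, 0.0, 1.0)
        sev = np.round(sev * cfg.years) / cfg.years  # whole altered years
        site[var] = sev
        latent[var] = _standardize(sev)

    # --- species pool ----------------------------------------------------
    mix = rng.dirichlet([cfg.dirichlet_alpha] * 3, size=cfg.n_species)  # eq, per, opp
    base = mix @ _ARCHETYPE_TRAITS.T.to_numpy()
    ranges = _ARCHETYPE_TRAITS.max(axis=1) - _ARCHETYPE_TRAITS.min(axis=1)
    sp_noise = cfg.trait_noise * ranges.to_numpy()
    sp_noise[_ARCHETYPE_TRAITS.index.get_loc("trophic_level")] = cfg.trophic_noise_sd
    sp_noise[_ARCHETYPE_TRAITS.index.get_loc("ct_max")] = cfg.ctmax_noise_sd
    noise = rng.normal(size=base.shape) * sp_noise
    traits = pd.DataFrame(base + noise, columns=_ARCHETYPE_TRAITS.index)
    traits["age_maturity"] = traits["age_maturity"].clip(lower=0.3)
    traits["spawning_season"] = traits["spawning_season"].clip(1.0, 12.0)
    care = traits["parental_care"].clip(1.0, 4.0).round().astype(int)
    code_to_mode = {v: k for k, v in PARENTAL_CARE_CODES.items()}
    traits["parental_care"] = care
    traits["reproductive_mode"] = care.map(code_to_mode)
    traits.insert(0, "species", [f"Genus{i // 4:02d} species{i:03d}" for i in range(cfg.n_species)])
    traits["fecundity"] = 10.0 ** traits.pop("log10_fecundity")

    # species axes matching the four CWM trait variables
    axes = np.column_stack([mix[:, 1], mix[:, 2],
                            traits["trophic_level"], traits["ct_max"]])
    axes_z = (axes - axes.mean(axis=0)) / axes.std(axis=0)

    # --- trait layer: targets -> softmax weights -> realised CWMs --------
    targets = {}
    for var in TRAIT_VARS:
        parents = [p for (p, v) in EDGE_SIGNS if v == var]
        targets[var] = realise(var, parents)
    T = np.column_stack([targets[v] for v in TRAIT_VARS])  # n_sites x 4

    d2 = ((axes_z[None, :, :] - cfg.target_scale * T[:, None, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * cfg.weight_temperature**2))
    w /= w.sum(axis=1, keepdims=True)

    counts = np.empty((n, cfg.n_species), dtype=int)
    for i in range(n):
        counts[i] = rng.multinomial(cfg.individuals_per_site, w[i])

    realised = counts @ axes / counts.sum(axis=1, keepdims=True)
    realised_z = (realised - realised.mean(axis=0)) / realised.std(axis=0)
    for j, var in enumerate(TRAIT_VARS):
        site[var] = realised[:, j]
        latent[var] = realised_z[:, j]
        site[f"{var}_target"] = targets[var]

    # --- exponent layer --------------------------------------------------
    zb = realise("b", [p for (p, v) in EDGE_SIGNS if v == "b"])
    zb = np.clip(zb, -4.0, 4.0)
    site_b = np.clip(cfg.b_mean + cfg.b_sd * zb, -3.0, 0.0)
    site["b"] = site_b

    return SyntheticTruth(
        path_coefficients=coefs,
        noise_sd=noise_sd,
        site_b=site_b,
        species_archetype_mixture=mix,
        seed=seed,
        site_table=site,
        species_table=traits,
        counts=counts,
        config=cfg,
    )


def simulate_study(truth: SyntheticTruth) -> SyntheticStudy:
    """Expand a realised truth into the observable study tables."""
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    site = truth.site_table
    traits = truth.species_table
    n = len(site)

    # --- individual records ---------------------------------------------
    frames = []
    species_names = traits["species"].to_numpy()
    for i, row in site.iterrows():
        n_i = int(truth.counts[i].sum())
        masses = plb_sample(n_i, PLBParams(row["b"], cfg.x_min, cfg.x_max),
                            seed=np.random.SeedSequence([truth.seed, 2, i]))
        sp = np.repeat(species_names, truth.counts[i])
        rng.shuffle(sp)
        # common cube-law allometry W(g) = 1e-5 L(mm)^3 with mild length noise
        length = (masses / 1e-5) ** (1.0 / 3.0) * np.exp(0.02 * rng.normal(size=n_i))
        frames.append(pd.DataFrame({
            "site_id": row["site_id"], "species": sp,
            "length_mm": length, "mass_g": masses,
            "sample_date": "2015-08-15",
        }))
        if cfg.include_repeat_samples and i < 3:
            # an older, smaller revisit the most-recent-sample rule must drop
            m_old = plb_sample(40, PLBParams(row["b"], cfg.x_min, cfg.x_max),
                               seed=np.random.SeedSequence([truth.seed, 3, i]))
            frames.append(pd.DataFrame({
                "site_id": row["site_id"],
                "species": rng.choice(species_names, size=40),
                "length_mm": (m_old / 1e-5) ** (1.0 / 3.0),
                "mass_g": m_old, "sample_date": "2000-06-01",
            }))
    individuals = pd.concat(frames, ignore_index=True)

    ab_rows = []
    for i, sid in enumerate(site["site_id"]):
        for j in np.nonzero(truth.counts[i])[0]:
            ab_rows.append({"site_id": sid, "species": species_names[j],
                            "count": int(truth.counts[i, j])})
    abundance = pd.DataFrame(ab_rows)

    # --- annual flow records ---------------------------------------------
    years = np.arange(cfg.start_year, cfg.start_year + cfg.years)
    rec = []
    gage_ids = [f"G{i:04d}" for i in range(n)]
    z_hf_frq = _standardize(site["high_flow_frequency_inflated"].to_numpy())
    for i in range(n):
        for var, (metric, mclass, direction) in _FLOW_METRICS.items():
            sev = site.loc[i, var]
            rec.extend(_annual_records(gage_ids[i], metric, mclass, direction,
                                       sev, years, rng))
        if cfg.include_duration_metric:
            # shorter events where high flows are frequent; removed by the
            # duration-omission rule before modelling
            z = -0.8 * z_hf_frq[i]
            sev = float(np.round(np.clip(0.35 + 0.13 * (z + 0.6 * rng.normal()), 0, 1)
                                 * cfg.years) / cfg.years)
            rec.extend(_annual_records(gage_ids[i], "high_flow_duration", "duration",
                                       "diminished", sev, years, rng))
    flow_records = pd.DataFrame(rec)

    # --- site / gage attributes ------------------------------------------
    gages = pd.DataFrame({
        "gage_id": gage_ids,
        "drainage_area_km2": site["drainage_area_km2"].to_numpy()
        * rng.uniform(0.96, 1.04, size=n),
    })
    sites = site[["site_id", "drainage_area_km2", "ecoregion", "pct_crop",
                  "pct_developed"]].copy()
    cand = pd.DataFrame({"site_id": site["site_id"], "gage_id": gage_ids,
                         "discontinuity": False})
    distract = pd.DataFrame({
        "site_id": site["site_id"].iloc[:5],
        "gage_id": [gage_ids[(i + 7) % n] for i in range(5)],
        "discontinuity": True,
    })
    candidates = pd.concat([cand, distract], ignore_index=True)

    species_traits = traits[["species", "age_maturity", "fecundity", "spawning_season",
                             "reproductive_mode", "trophic_level", "ct_max"]].copy()
    return SyntheticStudy(individuals, abundance, species_traits, flow_records,
                          sites, gages, candidates, truth)


def _annual_records(gage_id, metric, mclass, direction, severity, years, rng):
    n_alt = int(round(severity * len(years)))
    altered = np.zeros(len(years), dtype=bool)
    altered[rng.choice(len(years), size=n_alt, replace=False)] = True
    out = []
    for yr, alt in zip(years, altered):
        expected, lo, hi = 100.0, 95.0, 105.0
        if not alt:
            obs = expected
        elif direction in ("inflated", "later"):
            obs = 112.0
        else:
            obs = 88.0
        out.append({"gage_id": gage_id, "year": int(yr), "metric": metric,
                    "metric_class": mclass, "observed": obs, "expected": expected,
                    "expected_lo": lo, "expected_hi": hi})
    return out


def simulate(seed: int = 0, config: SyntheticConfig | None = None) -> SyntheticStudy:
    """One-call generator: truth plus observable study."""
    return simulate_study(simulate_truth(config, seed))
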