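"""End-to-end orchestration: tables in, fitted path model and effects out.

Stage order: prep (sample selection + length-weight QC) -> per-site ISD
fits -> species life-history affinities and site CWM traits -> flow
severities, site-gage pairing and metric selection -> merge -> standardize
-> piecewise path model -> effect decomposition.  Every stage records what
it read, kept and dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import prep
from .isd import fit_isd
from .life_history import affinity_redundancy_filter, life_history_affinities
from .sem import PiecewisePathModel, standardize_table

__all__ = ["PipelineConfig", "PipelineResult", "load_inputs", "run_pipeline"]

INPUT_TABLES = ("individuals", "species_traits", "flow_records", "sites", "gages",
                "site_gage_candidates")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str | None = None
    min_n: int = 10              # records needed for a length-weight QC fit
    z_thresh: float = 3.0        # standardized-residual cut for QC flags
    min_years: int = 10          # gage record-length filter
    r_thresh: float = 0.7        # collinearity threshold
    drainage_tolerance: float = 0.10
    skew_threshold: float = 1.0
    nmds_starts: int = 20
    aa_restarts: int = 10
    use_default_flow_metrics: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.drainage_tolerance < 1):
            raise ValueError("drainage_tolerance must be in (0, 1)")
        if not (0 < self.r_thresh <= 1):
            raise ValueError("r_thresh must be in (0, 1]")
        if self.min_years < 1 or self.min_n < 2:
            raise ValueError("min_years and min_n must be positive")


@dataclass
class PipelineResult:
    isd_fits: pd.DataFrame
    affinities: pd.DataFrame
    cwm: pd.DataFrame
    severity_wide: pd.DataFrame
    retained_metrics: list[str]
    retained_affinities: list[str]
    site_table: pd.DataFrame
    frame: pd.DataFrame
    path_model: PiecewisePathModel
    effects: pd.DataFrame
    logs: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def load_inputs(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    d = Path(config.input_dir)
    tables = {}
    for name in INPUT_TABLES:
        path = d / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        tables[name] = pd.read_csv(path)
    prep.validate_individual_records(tables["individuals"])
    return tables


def run_pipeline(config: PipelineConfig, tables: dict[str, pd.DataFrame] | None = None) -> PipelineResult:
    """Run every stage; optionally write artifacts to ``config.output_dir``."""
    config.validate()
    if tables is None:
        tables = load_inputs(config)
    logs: dict = {}
    seeds = np.random.SeedSequence(config.seed).generate_state(4)

    # --- prep: most recent sample, length-weight QC ----------------------
    ind = tables["individuals"]
    latest = prep.select_latest_samples(ind)
    qc_fits, flags = prep.flag_lengthweight_outliers(latest, config.min_n, config.z_thresh)
    clean = latest[~flags].reset_index(drop=True)
    logs["prep"] = {
        "records_in": int(len(ind)),
        "records_after_latest": int(len(latest)),
        "records_flagged": int(flags.sum()),
        "records_out": int(len(clean)),
    }

    # --- per-site ISD fits ------------------------------------------------
    rows = []
    for site, grp in clean.groupby("site_id", sort=True):
        fit = fit_isd(grp["mass_g"].dropna().to_numpy())
        rows.append({"site_id": site, "b_hat": fit.b_hat, "ci_lo": fit.ci_lo,
                     "ci_hi": fit.ci_hi, "n": fit.n, "x_min": fit.x_min,
                     "x_max": fit.x_max, "nll": fit.neg_loglik_at_mle})
    isd_fits = pd.DataFrame(rows)
    logs["isd"] = {"sites_fit": int(len(isd_fits))}

    # --- traits: affinities + CWMs ----------------------------------------
    affinities, lh_diag = life_history_affinities(
        tables["species_traits"], seed=int(seeds[0]) % (2**31),
        n_starts=config.nmds_starts, n_restarts=config.aa_restarts,
    )
    species_vals = affinities.merge(
        tables["species_traits"][["species", "trophic_level", "ct_max"]], on="species"
    )
    abundance = (
        clean.groupby(["site_id", "species"], sort=True).size().rename("count").reset_index()
    )
    cwm = prep.assemblage_trait_summary(
        abundance, species_vals,
        ["equilibrium", "periodic", "opportunistic", "trophic_level", "ct_max"],
    )
    cwm = cwm.rename(columns={"cwm_trophic_level": "cwm_trophic", "cwm_ct_max": "cwm_ctmax"})
    retained_aff = affinity_redundancy_filter(
        cwm.rename(columns={"cwm_equilibrium": "equilibrium", "cwm_periodic": "periodic",
                            "cwm_opportunistic": "opportunistic"}),
        config.r_thresh,
    )
    # the path model carries the two hypothesis-bearing axes at most
    trait_affinity_cols = [f"cwm_{a}" for a in retained_aff if a != "equilibrium"]
    logs["traits"] = {"nmds_stress": lh_diag["stress"],
                      "retained_affinities": retained_aff,
                      "n_imputed": int(len(lh_diag["imputation"]))}

    # --- flow: severities, pairing, metric selection ----------------------
    sev, excluded = flow_mod.severity_proportions(tables["flow_records"], config.min_years)
    pairs, pair_drops = flow_mod.pair_site_gage(
        tables["sites"], tables["gages"], tables["site_gage_candidates"],
        config.drainage_tolerance,
    )
    sev["column"] = sev["metric"] + "_" + sev["direction"]
    wide = sev.pivot(index="gage_id", columns="column", values="severity")
    site_sev = pairs[["site_id", "gage_id"]].merge(wide, on="gage_id").drop(columns="gage_id")
    site_sev = site_sev.set_index("site_id")

    if config.use_default_flow_metrics and all(
        c in site_sev.columns for c in flow_mod.DEFAULT_RETAINED_METRICS
    ):
        retained_metrics = list(flow_mod.DEFAULT_RETAINED_METRICS)
        metric_log = [{"column": c, "reason": "not in default retained set"}
                      for c in site_sev.columns if c not in retained_metrics]
    else:
        retained_metrics, metric_log = flow_mod.select_flow_metrics(
            site_sev, config.r_thresh
        )
    logs["flow"] = {"gage_metrics_excluded": excluded.to_dict(orient="records"),
                    "sites_unpaired": pair_drops.to_dict(orient="records"),
                    "metric_drops": metric_log}

    # --- merge -------------------------------------------------------------
    site_table = (
        isd_fits[["site_id", "b_hat"]].rename(columns={"b_hat": "b"})
        .merge(cwm[["site_id"] + trait_affinity_cols + ["cwm_trophic", "cwm_ctmax"]],
               on="site_id")
        .merge(site_sev[retained_metrics].reset_index(), on="site_id")
        .merge(tables["sites"][["site_id", "drainage_area_km2", "ecoregion",
                                "pct_crop", "pct_developed"]], on="site_id")
        .rename(columns={"drainage_area_km2": "drainage_area"})
    )
    logs["merge"] = {"sites_modelled": int(len(site_table))}

    # --- standardize + path model ------------------------------------------
    numeric = site_table.drop(columns=["site_id"])
    frame, transform_report = standardize_table(
        numeric, categorical=("ecoregion",), skew_threshold=config.skew_threshold
    )
    traits_list = trait_affinity_cols + ["cwm_trophic", "cwm_ctmax"]
    model = PiecewisePathModel(
        response="b",
        traits=traits_list,
        flows=retained_metrics,
        landuse=["pct_crop", "pct_developed"],
        controls=["drainage_area"],
        categorical_controls=["ecoregion"],
    ).fit(frame)
    logs["sem"] = {"fisher_c": dict(zip(("C", "df", "p"), model.fisher_c_)),
                   "transforms": transform_report.to_dict(orient="records")}

    result = PipelineResult(
        isd_fits=isd_fits, affinities=affinities, cwm=cwm, severity_wide=site_sev,
        retained_metrics=retained_metrics, retained_affinities=retained_aff,
        site_table=site_table, frame=frame, path_model=model,
        effects=model.effects_, logs=logs,
        diagnostics={"life_history": {k: v for k, v in lh_diag.items() if k != "imputation"},
                     "qc_fits": qc_fits, "pairs": pairs},
    )
    if config.output_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.isd_fits.to_csv(out / "isd_fits.csv", index=False)
    result.isd_fits.to_json(out / "isd_fits.json", orient="records", indent=1)
    result.affinities.to_csv(out / "species_affinities.csv", index=False)
    result.cwm.to_csv(out / "site_cwm.csv", index=False)
    result.site_table.to_csv(out / "site_table.csv", index=False)
    result.path_model.model_.to_edge_list().to_csv(out / "path_edges.csv", index=False)
    result.effects.to_csv(out / "effects.csv", index=False)
    with open(out / "model_summary.json", "w") as fh:
        json.dump(result.path_model.summary(), fh, indent=1, default=float)
    with open(out / "logs.json", "w") as fh:
        json.dump(result.logs, fh, indent=1, default=float)


def compare_to_truth(result: PipelineResult, truth) -> pd.DataFrame:
    """Planted vs recovered standardized coefficients, edge by edge.

    A planted edge absent from the fitted model counts as a recovered
    coefficient of 0.
    """
    model = result.path_model.model_
    rows = []
    for (a, b), c in truth.path_coefficients.items():
        rec = model.edge_coef(a, b)
        rows.append({"from": a, "to": b, "planted": c,
                     "recovered": 0.0 if rec is None else rec,
                     "in_model": rec is not None})
    df = pd.DataFrame(rows)
    df["abs_error"] = (df["planted"] - df["recovered"]).abs()
    df["sign_ok"] = np.sign(df["planted"]) == np.sign(df["recovered"])
    return df
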