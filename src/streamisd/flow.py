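"""Flow-regime alteration severity from observed/expected flow metrics.

Each gage-year carries an observed value of a flow metric (magnitude,
frequency, duration or timing of high/low-flow events) together with the
value expected under an unaltered flow regime and a model-error band around
it.  A year is "inflated"/"diminished" (or, for timing metrics,
"later"/"earlier") when the observation falls outside the band; otherwise it
is indeterminate.  Alteration *severity* for a gage, metric and direction is
the proportion of years carrying that designation — a 0-1 score where higher
values mean more frequently altered flows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "METRIC_CLASSES",
    "DEFAULT_RETAINED_METRICS",
    "classify_metric_year",
    "classify_records",
    "severity_proportions",
    "pair_site_gage",
    "select_flow_metrics",
]

METRIC_CLASSES = ("magnitude", "frequency", "duration", "timing")

# covariates used in the path model when present: diminished low-flow
# magnitude, inflated high-flow frequency, later high-flow timing
DEFAULT_RETAINED_METRICS = (
    "low_flow_magnitude_diminished",
    "high_flow_frequency_inflated",
    "high_flow_timing_later",
)

_DIRECTIONS = {
    "timing": ("later", "earlier"),
    "magnitude": ("inflated", "diminished"),
    "frequency": ("inflated", "diminished"),
    "duration": ("inflated", "diminished"),
}


def classify_metric_year(
    observed: float, expected_lo: float, expected_hi: float, metric_class: str
) -> str:
    """Directional designation of one gage-year.

    Above the expected band -> "inflated" ("later" for timing metrics);
    below -> "diminished" ("earlier"); inside -> "indeterminate".
    """
    if metric_class not in _DIRECTIONS:
        raise ValueError(f"unknown metric class {metric_class!r}")
    if not (expected_lo <= expected_hi):
        raise ValueError(f"malformed expected band [{expected_lo}, {expected_hi}]")
    up, down = _DIRECTIONS[metric_class]
    if observed > expected_hi:
        return up
    if observed < expected_lo:
        return down
    return "indeterminate"


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised designation column for an annual O/E record table."""
    req = {"gage_id", "year", "metric", "metric_class", "observed", "expected_lo", "expected_hi"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"flow records missing columns: {sorted(missing)}")
    bad = records.index[records["expected_lo"] > records["expected_hi"]].tolist()
    if bad:
        raise ValueError(f"malformed expected band at rows {bad[:20]}")
    unknown = set(records["metric_class"]) - set(METRIC_CLASSES)
    if unknown:
        raise ValueError(f"unknown metric classes: {sorted(unknown)}")
    timing = records["metric_class"].eq("timing")
    above = records["observed"] > records["expected_hi"]
    below = records["observed"] < records["expected_lo"]
    desig = np.where(
        above, np.where(timing, "later", "inflated"),
        np.where(below, np.where(timing, "earlier", "diminished"), "indeterminate"),
    )
    return records.assign(designation=desig)


def severity_proportions(
    records: pd.DataFrame, min_years: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per gage x metric x direction severity.

    severity = (# years with that designation) / (# years of record);
    indeterminate years count in the denominator only.  Gage x metric series
    shorter than ``min_years`` are excluded and logged.

    Returns
    -------
    severities : DataFrame
        Columns gage_id, metric, direction, severity, n_years (both
        directions reported for every retained gage x metric).
    exclusions : DataFrame
        Columns gage_id, metric, n_years, reason.
    """
    df = classify_records(records)
    out, dropped = [], []
    for (gage, metric), grp in df.groupby(["gage_id", "metric"], sort=True):
        n_years = grp["year"].nunique()
        if n_years < min_years:
            dropped.append(
                {"gage_id": gage, "metric": metric, "n_years": n_years,
                 "reason": f"record shorter than {min_years} years"}
            )
            continue
        up, down = _DIRECTIONS[grp["metric_class"].iloc[0]]
        counts = grp["designation"].value_counts()
        for direction in (up, down):
            out.append(
                {"gage_id": gage, "metric": metric, "direction": direction,
                 "severity": counts.get(direction, 0) / n_years, "n_years": n_years}
            )
    sev = pd.DataFrame(out, columns=["gage_id", "metric", "direction", "severity", "n_years"])
    exc = pd.DataFrame(dropped, columns=["gage_id", "metric", "n_years", "reason"])
    return sev, exc


def pair_site_gage(
    sites: pd.DataFrame,
    gages: pd.DataFrame,
    candidates: pd.DataFrame,
    tolerance: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each fish site to a representative flow gage.

    A candidate is valid when the site's upstream drainage area is within
    ``tolerance`` (relative, default +-10%) of the gage's and no major
    discontinuity (dam or large tributary) lies between them.  Among valid
    candidates the smallest relative drainage difference wins, ties broken by
    lexicographic gage id.  Sites with no valid candidate are dropped and
    logged.

    Parameters
    ----------
    sites, gages : DataFrame
        ``site_id``/``gage_id`` with ``drainage_area_km2``.
    candidates : DataFrame
        Columns site_id, gage_id, discontinuity (bool).
    """
    site_da = sites.set_index("site_id")["drainage_area_km2"]
    gage_da = gages.set_index("gage_id")["drainage_area_km2"]
    if (site_da <= 0).any() or (gage_da <= 0).any():
        raise ValueError("drainage areas must be positive")
    pairs, drops = [], []
    for site, grp in candidates.groupby("site_id", sort=True):
        sd = site_da.get(site)
        if sd is None:
            drops.append({"site_id": site, "reason": "unknown site drainage area"})
            continue
        best = None
        reasons = []
        for _, row in grp.iterrows():
            gd = gage_da.get(row["gage_id"])
            if gd is None:
                reasons.append(f"{row['gage_id']}: unknown gage drainage")
                continue
            rel = abs(sd - gd) / gd
            if bool(row["discontinuity"]):
                reasons.append(f"{row['gage_id']}: discontinuity between site and gage")
                continue
            if rel > tolerance:
                reasons.append(f"{row['gage_id']}: drainage mismatch {rel:.1%}")
                continue
            key = (rel, str(row["gage_id"]))
            if best is None or key < best[0]:
                best = (key, row["gage_id"], gd, rel)
        if best is None:
            drops.append({"site_id": site, "reason": "; ".join(reasons) or "no candidates"})
        else:
            pairs.append(
                {"site_id": site, "gage_id": best[1], "site_drainage": float(sd),
                 "gage_drainage": float(best[2]), "relative_difference": float(best[3])}
            )
    return (
        pd.DataFrame(pairs, columns=["site_id", "gage_id", "site_drainage", "gage_drainage",
                                     "relative_difference"]),
        pd.DataFrame(drops, columns=["site_id", "reason"]),
    )


def _metric_class_of(column: str) -> str:
    for mc in METRIC_CLASSES:
        if mc in column:
            return mc
    raise ValueError(f"cannot infer metric class from column {column!r}")


def select_flow_metrics(
    severity_table: pd.DataFrame, r_thresh: float = 0.7, drop_duration: bool = True
) -> tuple[list[str], list[dict]]:
    """Low-collinearity subset of site x metric-direction severity columns.

    Duration metrics are removed unconditionally (annually, more frequent
    events are necessarily shorter, so duration mirrors frequency).  Constant
    columns are dropped with a warning entry.  Then, while any pair of
    remaining columns has ``|Pearson r| > r_thresh``, the member of the
    worst-offending pair with the larger mean absolute correlation to all
    other columns is dropped.

    Returns the retained column names and a log of drops.
    """
    if len(severity_table) < 3:
        raise ValueError("need at least three sites")
    cols = list(severity_table.columns)
    log = []
    if drop_duration:
        for c in cols[:]:
            if _metric_class_of(c) == "duration":
                cols.remove(c)
                log.append({"column": c, "reason": "duration metric omitted"})
    for c in cols[:]:
        if severity_table[c].std(ddof=0) < 1e-12:
            cols.remove(c)
            log.append({"column": c, "reason": "constant column"})
    while len(cols) > 1:
        corr = severity_table[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        if corr.loc[worst] <= r_thresh:
            break
        a, b = worst
        mean_r = corr.mean(axis=0)
        drop = a if mean_r[a] >= mean_r[b] else b
        cols.remove(drop)
        log.append({"column": drop,
                    "reason": f"|r|={corr.loc[worst]:.3f} with {b if drop == a else a}"})
    return cols, log
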