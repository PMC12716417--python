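"""Quality control of individual fish records and assemblage trait summaries.

Individual records carry site, species, length (mm), mass (g) and sample
date.  Before any size-spectrum fitting we (1) keep only the most recent
sample per site, (2) screen gross length-weight errors with per-species
allometric regressions, and (3) compute abundance-weighted (community
weighted mean, CWM) trait values per site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AllometricFit",
    "select_latest_samples",
    "flag_lengthweight_outliers",
    "community_weighted_mean",
    "assemblage_trait_summary",
]

REQUIRED_COLUMNS = ("site_id", "species", "length_mm", "mass_g", "sample_date")


@dataclass(frozen=True)
class AllometricFit:
    """Per-species log10 length-weight regression used for QC."""

    species: str
    intercept_a: float  # log10 g at length 1 mm
    slope_beta: float  # allometric slope (~3 for isometric growth)
    resid_sd: float  # residual SD on the log10-mass scale
    n_fit: int


def validate_individual_records(df: pd.DataFrame) -> None:
    """Raise with row indices for nonpositive lengths or masses."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"individual records missing columns: {missing}")
    bad_len = df.index[df["length_mm"] <= 0].tolist()
    if bad_len:
        raise ValueError(f"nonpositive length_mm at rows {bad_len[:20]}")
    mass = df["mass_g"]
    bad_mass = df.index[mass.notna() & (mass <= 0)].tolist()
    if bad_mass:
        raise ValueError(f"nonpositive mass_g at rows {bad_mass[:20]}")


def select_latest_samples(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one sample per site: the most recent one.

    A "sample" is a (site_id, sample_date) group, or (site_id, sample_date,
    sample_id) when a ``sample_id`` column is present.  Ties on date are
    broken by the larger record count, then by first appearance in the input.
    """
    if "site_id" not in records.columns or "sample_date" not in records.columns:
        raise ValueError("records need site_id and sample_date columns")
    df = records.copy()
    dates = pd.to_datetime(df["sample_date"])
    keys = ["site_id", "sample_date"] + (["sample_id"] if "sample_id" in df.columns else [])

    df = df.assign(_date=dates, _order=np.arange(len(df)))
    groups = (
        df.groupby(keys, sort=False)
        .agg(_date=("_date", "first"), _n=("_order", "size"), _first=("_order", "min"))
        .reset_index()
    )
    # latest date, then largest sample, then stable input order
    groups = groups.sort_values(
        ["_date", "_n", "_first"], ascending=[False, False, True], kind="stable"
    )
    best = groups.drop_duplicates("site_id", keep="first")[keys]
    out = df.merge(best, on=keys, how="inner").sort_values("_order")
    return out.drop(columns=["_date", "_order"]).reset_index(drop=True)


def flag_lengthweight_outliers(
    records: pd.DataFrame, min_n: int = 10, z_thresh: float = 3.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag gross length-weight errors per species.

    For every species with at least ``min_n`` records carrying both length
    and mass, ordinary least squares of log10(mass) on log10(length) is fit;
    records whose standardized residual exceeds ``z_thresh`` in magnitude are
    flagged for removal.  Species below ``min_n`` are left unflagged (too few
    points to judge).

    Returns
    -------
    fits : DataFrame
        One row per fitted species (intercept, slope, residual SD, n).
    flags : Series of bool
        Aligned with ``records.index``; True marks an outlier.
    """
    validate_individual_records(records)
    flags = pd.Series(False, index=records.index)
    fits: list[AllometricFit] = []
    paired = records["mass_g"].notna()
    for species, grp in records[paired].groupby("species", sort=True):
        if len(grp) < min_n:
            continue
        lx = np.log10(grp["length_mm"].to_numpy(float))
        ly = np.log10(grp["mass_g"].to_numpy(float))
        X = np.column_stack([np.ones_like(lx), lx])
        beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
        resid = ly - X @ beta
        dof = max(len(grp) - 2, 1)
        sd = float(np.sqrt((resid**2).sum() / dof))
        fits.append(AllometricFit(str(species), float(beta[0]), float(beta[1]), sd, len(grp)))
        if sd > 0:
            flags.loc[grp.index[np.abs(resid / sd) > z_thresh]] = True
    fits_df = pd.DataFrame(
        [f.__dict__ for f in fits],
        columns=["species", "intercept_a", "slope_beta", "resid_sd", "n_fit"],
    )
    return fits_df, flags


def community_weighted_mean(abundances: Mapping[str, float], trait: Mapping[str, float]) -> float:
    """Abundance-weighted mean of a species-level trait.

    ``sum(n_s * t_s) / sum(n_s)`` over species with positive counts; raises
    naming the species if any abundant species lacks a trait value.
    """
    total = 0.0
    weighted = 0.0
    missing = []
    for sp, n in abundances.items():
        if n < 0:
            raise ValueError(f"negative abundance for {sp}")
        if n == 0:
            continue
        t = trait.get(sp)
        if t is None or (isinstance(t, float) and np.isnan(t)):
            missing.append(sp)
            continue
        total += n
        weighted += n * float(t)
    if missing:
        raise ValueError(f"missing trait values for abundant species: {sorted(missing)}")
    if total <= 0:
        raise ValueError("no positive abundances")
    return weighted / total


def assemblage_trait_summary(
    abundance: pd.DataFrame, species_values: pd.DataFrame, value_columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-site CWM of every species-level column in ``species_values``.

    Parameters
    ----------
    abundance : DataFrame
        Columns site_id, species, count.
    species_values : DataFrame
        Indexed by species (or with a ``species`` column); numeric columns
        are averaged with abundance weights.
    """
    vals = species_values.set_index("species") if "species" in species_values.columns else species_values
    cols = value_columns or [c for c in vals.columns if pd.api.types.is_numeric_dtype(vals[c])]
    rows = []
    for site, grp in abundance.groupby("site_id", sort=True):
        counts = dict(zip(grp["species"], grp["count"]))
        row = {"site_id": site}
        for c in cols:
            row[f"cwm_{c}"] = community_weighted_mean(counts, vals[c].to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
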