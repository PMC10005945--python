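"""Biome-level evaluation of predicted rooting depth against field observations.

Point observations of maximum rooting depth cannot be compared pixel-by-pixel
with coarse predictions, so the comparison is made at the biome level:
sites are aggregated by coordinates, optionally capped by the local
water-table depth (roots need not extend below the water table), and the
10% / 90% quantiles of observed and predicted depth are correlated across
biomes (Pearson).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("lon", "lat", "z_obs")


@dataclass(frozen=True)
class BiomeComparison:
    """Per-biome quantile table plus cross-biome Pearson correlation."""

    table: pd.DataFrame  # columns: biome, prob, z_obs_q, z_pred_q, n_sites
    r: float
    p_value: float
    n_biomes: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def aggregate_sites(records: pd.DataFrame, statistic: str = "max") -> pd.DataFrame:
    """Aggregate individual observations to one record per coordinate pair.

    ``z_obs`` (and ``z_pred`` / ``wtd`` when present) is aggregated by
    ``statistic`` ("max", matching the maximum-rooting-depth semantics, or
    "mean"); the biome label of the first record is carried through.
    Records without coordinates are dropped (count logged).
    """
    if statistic not in ("max", "mean"):
        raise ValueError("statistic must be 'max' or 'mean'")
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")

    has_coords = records["lon"].notna() & records["lat"].notna()
    n_dropped = int((~has_coords).sum())
    if n_dropped:
        logger.info("dropped %d records lacking coordinates", n_dropped)
    df = records[has_coords]

    agg: dict = {"z_obs": statistic}
    for col in ("z_pred", "wtd"):
        if col in df.columns:
            agg[col] = statistic
    if "biome" in df.columns:
        agg["biome"] = "first"
    if "site_id" in df.columns:
        agg["site_id"] = "first"

    out = df.groupby(["lon", "lat"], as_index=False).agg(agg)
    return out


def cap_by_wtd(records: pd.DataFrame) -> pd.DataFrame:
    """Cap observed and predicted depths at the water-table depth where known.

    Rows without a WTD pass through unchanged.  Idempotent, never increases
    a depth.
    """
    out = records.copy()
    if "wtd" not in out.columns:
        return out
    has_wtd = out["wtd"].notna()
    out.loc[has_wtd, "z_obs"] = np.minimum(out.loc[has_wtd, "z_obs"], out.loc[has_wtd, "wtd"])
    if "z_pred" in out.columns:
        has_both = has_wtd & out["z_pred"].notna()
        out.loc[has_both, "z_pred"] = np.minimum(
            out.loc[has_both, "z_pred"], out.loc[has_both, "wtd"]
        )
    return out


def biome_quantiles(
    site_records: pd.DataFrame,
    probs: tuple[float, ...] = (0.1, 0.9),
    min_sites: int = 3,
) -> BiomeComparison:
    """Per-biome quantiles of observed and predicted depth, with correlation.

    Biomes with fewer than ``min_sites`` sites are excluded (logged).
    Quantiles use linear interpolation of order statistics.  The Pearson
    correlation pools all (biome, prob) quantile pairs; with fewer than two
    biomes it is undefined and returned as NaN.
    """
    for col in ("biome", "z_obs", "z_pred"):
        if col not in site_records.columns:
            raise ValueError(f"missing required column {col!r}")

    rows = []
    for biome, grp in site_records.groupby("biome"):
        grp = grp[grp["z_obs"].notna() & grp["z_pred"].notna()]
        if len(grp) < min_sites:
            logger.info("biome %r excluded: %d sites < %d", biome, len(grp), min_sites)
            continue
        for p in probs:
            rows.append(
                {
                    "biome": biome,
                    "prob": p,
                    "z_obs_q": float(np.quantile(grp["z_obs"], p)),
                    "z_pred_q": float(np.quantile(grp["z_pred"], p)),
                    "n_sites": len(grp),
                }
            )
    table = pd.DataFrame(rows)
    n_biomes = table["biome"].nunique() if len(table) else 0
    if n_biomes < 2:
        logger.info("correlation undefined with %d biome(s)", n_biomes)
        return BiomeComparison(table=table, r=np.nan, p_value=np.nan, n_biomes=n_biomes)

    r, p = stats.pearsonr(table["z_obs_q"], table["z_pred_q"])
    return BiomeComparison(table=table, r=float(r), p_value=float(p), n_biomes=n_biomes)
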