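"""Return-period screening: which T reconciles the two S0 estimates.

Activity-based estimates (S_dEF / S_dSIF) constrain the return period T of
the extreme-value-based S_CWDXT.  Because inverting the fitted Gumbel for T
is strongly nonlinear, member locations are pooled within coarse blocks
(1 degree cells holding up to 400 fine-resolution members) and a discrete
grid of T values is screened; the best T minimizes the absolute median of
the log bias ln(S_CWDXT / S_activity) across members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rootzone.extremes import GumbelParams, return_level

#: Discrete return periods screened (years).
DEFAULT_T_GRID = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100,
                  150, 200, 250, 300, 350, 400, 450, 500)


class InsufficientDataError(ValueError):
    """Raised when a block has too few members to screen."""


@dataclass
class PooledBlock:
    """Members of one coarse cell: activity-based S0 values and Gumbel fits."""

    block_id: tuple
    s_activity: list[float]
    gumbel_fits: list[GumbelParams]

    def __post_init__(self) -> None:
        if len(self.s_activity) != len(self.gumbel_fits):
            raise ValueError("s_activity and gumbel_fits must align")

    @property
    def n_members(self) -> int:
        return len(self.s_activity)


def pool_blocks(location_table: pd.DataFrame, block_size: float = 1.0) -> list[PooledBlock]:
    """Group per-location results into coarse cells.

    ``location_table`` needs columns ``lon``, ``lat``, ``s0_estimate``,
    ``gumbel_mu``, ``gumbel_beta``, ``n_years`` and optionally
    ``classification``.  Locations without an S0 estimate (flattening or
    rejected) are excluded; empty blocks are omitted.
    """
    df = location_table.copy()
    if "classification" in df.columns:
        df = df[df["classification"] == "estimate"]
    df = df[np.isfinite(df["s0_estimate"].astype(float))]
    if df.empty:
        return []

    bx = np.floor(df["lon"].to_numpy(float) / block_size).astype(int)
    by = np.floor(df["lat"].to_numpy(float) / block_size).astype(int)
    df = df.assign(_bx=bx, _by=by)

    blocks = []
    for (cx, cy), grp in df.groupby(["_bx", "_by"], sort=True):
        fits = [
            GumbelParams(
                location_mu=row.gumbel_mu,
                scale_beta=row.gumbel_beta,
                n_years=int(getattr(row, "n_years", 0) or 0),
            )
            for row in grp.itertuples()
        ]
        blocks.append(
            PooledBlock(
                block_id=(cx, cy),
                s_activity=list(grp["s0_estimate"].astype(float)),
                gumbel_fits=fits,
            )
        )
    return blocks


def screen_return_period(
    block: PooledBlock, t_grid: Sequence[float] = DEFAULT_T_GRID
) -> tuple[float, pd.DataFrame]:
    """Screen the T grid for minimal |median log bias| in one block.

    For each T, per-member bias = ln(return_level(fit_i, T) / s_activity_i);
    the best T minimizes the absolute value of the median bias, with ties
    broken toward the smaller T (parsimony).  Returns
    ``(best_t, profile)`` where ``profile`` has columns ``t`` and
    ``median_log_bias``.
    """
    if block.n_members < 5:
        raise InsufficientDataError(
            f"block {block.block_id}: need >= 5 members, got {block.n_members}"
        )
    s_act = np.asarray(block.s_activity, dtype=float)
    if np.any(s_act <= 0):
        raise ValueError("s_activity values must be positive")

    t_grid = sorted(t_grid)
    medians = []
    for t in t_grid:
        rl = np.array([return_level(fit, t) for fit in block.gumbel_fits])
        bias = np.log(rl / s_act)
        medians.append(float(np.median(bias)))
    medians = np.asarray(medians)
    best_idx = int(np.argmin(np.abs(medians)))  # argmin takes the first == smallest T
    profile = pd.DataFrame({"t": t_grid, "median_log_bias": medians})
    return float(t_grid[best_idx]), profile
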