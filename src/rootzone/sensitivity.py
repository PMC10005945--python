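"""Diagnose S0 from the sensitivity of vegetation activity to the water deficit.

Under a single-store linear stress model, normalized vegetation activity
X' (the evaporative fraction ET/netrad, or SIF normalized by short-wave
radiation) declines linearly with the cumulative water deficit:

    X'(CWD) = a + b * CWD,      S0 = -a / b

because activity extrapolates to zero exactly when the deficit exhausts the
rooting-zone store.  The fit uses, per location, the pooled unmasked days of
the single largest CWD event of each year, reduced to the 90% quantile of X'
within 50 evenly spaced CWD bins (the upper-quantile profile suppresses
activity reductions not caused by water stress).  A linear model competes
against segmented (broken-line) models with one or two change points; the
lowest-BIC model wins.  A winning segmented model whose later slope is
significantly less negative than the first indicates *flattening* -- part of
the vegetation accesses a distinct, larger water store -- and no S0 estimate
is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rootzone.cwd import CwdEvent, CwdSeries, DAYS_PER_YEAR


@dataclass(frozen=True)
class BinnedProfile:
    """Per-bin upper-quantile activity profile along the CWD axis."""

    bin_center: np.ndarray
    q_value: np.ndarray
    n_in_bin: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.q_value)


@dataclass(frozen=True)
class CandidateFit:
    """One fitted candidate model (linear or segmented)."""

    model_class: str  # "linear" | "segmented-1" | "segmented-2"
    coef: np.ndarray  # [intercept, slope1, hinge1, (hinge2)]
    breakpoints: tuple[float, ...]
    rss: float
    n_points: int
    n_params: int
    bic: float
    slope1_se: float
    slope1_p: float  # one-sided P(slope1 < 0 rejected), i.e. H1: slope1 < 0
    flatten_p: float | None = None  # one-sided H1: next slope > slope1
    #: two-sided change-point significance, Bonferroni-adjusted for the
    #: break candidates searched (a conservative Davies-type bound)
    change_p: float | None = None

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def slope1(self) -> float:
        return float(self.coef[1])


@dataclass(frozen=True)
class SensitivityFit:
    """Final per-location sensitivity result.

    ``classification`` is ``estimate`` (linear decline; ``s0_estimate``
    present and equal to -a/b), ``flattening`` (significant slope decrease
    beyond a change point) or ``rejected``.
    """

    model_class: str
    intercept_a: float
    slope_b: float
    changepoints: tuple[float, ...]
    bic_by_model: dict
    slope_p: float
    classification: str
    s0_estimate: float | None = None
    fits: dict = field(default_factory=dict, repr=False)


def select_largest_events(
    series: CwdSeries,
    events: list[CwdEvent],
    activity: np.ndarray,
    days_per_year: int = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Pool (cwd, x_norm) pairs from the single largest CWD event of each year.

    For each year, the non-discarded event with the largest ``max_cwd``
    whose day of maximum falls in that year is selected; its unmasked days
    contribute pairs.  A day's activity reflects the water available at the
    start of that day, so it is paired with the deficit accumulated
    *before* the day (the previous day's CWD; zero on the event's first
    day).  Returns a (possibly empty) two-column DataFrame.
    """
    activity = np.asarray(activity, dtype=float)
    if len(activity) != len(series.cwd):
        raise ValueError("activity must align with the CWD series")

    best_by_year: dict[int, CwdEvent] = {}
    for ev in events:
        if ev.discarded_runaway:
            continue
        year = ev.day_of_max // days_per_year
        cur = best_by_year.get(year)
        if cur is None or ev.max_cwd > cur.max_cwd:
            best_by_year[year] = ev

    rows_cwd: list[np.ndarray] = []
    rows_x: list[np.ndarray] = []
    rows_year: list[np.ndarray] = []
    for year, ev in best_by_year.items():
        sl = slice(ev.start_day, ev.end_day)
        # start-of-day deficit: previous day's CWD, 0 on the first event day
        cwd_start = np.concatenate(([0.0], series.cwd[ev.start_day : ev.end_day - 1]))
        keep = ~series.masked[sl] & ~np.isnan(activity[sl])
        rows_cwd.append(cwd_start[keep])
        rows_x.append(activity[sl][keep])
        rows_year.append(np.full(int(keep.sum()), year))

    if not rows_cwd:
        return pd.DataFrame({"cwd": [], "x_norm": [], "year": []})
    return pd.DataFrame(
        {
            "cwd": np.concatenate(rows_cwd),
            "x_norm": np.concatenate(rows_x),
            "year": np.concatenate(rows_year),
        }
    )


def _binned_quantile_arrays(
    cwd: np.ndarray, x: np.ndarray, n_bins: int, q: float, min_count: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-bin empirical quantile (linear interpolation).

    One lexsort replaces per-bin quantile calls; results match
    ``np.quantile(..., method="linear")`` per bin exactly.
    """
    edges = np.linspace(0.0, cwd.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # right-inclusive last bin so the maximum is not orphaned
    idx = np.clip(np.digitize(cwd, edges[1:-1]), 0, n_bins - 1)

    order = np.lexsort((x, idx))
    idx_s = idx[order]
    x_s = x[order]
    n_in_bin = np.bincount(idx_s, minlength=n_bins)
    starts = np.concatenate(([0], np.cumsum(n_in_bin)[:-1]))

    q_value = np.full(n_bins, np.nan)
    ok = n_in_bin >= min_count
    if ok.any():
        m = n_in_bin[ok]
        pos = q * (m - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, m - 1)
        frac = pos - lo
        base = starts[ok]
        q_value[ok] = (1 - frac) * x_s[base + lo] + frac * x_s[base + hi]
    return centers, q_value, n_in_bin


def bin_quantiles(
    pairs: pd.DataFrame,
    n_bins: int = 50,
    q: float = 0.9,
    min_count: int = 3,
) -> BinnedProfile:
    """Reduce pooled pairs to per-bin empirical quantiles of activity.

    Bins partition [0, max CWD] evenly; bins holding fewer than
    ``min_count`` pairs yield NaN and are dropped from fitting.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if len(pairs) < 1:
        raise ValueError("need at least one (cwd, x_norm) pair")
    cwd = pairs["cwd"].to_numpy(dtype=float)
    x = pairs["x_norm"].to_numpy(dtype=float)
    centers, q_value, n_in_bin = _binned_quantile_arrays(cwd, x, n_bins, q, min_count)
    return BinnedProfile(bin_center=centers, q_value=q_value, n_in_bin=n_in_bin)


def _design(x: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for c in breaks:
        cols.append(np.maximum(x - c, 0.0))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    return coef, rss, rank


def _fit_at_breaks(
    x: np.ndarray, y: np.ndarray, breaks: tuple[float, ...]
) -> tuple[np.ndarray, float]:
    X = _design(x, breaks)
    coef, rss, _ = _ols(X, y)
    return coef, rss


def _inference(x: np.ndarray, y: np.ndarray, breaks: tuple[float, ...], n_search: int = 1):
    """Standard errors and p-values at fixed breakpoints.

    ``n_search`` is the number of break configurations that were screened
    to choose ``breaks``; the two-sided change-point p-value is
    Bonferroni-adjusted by it (times the number of hinge terms) to bound
    the selection effect of the grid search.
    """
    X = _design(x, breaks)
    n, p = X.shape
    coef, rss, rank = _ols(X, y)
    df = n - p
    if df <= 0 or rank < p:
        return coef, rss, np.nan, np.nan, None, None
    sigma2 = rss / df
    try:
        cov = sigma2 * np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        return coef, rss, np.nan, np.nan, None, None
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    slope1_se = se[1]
    # H1: slope1 < 0
    t1 = coef[1] / slope1_se if slope1_se > 0 else np.nan
    slope1_p = float(stats.t.cdf(t1, df)) if np.isfinite(t1) else np.nan
    flatten_p = None
    change_p = None
    if len(breaks) >= 1:
        # hinge coefficients ARE the slope changes; H1 for flattening:
        # first change > 0 (later slope less negative than the first)
        t2 = coef[2] / se[2] if se[2] > 0 else np.nan
        flatten_p = float(stats.t.sf(t2, df)) if np.isfinite(t2) else np.nan
        hinge_ps = []
        for j in range(2, p):
            tj = coef[j] / se[j] if se[j] > 0 else np.nan
            if np.isfinite(tj):
                hinge_ps.append(2.0 * float(stats.t.sf(abs(tj), df)))
        if hinge_ps:
            change_p = min(1.0, min(hinge_ps) * max(n_search, 1) * len(hinge_ps))
    return coef, rss, slope1_se, slope1_p, flatten_p, change_p


def _bic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + n_params * np.log(n)


def fit_candidate_models(
    profile: BinnedProfile, min_points_per_segment: int = 5
) -> dict[str, CandidateFit]:
    """Fit linear and 1-/2-change-point segmented models to a binned profile.

    Segmented fits use exhaustive grid search over bin-center break
    candidates (exact and deterministic for <= 50 bins); continuity at the
    breaks is built into the hinge basis.  Ties break toward smaller RSS
    then the leftmost break.  Each breakpoint counts as one parameter in
    the BIC.  Candidates with fewer usable points than parameters are
    omitted from the result.
    """
    ok = profile.valid
    x = profile.bin_center[ok]
    y = profile.q_value[ok]
    n = len(x)
    if n < 6:
        raise ValueError(f"need >= 6 non-missing binned points, got {n}")

    fits: dict[str, CandidateFit] = {}

    coef, rss, se1, p1, _, _ = _inference(x, y, ())
    fits["linear"] = CandidateFit(
        model_class="linear",
        coef=coef,
        breakpoints=(),
        rss=rss,
        n_points=n,
        n_params=2,
        bic=_bic(rss, n, 2),
        slope1_se=se1,
        slope1_p=p1,
    )

    m = min_points_per_segment
    # interior candidates leaving >= m points strictly on each side
    candidates = [c for c in x[m : n - m]] if n > 2 * m else []

    if n >= 4 + 1 and candidates:
        best = None
        for c in candidates:
            _, rss_c = _fit_at_breaks(x, y, (c,))
            if best is None or rss_c < best[1] - 1e-12:
                best = ((c,), rss_c)
        if best is not None:
            coef, rss, se1, p1, pf, pc = _inference(x, y, best[0], len(candidates))
            fits["segmented-1"] = CandidateFit(
                model_class="segmented-1",
                coef=coef,
                breakpoints=best[0],
                rss=rss,
                n_points=n,
                n_params=4,
                bic=_bic(rss, n, 4),
                slope1_se=se1,
                slope1_p=p1,
                flatten_p=pf,
                change_p=pc,
            )

    if n >= 6 + 1 and len(candidates) >= 2:
        best = None
        n_search = 0
        for i, c1 in enumerate(candidates):
            for c2 in candidates[i + 1 :]:
                # require >= m points between the two breaks
                if np.sum((x > c1) & (x <= c2)) < m:
                    continue
                n_search += 1
                _, rss_c = _fit_at_breaks(x, y, (c1, c2))
                if best is None or rss_c < best[1] - 1e-12:
                    best = ((c1, c2), rss_c)
        if best is not None:
            coef, rss, se1, p1, pf, pc = _inference(x, y, best[0], n_search)
            fits["segmented-2"] = CandidateFit(
                model_class="segmented-2",
                coef=coef,
                breakpoints=best[0],
                rss=rss,
                n_points=n,
                n_params=6,
                bic=_bic(rss, n, 6),
                slope1_se=se1,
                slope1_p=p1,
                flatten_p=pf,
                change_p=pc,
            )
    return fits


def bootstrap_change_test(
    pairs: pd.DataFrame,
    breakpoints: tuple[float, ...],
    n_bins: int = 50,
    q: float = 0.9,
    min_count: int = 3,
    n_boot: int = 499,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Two-stage cluster bootstrap of the slope-change (hinge) coefficients.

    The pooled pairs are dependent within years (each year contributes one
    event), so years are resampled with replacement (capturing event-
    composition uncertainty) and then days are resampled within each drawn
    year (capturing the estimation noise of the per-bin quantiles, which
    in sparse high-CWD bins comes from a single event).  This asks whether
    an apparent change point reflects a reproducible feature of the
    decline or merely pooled-event composition and bin-quantile noise.
    The profile is rebuilt for each resample and the hinge coefficients
    are re-estimated at the *fixed* breakpoints.

    Returns ``(hinge_samples, n_ok)``: an array of shape
    (n_ok, n_breakpoints) of bootstrap hinge coefficients, and the number
    of resamples that yielded a valid fit.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    years = pairs["year"].unique()
    cwd_all = pairs["cwd"].to_numpy(float)
    x_all = pairs["x_norm"].to_numpy(float)
    year_col = pairs["year"].to_numpy()
    by_year = {yr: (cwd_all[year_col == yr], x_all[year_col == yr]) for yr in years}

    samples = []
    for _ in range(n_boot):
        chosen = rng.choice(years, size=len(years), replace=True)
        parts_cwd, parts_x = [], []
        for yr in chosen:
            c_yr, x_yr = by_year[yr]
            idx = rng.integers(0, len(c_yr), size=len(c_yr))
            parts_cwd.append(c_yr[idx])
            parts_x.append(x_yr[idx])
        cwd = np.concatenate(parts_cwd)
        x = np.concatenate(parts_x)
        if cwd.max() <= 0:
            continue
        prof = bin_quantiles(
            pd.DataFrame({"cwd": cwd, "x_norm": x}), n_bins=n_bins, q=q, min_count=min_count
        )
        ok = prof.valid
        xs, ys = prof.bin_center[ok], prof.q_value[ok]
        # each segment needs enough support in the resample, else the
        # hinge coefficient is ill-conditioned and only adds wild tails
        if len(xs) < len(breakpoints) + 3 or any(
            np.sum(xs < c) < 4 or np.sum(xs > c) < 4 for c in breakpoints
        ):
            continue
        coef, _, rank = _ols(_design(xs, breakpoints), ys)
        if rank < 2 + len(breakpoints):
            continue
        samples.append(coef[2:])
    return np.asarray(samples), len(samples)


def change_point_verdict(
    hinge_samples: np.ndarray, alpha: float = 0.05
) -> tuple[bool, bool]:
    """Bootstrap verdict: (significant change point, significant flattening).

    A change point is credible when the two-sided percentile interval of
    some hinge coefficient (Bonferroni across hinges) excludes zero;
    flattening additionally requires the first hinge to be positive (the
    post-break slope significantly less negative) at one-sided ``alpha``.
    """
    if hinge_samples.ndim != 2 or len(hinge_samples) < 20:
        return False, False
    k = hinge_samples.shape[1]
    a2 = alpha / (2 * k)
    significant = False
    for j in range(k):
        lo, hi = np.quantile(hinge_samples[:, j], [a2, 1 - a2])
        if lo > 0 or hi < 0:
            significant = True
    flattening = significant and float(np.quantile(hinge_samples[:, 0], alpha)) > 0
    return significant, flattening


def classify_and_estimate(
    fits: dict[str, CandidateFit],
    alpha: float = 0.05,
    change_significant: bool | None = None,
    flatten_significant: bool | None = None,
    min_slope_change_frac: float = 0.2,
) -> SensitivityFit:
    """Select the lowest-BIC model and classify the location.

    S0 is quantified only where *no significant change point* is detected
    and the linear decline is significantly negative:

    * no significant change point (linear wins the BIC, or a segmented
      winner's change point fails the significance test) and the linear
      slope is significantly negative -> ``estimate`` with S0 = -a/b from
      the linear fit;
    * significant change point whose post-break slope is significantly
      less negative than the first segment's -> ``flattening``, no S0;
    * anything else -> ``rejected``.

    ``change_significant`` / ``flatten_significant`` carry the verdict of
    the year-level bootstrap (:func:`change_point_verdict`); when omitted,
    the parametric search-adjusted t tests stored on the winning fit are
    used instead.  Besides statistical significance, a change point must
    be practically meaningful: the largest slope change must amount to at
    least ``min_slope_change_frac`` of the first-segment slope (with very
    clean data, negligible profile wiggles are otherwise "significant"
    without constituting a distinct hydrological regime).
    """
    if "linear" not in fits:
        raise ValueError("the linear fit must always be available")
    winner = min(fits.values(), key=lambda f: f.bic)
    bic_by_model = {name: f.bic for name, f in fits.items()}

    if winner.model_class == "linear":
        significant_change = False
    else:
        if change_significant is not None:
            significant_change = change_significant
        else:
            significant_change = (
                winner.change_p is not None
                and np.isfinite(winner.change_p)
                and winner.change_p < alpha
            )
        if significant_change and abs(winner.slope1) > 0:
            effect = np.max(np.abs(winner.coef[2:])) / abs(winner.slope1)
            significant_change = effect >= min_slope_change_frac

    if flatten_significant is None:
        flatten_significant = (
            winner.flatten_p is not None
            and np.isfinite(winner.flatten_p)
            and winner.flatten_p < alpha
        )

    classification = "rejected"
    s0 = None
    if significant_change:
        reported = winner
        if flatten_significant:
            classification = "flattening"
    else:
        # no credible change point: quantify from the plain linear decline
        reported = fits["linear"]
        if reported.slope1 < 0 and np.isfinite(reported.slope1_p) and reported.slope1_p < alpha:
            classification = "estimate"
            s0 = -reported.intercept / reported.slope1

    return SensitivityFit(
        model_class=winner.model_class,
        intercept_a=reported.intercept,
        slope_b=reported.slope1,
        changepoints=reported.breakpoints,
        bic_by_model=bic_by_model,
        slope_p=reported.slope1_p,
        classification=classification,
        s0_estimate=s0,
        fits=fits,
    )


def estimate_s0(
    series: CwdSeries,
    events: list[CwdEvent],
    activity: np.ndarray,
    n_bins: int = 50,
    q: float = 0.9,
    alpha: float = 0.05,
    min_count: int = 3,
    days_per_year: int = DAYS_PER_YEAR,
    n_boot: int = 499,
    seed: int = 0,
) -> SensitivityFit:
    """Full sensitivity chain: pool largest events, bin, fit, classify.

    When a segmented model wins the BIC, the change point is vetted by the
    year-level cluster bootstrap (``n_boot`` resamples, seeded by
    ``seed``); set ``n_boot=0`` to rely on the parametric t tests only.
    """
    pairs = select_largest_events(series, events, activity, days_per_year)
    if len(pairs) == 0:
        raise ValueError("no CWD events available for the sensitivity analysis")
    profile = bin_quantiles(pairs, n_bins=n_bins, q=q, min_count=min_count)
    fits = fit_candidate_models(profile)

    change_sig = flatten_sig = None
    winner = min(fits.values(), key=lambda f: f.bic)
    if winner.model_class != "linear" and n_boot > 0:
        samples, n_ok = bootstrap_change_test(
            pairs,
            winner.breakpoints,
            n_bins=n_bins,
            q=q,
            min_count=min_count,
            n_boot=n_boot,
            rng=np.random.default_rng(seed),
        )
        boot_change, boot_flatten = change_point_verdict(samples, alpha=alpha)
        # a credible change point must pass both the search-adjusted
        # parametric test and the cluster bootstrap: the former guards
        # against composition artifacts the bootstrap reproduces, the
        # latter against bin-quantile noise the parametric test ignores
        param_change = (
            winner.change_p is not None
            and np.isfinite(winner.change_p)
            and winner.change_p < alpha
        )
        change_sig = boot_change and param_change
        flatten_sig = boot_flatten
    return classify_and_estimate(
        fits, alpha=alpha, change_significant=change_sig, flatten_significant=flatten_sig
    )
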