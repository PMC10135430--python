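"""Pause kinetics from gel band-intensity time courses.

A transcription time course run on a denaturing gel gives, per timepoint
(lane), the band intensity at each transcript position.  Normalising the
pause-band intensity P to the lane total T gives the fraction of polymerases
paused at that site; its decay over time is single-exponential for a simple
pause and biphasic when a second, longer-lived ("sluggish") paused
population exists.  Fitting log10(P/T) against time therefore yields the
pause efficiency (y-intercept) and apparent pause duration (slope); a
two-segment piecewise fit resolves the slow and sluggish populations.

Because not every polymerase reaches the pause site within the assay, the
raw intercept underestimates the efficiency.  The cumulative intensity from
the pause band and beyond (A/T) saturates at the fraction F of polymerases
that arrived; dividing the raw efficiency by F gives the arrival-corrected
efficiency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import PauseEstimate

__all__ = [
    "GelTimeCourse",
    "TwoSegmentFit",
    "normalize_lanes",
    "cumulative_arrival",
    "fit_single_exponential_decay",
    "fit_two_segment",
    "fit_arrival",
    "termination_stats",
    "initial_rate",
    "bootstrap_fit",
]

TERMINATION = "termination"
RUNOFF = "runoff"


@dataclass
class GelTimeCourse:
    """Band-intensity matrix: rows = transcript positions, columns = lanes.

    ``intensities`` is indexed by band label (stringified positions plus
    special bands such as "termination" / "runoff"); columns are timepoints.
    ``band_labels`` maps band index labels to semantic roles
    ({"P1", "HP", "termination", "runoff", "other"}).  ``time_unit`` is
    "s" or "min".
    """

    intensities: pd.DataFrame
    band_labels: dict = field(default_factory=dict)
    time_unit: str = "s"

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("band intensities must be non-negative")
        t = np.asarray(self.intensities.columns, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    def band(self, role: str) -> str:
        """Return the band index label carrying the given semantic role."""
        for label, r in self.band_labels.items():
            if r == role:
                return label
        raise KeyError(f"no band labelled {role!r}")


@dataclass
class TwoSegmentFit:
    """Result of the two-segment semilog decay fit.

    The first (early, steeper) segment characterises the slow paused
    population, the second the sluggish one.  Efficiencies are the
    10^intercept extrapolations of each segment, arrival-corrected when an
    arrival fraction is supplied; durations are -1/(slope*ln10).
    """

    e_slow: float
    t_slow_app: float
    e_sluggish: float
    t_sluggish_app: float
    breakpoint: float
    sse: float
    degenerate: bool = False
    single: PauseEstimate | None = None
    ci: dict = field(default_factory=dict)


def normalize_lanes(gel: GelTimeCourse) -> pd.DataFrame:
    """Per-lane band fractions, each lane normalised to its total intensity.

    Raises if any lane total is zero (empty lane cannot be normalised).
    """
    totals = gel.intensities.sum(axis=0)
    bad = np.flatnonzero(totals.values <= 0)
    if bad.size:
        raise ValueError(f"zero-total lane(s) at column index {bad.tolist()}")
    return gel.intensities / totals


def cumulative_arrival(gel: GelTimeCourse, position) -> pd.Series:
    """Fraction of signal at `position` and farther (A/T) per lane.

    Bands whose labels parse as integers at or beyond ``position`` are
    summed, as are the termination and runoff bands, then normalised to the
    lane total.  This is the cumulative-arrival curve whose plateau is the
    fraction of polymerases that reached the site during the assay.
    """
    fractions = normalize_lanes(gel)
    rows = []
    for label in fractions.index:
        if label in (TERMINATION, RUNOFF):
            rows.append(label)
            continue
        try:
            if int(label) >= int(position):
                rows.append(label)
        except (TypeError, ValueError):
            continue
    return fractions.loc[rows].sum(axis=0)


def _semilog_points(timepoints, fractions):
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(fractions, dtype=float)
    keep = f > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} non-positive fraction(s) before "
            "log transform", stacklevel=3)
    return t[keep], np.log10(f[keep])


def _line_to_estimate(slope: float, intercept: float,
                      arrival_fraction: float | None) -> PauseEstimate:
    k = -slope * math.log(10.0)
    if k <= 0:
        raise ValueError("decay fit produced a non-positive escape rate")
    e_raw = 10.0 ** intercept
    capped = False
    e = e_raw
    if arrival_fraction is not None:
        if arrival_fraction <= 0:
            raise ValueError("arrival_fraction must be > 0")
        e = e_raw / arrival_fraction
    if e > 1.0:
        e, capped = 1.0, True
    return PauseEstimate(
        efficiency=e,
        duration_apparent=1.0 / k,
        escape_rate_apparent=k,
        half_life=math.log(2.0) / k,
        efficiency_raw=e_raw,
        capped=capped,
    )


def fit_single_exponential_decay(
    timepoints,
    pause_fractions,
    arrival_fraction: float | None = None,
) -> PauseEstimate:
    """Fit P(t) = P0 * exp(-k * t) on a semilog scale.

    Ordinary least squares of log10(P/T) on t; the escape rate is
    -slope * ln(10), the raw efficiency 10^intercept, divided by the
    arrival fraction F when given.  Non-positive fractions (noise) are
    dropped with a warning; at least three positive points are required.
    """
    t, logf = _semilog_points(timepoints, pause_fractions)
    if t.size < 3:
        raise ValueError("need >= 3 positive fractions for a decay fit")
    res = stats.linregress(t, logf)
    return _line_to_estimate(res.slope, res.intercept, arrival_fraction)


def _two_line_sse(t, y, split):
    """Peeled two-segment fit at one breakpoint.

    The late segment (sluggish population) is a least-squares line on the
    raw log10 fractions beyond the split.  Its extrapolation is subtracted
    from the early fractions (classic exponential peeling) and the early
    (slow) segment fit to the log10 residual, so each intercept is that
    population's own amplitude.  The SSE scored is of the full
    two-exponential sum against the data in log space.
    """
    frac = 10.0 ** y
    fast = np.zeros_like(frac)
    res1 = None
    for _ in range(4):
        resid2 = frac[split:] - fast[split:]
        keep2 = resid2 > 0
        if keep2.sum() < 2:
            return math.inf, None
        res2 = stats.linregress(t[split:][keep2], np.log10(resid2[keep2]))
        slug = 10.0 ** (res2.intercept + res2.slope * t)
        resid1 = frac[:split] - slug[:split]
        keep1 = resid1 > 0
        if keep1.sum() < 2:
            return math.inf, None
        res1 = stats.linregress(t[:split][keep1], np.log10(resid1[keep1]))
        fast = 10.0 ** (res1.intercept + res1.slope * t)
    model = fast + 10.0 ** (res2.intercept + res2.slope * t)
    sse = float(np.sum((y - np.log10(model)) ** 2))
    return sse, [(res1.slope, res1.intercept), (res2.slope, res2.intercept)]


def _aicc(n: int, sse: float, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(sse, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_two_segment(
    timepoints,
    pause_fractions,
    arrival_fraction: float | None = None,
    min_points: int = 3,
) -> TwoSegmentFit:
    """Two-segment piecewise semilog fit resolving slow and sluggish decays.

    Every breakpoint leaving at least ``min_points`` observations per
    segment is tried; for each, two independent lines are fit to
    log10(fraction) vs t and the split with the smallest total SSE wins.
    The extrapolated 10^intercept of each segment gives that population's
    efficiency (arrival-corrected when F is supplied) and -1/(slope*ln10)
    its apparent duration.

    When a small-sample AIC prefers a single line, the result is flagged
    ``degenerate`` and carries the single-exponential estimate.
    """
    t, logf = _semilog_points(timepoints, pause_fractions)
    n = t.size
    if n < 2 * min_points:
        raise ValueError(
            f"need >= {2 * min_points} positive fractions spanning both regimes")

    best = None
    for split in range(min_points, n - min_points + 1):
        sse, lines = _two_line_sse(t, logf, split)
        if lines is None:
            continue
        if best is None or sse < best[0]:
            best = (sse, split, lines)
    single_fallback = best is None
    if not single_fallback:
        sse, split, ((s1, b1), (s2, b2)) = best

    single_res = stats.linregress(t, logf)
    sse_single = float(np.sum(
        (logf - single_res.intercept - single_res.slope * t) ** 2))
    single = _line_to_estimate(single_res.slope, single_res.intercept,
                               arrival_fraction)
    if single_fallback:
        return TwoSegmentFit(
            e_slow=single.efficiency, t_slow_app=single.duration_apparent,
            e_sluggish=single.efficiency, t_sluggish_app=single.duration_apparent,
            breakpoint=float(t[-1]), sse=sse_single, degenerate=True,
            single=single)

    # two segments: 4 line coefficients + breakpoint; single line: 2
    degenerate = _aicc(n, sse, 5) >= _aicc(n, sse_single, 2)
    # unidentifiable when the two slopes are essentially equal
    if s1 < 0 and s2 < 0 and 0.8 < s1 / s2 < 1.25:
        degenerate = True
    # an inverted amplitude ordering (slow amplitude below sluggish) marks a
    # spurious peel of what is really a single decay
    if 10.0 ** b1 < 10.0 ** b2:
        degenerate = True

    if s1 >= 0 or s2 >= 0:
        return TwoSegmentFit(
            e_slow=single.efficiency, t_slow_app=single.duration_apparent,
            e_sluggish=single.efficiency, t_sluggish_app=single.duration_apparent,
            breakpoint=float(t[split - 1]), sse=sse, degenerate=True,
            single=single)

    slow = _line_to_estimate(s1, b1, arrival_fraction)
    sluggish = _line_to_estimate(s2, b2, arrival_fraction)
    return TwoSegmentFit(
        e_slow=slow.efficiency,
        t_slow_app=slow.duration_apparent,
        e_sluggish=sluggish.efficiency,
        t_sluggish_app=sluggish.duration_apparent,
        breakpoint=float(0.5 * (t[split - 1] + t[split])),
        sse=sse,
        degenerate=degenerate,
        single=single,
    )


def fit_arrival(timepoints, cumulative_fractions):
    """Fit the cumulative-arrival curve F(t) = F_plateau * (1 - exp(-t/tau)).

    Returns ``(F_plateau, t_half)`` where ``t_half = tau * ln 2`` is the
    half-maximal arrival time.  Warns on clearly non-monotone input.
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(cumulative_fractions, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 points for an arrival fit")
    drops = np.diff(f)
    if (drops < -0.05 * max(f.max(), 1e-12)).any():
        warnings.warn("cumulative arrival decreases beyond noise tolerance")

    fmax = float(f.max())
    tmid = float(t[np.searchsorted(f, 0.5 * fmax)]) if fmax > 0 else float(t[-1])
    popt, _ = optimize.curve_fit(
        lambda tt, fp, tau: fp * (1.0 - np.exp(-tt / tau)),
        t, f, p0=[max(fmax, 1e-6), max(tmid / math.log(2.0), t[1] - t[0])],
        bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000)
    f_plateau, tau = popt
    return float(f_plateau), float(tau * math.log(2.0))


def termination_stats(gel: GelTimeCourse) -> tuple[float, float]:
    """Termination and runoff fractions in the final lane.

    Requires bands labelled "termination" and "runoff" in
    ``gel.band_labels``.
    """
    term_band = gel.band(TERMINATION)
    runoff_band = gel.band(RUNOFF)
    fractions = normalize_lanes(gel)
    last = fractions.iloc[:, -1]
    return float(last.loc[term_band]), float(last.loc[runoff_band])


def initial_rate(timepoints, fractions, window: int = 3) -> float:
    """Initial accumulation rate: slope of a line over the first points.

    ``window`` early points (>= 2) are fit by least squares; the slope is
    in fraction per time unit of ``timepoints``.
    """
    if window < 2:
        raise ValueError("window must cover >= 2 points")
    t = np.asarray(timepoints, dtype=float)[:window]
    f = np.asarray(fractions, dtype=float)[:window]
    if t.size < 2:
        raise ValueError("not enough points in window")
    return float(stats.linregress(t, f).slope)


def bootstrap_fit(
    timepoints,
    pause_fractions,
    fit,
    extract,
    n_boot: int = 200,
    seed: int | None = None,
    levels: tuple = (0.95,),
):
    """Nonparametric bootstrap over timepoints for any decay fit.

    ``fit(t, f)`` performs the fit and ``extract(result)`` returns a dict of
    scalars; resampled timepoint/fraction pairs are refit ``n_boot`` times
    and percentile intervals at each confidence ``level`` returned as
    ``{param: {level: (lo, hi)}}``.  Resamples on which the fit fails are
    skipped.
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(pause_fractions, dtype=float)
    rng = np.random.default_rng(seed)
    samples: dict[str, list] = {}
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, t.size, size=t.size))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit(t[idx], f[idx])
        except (ValueError, RuntimeError):
            continue
        for key, val in extract(res).items():
            samples.setdefault(key, []).append(val)
    out: dict[str, dict] = {}
    for key, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[key] = {}
        for level in levels:
            alpha = 100.0 * (1.0 - level) / 2.0
            if arr.size:
                out[key][level] = (float(np.percentile(arr, alpha)),
                                   float(np.percentile(arr, 100.0 - alpha)))
            else:
                out[key][level] = (math.nan, math.nan)
    return out
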