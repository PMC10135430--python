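"""Single-molecule optical-tweezers transcription trace analysis.

An RNAP tethered between two trapped beads transcribes against (or with) a
constant force; the bead-to-bead distance reports the DNA tether length.
The pipeline implemented here:

1. convert measured extension (nm) at the held force to template contour
   length in bp with the extensible worm-like chain (WLC) model;
2. fit a monotone 1-bp staircase to the position signal with a hidden
   Markov model (integer-bp states, stay/+1 transitions, Gaussian
   emissions, Viterbi decoding) to segment translocation from pausing;
3. classify dwells longer than 0.5 s as pauses and compute the pause
   density (pauses per bp transcribed);
4. estimate the pause-free velocity (PFV) from Savitzky-Golay filtered
   velocities of the translocating sections, fit as a two-Gaussian
   histogram (one component pinned at zero for residual short pauses);
5. locate pause sites as peaks of the pooled residence-time histogram and
   measure crossing times through a 5-bp window around each site;
6. fit the crossing-time distribution to a two-exponential mixture by
   maximum likelihood, giving the pause efficiency E = a2/(a1+a2) and
   pause duration tau = 1/k2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.special import expit, logsumexp, logit

__all__ = [
    "WLCParams",
    "TraceSignal",
    "StepPath",
    "BiexpFit",
    "PFVResult",
    "wlc_extension_factor",
    "extension_from_contour",
    "contour_length_from_extension",
    "fit_staircase",
    "pause_catalog",
    "pause_free_velocity",
    "locate_pause_sites",
    "crossing_times",
    "fit_biexponential",
]

DEFAULT_SAMPLE_RATE_HZ = 1333.0  # instrument acquisition rate


@dataclass(frozen=True)
class WLCParams:
    """Extensible worm-like chain elasticity of the dsDNA tether.

    Defaults are standard dsDNA values: persistence length 45 nm, stretch
    modulus 1200 pN, kBT = 4.11 pN nm (25 C), helical rise 0.34 nm/bp.
    """

    persistence_length_nm: float = 45.0
    stretch_modulus_pn: float = 1200.0
    kbt: float = 4.11
    rise_per_bp_nm: float = 0.34

    def __post_init__(self) -> None:
        if min(self.persistence_length_nm, self.stretch_modulus_pn,
               self.kbt, self.rise_per_bp_nm) <= 0:
            raise ValueError("all WLC parameters must be > 0")


@dataclass
class TraceSignal:
    """Sampled (time, distance, force) record of one tether.

    ``time_s`` is a uniform grid; ``distance_nm`` the bead-to-bead
    distance; ``force_pn`` the held force.  ``position_bp`` is filled by
    the WLC conversion.
    """

    time_s: np.ndarray
    distance_nm: np.ndarray
    force_pn: float
    position_bp: np.ndarray | None = None

    @property
    def sample_rate_hz(self) -> float:
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid is not uniform")
        return 1.0 / float(dt[0]) if dt.size else math.nan


@dataclass
class StepPath:
    """Monotone staircase: one row per dwell at an integer bp position."""

    position_bp: np.ndarray   # int positions, strictly increasing by 1
    t_start: np.ndarray       # s
    t_end: np.ndarray         # s (end of dwell, start of the next)

    def __post_init__(self) -> None:
        pos = np.asarray(self.position_bp)
        if pos.size > 1 and not np.all(np.diff(pos) == 1):
            raise ValueError("step path must increase by exactly 1 bp per step")
        if np.any(np.asarray(self.t_end) < np.asarray(self.t_start)):
            raise ValueError("dwell end times precede start times")

    @property
    def dwell_s(self) -> np.ndarray:
        return np.asarray(self.t_end) - np.asarray(self.t_start)

    @property
    def bp_transcribed(self) -> int:
        return int(self.position_bp[-1] - self.position_bp[0])


@dataclass
class BiexpFit:
    """Two-exponential mixture fit of crossing times.

    PDF = a1*k1*exp(-k1 t) + a2*k2*exp(-k2 t) with a1 + a2 = 1 and
    k1 > k2.  The fast component represents transits that did not pause;
    E = a2 is the pause efficiency and tau = 1/k2 the pause duration.
    """

    a1: float
    a2: float
    k1: float
    k2: float
    loglik: float
    degenerate: bool = False
    ci: dict = field(default_factory=dict)

    @property
    def efficiency(self) -> float:
        return self.a2 / (self.a1 + self.a2)

    @property
    def tau(self) -> float:
        return 1.0 / self.k2


@dataclass
class PFVResult:
    """Pause-free velocity estimate from the two-Gaussian velocity fit."""

    pfv_bp_s: float
    zero_weight: float
    moving_weight: float
    sigma_zero: float
    sigma_moving: float
    undefined: bool = False


# ---------------------------------------------------------------------------
# WLC conversion
# ---------------------------------------------------------------------------

def wlc_extension_factor(force_pn: float, wlc: WLCParams) -> float:
    """Fractional extension x/L at a force, interpolation-formula eWLC.

    x/L = 1 - (1/2) sqrt(kBT / (F Lp)) + F/K.  Valid above ~0.1 pN.
    """
    if force_pn <= 0.1:
        raise ValueError("WLC conversion requires force > 0.1 pN")
    return (1.0
            - 0.5 * math.sqrt(wlc.kbt / (force_pn * wlc.persistence_length_nm))
            + force_pn / wlc.stretch_modulus_pn)


def extension_from_contour(contour_bp, force_pn: float,
                           wlc: WLCParams = WLCParams()):
    """Forward model: tether extension (nm) of a contour length in bp."""
    c = wlc_extension_factor(force_pn, wlc)
    return np.asarray(contour_bp, dtype=float) * wlc.rise_per_bp_nm * c


def contour_length_from_extension(distance_nm, force_pn: float,
                                  wlc: WLCParams = WLCParams()):
    """Invert the eWLC: contour length in bp from extension at a force.

    With the interpolation formula the fractional extension is independent
    of L, so the inversion is exact: L = x / (c * rise).
    """
    c = wlc_extension_factor(force_pn, wlc)
    return np.asarray(distance_nm, dtype=float) / (c * wlc.rise_per_bp_nm)


# ---------------------------------------------------------------------------
# Staircase HMM
# ---------------------------------------------------------------------------

def _estimate_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the MAD of first differences (high-pass estimate)."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    sd = 1.4826 * mad / math.sqrt(2.0)
    return float(sd)


def fit_staircase(
    position_bp,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    noise_sd: float | None = None,
    step_prob: float | None = None,
    decimate: int = 1,
) -> StepPath:
    """Fit a 1-bp monotone staircase to a position signal by Viterbi HMM.

    Hidden states are integer bp positions spanning the signal range;
    transitions are restricted to {stay, +1} with per-sample stepping
    probability ``step_prob`` (default: expected step count / samples);
    emissions are Gaussian with SD ``noise_sd`` (default: MAD estimate of
    the high-frequency noise).  The Viterbi path is monotone nondecreasing
    by construction.

    ``decimate`` block-averages that many raw samples before decoding;
    at acquisition noise of order a few bp per sample this trades time
    resolution for the SNR the 1-bp state grid needs.

    Raises on a clearly decreasing signal: monotone transcription is a
    contract of this model.
    """
    y = np.asarray(position_bp, dtype=float)
    if decimate > 1:
        n = (y.size // decimate) * decimate
        if n == 0:
            raise ValueError("signal shorter than one decimation block")
        y = y[:n].reshape(-1, decimate).mean(axis=1)
        sample_rate_hz = sample_rate_hz / decimate
    if y.size < 2:
        raise ValueError("signal too short")
    sd = _estimate_noise_sd(y) if noise_sd is None else float(noise_sd)
    if not np.isfinite(sd):
        raise ValueError("noise SD estimate failed")
    sd = max(sd, 1e-3)

    if y[-1] - y[0] < -5.0 * sd - 1.0:
        raise ValueError("signal decreases overall; staircase model "
                         "requires nondecreasing positions")

    lo = int(math.floor(np.percentile(y, 0.5)))
    hi = int(math.ceil(np.percentile(y, 99.5)))
    hi = max(hi, lo + 1)
    states = np.arange(lo, hi + 1)
    n_states = states.size

    if step_prob is None:
        step_prob = min(0.5, max((hi - lo) / y.size, 1e-6))
    log_stay = math.log1p(-step_prob)
    log_step = math.log(step_prob)

    # Viterbi with banded transitions: predecessor is self or self-1
    ll_obs = -0.5 * ((y[:, None] - states[None, :]) / sd) ** 2
    delta = ll_obs[0].copy()  # uniform prior over starting states
    back = np.zeros((y.size, n_states), dtype=bool)  # True = stepped
    for t in range(1, y.size):
        stay = delta + log_stay
        step = np.full(n_states, -np.inf)
        step[1:] = delta[:-1] + log_step
        stepped = step > stay
        delta = np.where(stepped, step, stay) + ll_obs[t]
        back[t] = stepped

    path = np.empty(y.size, dtype=np.int64)
    s = int(np.argmax(delta))
    path[-1] = s
    for t in range(y.size - 1, 0, -1):
        if back[t, s]:
            s -= 1
        path[t - 1] = s

    positions = states[path]
    change = np.flatnonzero(np.diff(positions)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [y.size]])
    dt = 1.0 / sample_rate_hz
    return StepPath(
        position_bp=positions[starts],
        t_start=starts * dt,
        t_end=ends * dt,
    )


# ---------------------------------------------------------------------------
# Pause catalogue and pause-free velocity
# ---------------------------------------------------------------------------

def pause_catalog(step_path: StepPath, min_dwell_s: float = 0.5,
                  exclude_boundaries: bool = True):
    """Dwells longer than the threshold, and the pause density.

    A dwell exceeding ``min_dwell_s`` (default 0.5 s) is a pause.  The
    first and last dwells are excluded by default: the first is the
    pre-experiment stall and the last is truncated by the end of the
    record.  Density = pauses / bp transcribed.
    """
    dwell = step_path.dwell_s
    pos = np.asarray(step_path.position_bp)
    if dwell.size == 0:
        raise ValueError("empty step path")
    sel = np.ones(dwell.size, dtype=bool)
    if exclude_boundaries and dwell.size > 2:
        sel[0] = sel[-1] = False
    mask = sel & (dwell > min_dwell_s)
    pauses = [
        {"position_bp": int(pos[i]), "t_start": float(step_path.t_start[i]),
         "duration_s": float(dwell[i])}
        for i in np.flatnonzero(mask)
    ]
    bp = max(step_path.bp_transcribed, 1)
    return pauses, len(pauses) / bp


def _sg_window_samples(width_s: float, sample_rate_hz: float) -> int:
    w = int(round(width_s * sample_rate_hz))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def pause_free_velocity(
    position_bp,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    step_path: StepPath | None = None,
    min_dwell_s: float = 0.5,
    filter_width_s: float = 0.150,
    bin_width: float = 0.25,
) -> PFVResult:
    """Pause-free velocity from filtered velocities of moving sections.

    The position signal is differentiated with a first-order Savitzky-
    Golay filter (window = nearest odd sample count to ``filter_width_s``);
    samples inside pauses (from ``step_path``, fitted if not given) are
    discarded; the remaining velocities are histogrammed at ``bin_width``
    bp/s and fit with two Gaussians, one pinned at zero for residual short
    pauses and one at positive velocity whose mean is the PFV.
    """
    y = np.asarray(position_bp, dtype=float)
    window = _sg_window_samples(filter_width_s, sample_rate_hz)
    if y.size <= window:
        raise ValueError("signal shorter than the differentiating window")
    vel = signal.savgol_filter(y, window, polyorder=1, deriv=1,
                               delta=1.0 / sample_rate_hz)

    if step_path is None:
        step_path = fit_staircase(y, sample_rate_hz)
    pauses, _ = pause_catalog(step_path, min_dwell_s,
                              exclude_boundaries=True)
    keep = np.ones(y.size, dtype=bool)
    for p in pauses:
        i0 = int(round(p["t_start"] * sample_rate_hz))
        i1 = i0 + int(round(p["duration_s"] * sample_rate_hz))
        keep[i0:i1 + 1] = False
    # trim filter edge effects
    keep[:window // 2] = keep[-(window // 2):] = False
    v = vel[keep]
    if v.size < 10:
        return PFVResult(math.nan, math.nan, math.nan, math.nan, math.nan,
                         undefined=True)

    edges = np.arange(v.min() - bin_width, v.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, a0, s0, a1, mu1, s1):
        return (a0 * np.exp(-0.5 * (x / s0) ** 2)
                + a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2))

    vpos = v[v > bin_width]
    mu0 = float(np.median(vpos)) if vpos.size else float(np.mean(v))
    amax = float(counts.max())
    p0 = [amax / 2, max(bin_width, np.std(v[v <= bin_width]) if
                        (v <= bin_width).any() else bin_width),
          amax / 2, max(mu0, bin_width), max(bin_width, np.std(v) / 2)]
    lower = [0.0, bin_width / 4, 0.0, 0.0, bin_width / 4]
    upper = [np.inf, np.inf, np.inf, np.inf, np.inf]
    try:
        with warnings.catch_warnings():
            # covariance is not used; singular on near-delta histograms
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(model, centers, counts, p0=p0,
                                         bounds=(lower, upper), maxfev=20000)
    except (RuntimeError, ValueError):
        return PFVResult(math.nan, math.nan, math.nan, math.nan, math.nan,
                         undefined=True)
    a0, s0, a1, mu1, s1 = popt
    undefined = mu1 <= bin_width / 2 or a1 <= 0
    return PFVResult(float(mu1), float(a0), float(a1), float(s0), float(s1),
                     undefined=bool(undefined))


# ---------------------------------------------------------------------------
# Pause sites and crossing times
# ---------------------------------------------------------------------------

def locate_pause_sites(step_paths, prominence: float | None = None,
                       region: tuple | None = None):
    """Pause positions as peaks of the pooled residence-time histogram.

    Dwell times of all traces (aligned to a common start) are summed into
    1-bp bins; peaks exceeding ``prominence`` (default: 5x the median
    positive residence) are returned.  ``region=(lo, hi)`` restricts the
    search, e.g. to avoid the stall site.
    """
    if len(step_paths) < 2:
        raise ValueError("need >= 2 traces to pool residence times")
    lo = min(int(p.position_bp[0]) for p in step_paths)
    hi = max(int(p.position_bp[-1]) for p in step_paths)
    residence = np.zeros(hi - lo + 1)
    for p in step_paths:
        idx = np.asarray(p.position_bp, dtype=int) - lo
        np.add.at(residence, idx, p.dwell_s)
    positions = np.arange(lo, hi + 1)
    if region is not None:
        sel = (positions >= region[0]) & (positions <= region[1])
        positions, residence = positions[sel], residence[sel]
    pos_res = residence[residence > 0]
    if prominence is None:
        if pos_res.size == 0:
            return np.array([], dtype=int)
        prominence = 5.0 * float(np.median(pos_res))
    peaks, _ = signal.find_peaks(residence, prominence=prominence)
    return positions[peaks]


def crossing_times(step_paths, center_bp: float, halfwidth_bp: float = 2.5):
    """Per-trace time to traverse a window around a pause locus.

    Entry is the first arrival at ``center - halfwidth``; exit the first
    arrival beyond ``center + halfwidth``.  Traces that never exit are
    censored and excluded; their count is returned alongside.
    """
    lo_edge = center_bp - halfwidth_bp
    hi_edge = center_bp + halfwidth_bp
    if all(p.position_bp[-1] < lo_edge for p in step_paths) or \
            all(p.position_bp[0] > hi_edge for p in step_paths):
        raise ValueError("crossing window outside every trace")
    durations = []
    n_censored = 0
    for p in step_paths:
        pos = np.asarray(p.position_bp, dtype=float)
        if pos[0] > lo_edge:
            continue  # window already behind the trace at its start
        inside = np.flatnonzero(pos >= lo_edge)
        beyond = np.flatnonzero(pos > hi_edge)
        if inside.size == 0 or beyond.size == 0:
            n_censored += 1  # ended inside or before the window
            continue
        t_in = float(p.t_start[inside[0]])
        t_out = float(p.t_start[beyond[0]])
        durations.append(t_out - t_in)
    return np.asarray(durations), n_censored


# ---------------------------------------------------------------------------
# Biexponential MLE
# ---------------------------------------------------------------------------

def _biexp_nll(theta, t):
    """Negative log-likelihood; theta = (logit a2, log k1, logit r), k2=r*k1."""
    a2 = expit(theta[0])
    k1 = math.exp(theta[1])
    k2 = expit(theta[2]) * k1
    la = np.log([1.0 - a2, a2])
    lk = np.log([k1, k2])
    comp = la[None, :] + lk[None, :] - np.outer(t, [k1, k2])
    return -float(np.sum(logsumexp(comp, axis=1)))


def fit_biexponential(durations, n_starts: int = 8, seed: int | None = 0,
                      bootstrap: int = 0) -> BiexpFit:
    """Maximum-likelihood two-exponential mixture fit of dwell times.

    Maximises sum log[a1 k1 e^(-k1 t) + a2 k2 e^(-k2 t)] with a1+a2=1 and
    k1 > k2 > 0 (enforced by parametrising k2 as a fraction of k1), using
    multi-start BFGS from moment-based and randomised initial points.

    When the optimum sits on the mixture boundary (a2 -> 0 or 1, or
    k1 ~ k2) the fit degenerates to a single exponential and is flagged.
    Optional bootstrap resampling gives 95% CIs for E and tau.
    """
    t = np.asarray(durations, dtype=float)
    if t.size < 5:
        raise ValueError("too few durations for a mixture fit")
    if (t <= 0).any():
        raise ValueError("durations must be > 0")
    if t.size < 30:
        warnings.warn("fewer than 30 durations; mixture fit may be unstable")

    rng = np.random.default_rng(seed)
    mean = float(np.mean(t))
    slow = float(np.mean(t[t > np.quantile(t, 0.8)]))
    fast = float(np.mean(t[t < np.quantile(t, 0.5)]))
    fast = max(fast, 1e-9)
    starts = [
        np.array([logit(0.3), math.log(1.0 / fast),
                  logit(min(fast / slow, 0.5))]),
        np.array([logit(0.5), math.log(1.0 / mean), logit(0.2)]),
    ]
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(np.array([
            rng.normal(0, 1.5),
            math.log(1.0 / mean) + rng.normal(0, 1.0),
            rng.normal(-1.5, 1.0),
        ]))

    best = None
    for x0 in starts:
        res = optimize.minimize(_biexp_nll, x0, args=(t,), method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    a2 = float(expit(best.x[0]))
    k1 = float(math.exp(best.x[1]))
    k2 = float(expit(best.x[2]) * k1)
    # degenerate when AIC prefers a single exponential, or the optimum sits
    # on the mixture boundary
    ll_single = t.size * (math.log(1.0 / mean) - 1.0)
    aic_single = 2.0 * 1 - 2.0 * ll_single
    aic_mix = 2.0 * 3 + 2.0 * best.fun
    degenerate = (aic_single <= aic_mix or a2 < 0.01 or a2 > 0.99
                  or k1 / k2 < 1.05)
    fit = BiexpFit(a1=1.0 - a2, a2=a2, k1=k1, k2=k2,
                   loglik=-float(best.fun), degenerate=degenerate)

    if bootstrap > 0:
        es, taus = [], []
        for _ in range(bootstrap):
            tb = rng.choice(t, size=t.size, replace=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fb = fit_biexponential(tb, n_starts=4,
                                           seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            es.append(fb.efficiency)
            taus.append(fb.tau)
        if es:
            fit.ci = {
                "efficiency": (float(np.percentile(es, 2.5)),
                               float(np.percentile(es, 97.5))),
                "tau": (float(np.percentile(taus, 2.5)),
                        float(np.percentile(taus, 97.5))),
            }
    return fit
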