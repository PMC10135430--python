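"""Force dependence of transcription restart for a backtracked RNAP.

A polymerase carrying a terminal mismatch backtracks and must diffuse back
on pathway before it can resume elongation.  An assisting force F tilts
that landscape, so the restart time follows a Bell/Arrhenius law up to a
saturation force Fmax above which it is constant:

    t_restart(F) = t0 * exp(-F * dx / kBT)          for F <  Fmax
    t_restart(F) = t0 * exp(-Fmax * dx / kBT)       for F >= Fmax

t0 is the zero-force restart time (s), dx the distance to the transition
state (nm) — interpreted as the backtrack depth — and kBT the thermal
energy (4.11 pN nm at 25 C).  On a log scale the model is bilinear in F:
a line of slope -dx/kBT followed by a flat segment, which is how it is fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KBT_25C",
    "RISE_PER_BP_NM",
    "RestartModelParams",
    "RestartFit",
    "restart_time",
    "fit_restart",
    "backtrack_extent",
]

KBT_25C = 4.11       # pN nm, thermal energy at 25 C
RISE_PER_BP_NM = 0.34  # nm per bp, B-form DNA helical rise


@dataclass(frozen=True)
class RestartModelParams:
    """Parameters of the piecewise Arrhenius restart-time law."""

    t0: float            # zero-force restart time, s
    dx: float            # distance to transition state, nm
    f_max: float         # saturation force, pN
    kbt: float = KBT_25C

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.dx <= 0 or self.f_max <= 0 or self.kbt <= 0:
            raise ValueError("all restart-model parameters must be > 0")


@dataclass
class RestartFit:
    """Bilinear fit result with per-force medians and bootstrap CIs."""

    params: RestartModelParams
    sse: float
    medians: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)   # {param: {level: (lo, hi)}}


def restart_time(force, params: RestartModelParams):
    """Median restart time at force(s) in pN; vectorised over ``force``.

    Continuous at ``f_max``, strictly decreasing below it, constant above.
    """
    f = np.asarray(force, dtype=float)
    if (f < 0).any():
        raise ValueError("force must be >= 0")
    eff = np.minimum(f, params.f_max)
    out = params.t0 * np.exp(-eff * params.dx / params.kbt)
    return float(out) if np.isscalar(force) or out.ndim == 0 else out


def _bilinear_sse(f, logt, knot):
    """LSQ of log t on min(F, knot): slope -dx/kBT then flat; continuous."""
    g = np.minimum(f, knot)
    # guard: slope unidentifiable when all g equal
    if np.ptp(g) < 1e-12:
        return math.inf, (math.nan, math.nan)
    a = np.vstack([np.ones_like(g), g]).T
    coef, *_ = np.linalg.lstsq(a, logt, rcond=None)
    resid = logt - a @ coef
    return float(resid @ resid), (float(coef[0]), float(coef[1]))


def _fit_once(f, logt, knots, kbt):
    best = None
    for knot in knots:
        sse, (intercept, slope) = _bilinear_sse(f, logt, knot)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, knot, intercept, slope)
    sse, knot, intercept, slope = best
    if slope >= 0:
        raise ValueError("restart times do not decrease with force; "
                         "dx unidentifiable")
    return RestartModelParams(
        t0=math.exp(intercept), dx=-slope * kbt, f_max=float(knot), kbt=kbt), sse


def fit_restart(
    forces,
    times,
    kbt: float = KBT_25C,
    knot_resolution: float = 0.25,
    n_boot: int = 500,
    seed: int | None = None,
    levels: tuple = (0.90, 0.95),
) -> RestartFit:
    """Fit the piecewise Arrhenius law by a bilinear fit of ln(t) on F.

    The saturation force is found by grid search over candidate knots at
    ``knot_resolution`` (pN) across the observed force range; within each
    candidate the model is linear in (ln t0, -dx/kBT) via the regressor
    min(F, knot) and solved by least squares.  Bootstrap CIs resample
    observations (tethers) with replacement.

    Requires forces on both sides of at least one candidate knot; raises
    when the slope is unidentifiable.
    """
    f = np.asarray(forces, dtype=float)
    t = np.asarray(times, dtype=float)
    if f.shape != t.shape:
        raise ValueError("forces and times must have equal length")
    if (t <= 0).any():
        raise ValueError("restart times must be > 0")
    if np.unique(f).size < 3:
        raise ValueError("need >= 3 distinct forces")
    logt = np.log(t)

    lo, hi = float(f.min()), float(f.max())
    knots = np.arange(lo + knot_resolution, hi + knot_resolution / 2,
                      knot_resolution)
    if knots.size == 0:
        raise ValueError("force range too narrow for any candidate knot")
    params, sse = _fit_once(f, logt, knots, kbt)

    medians = {float(ff): float(np.median(t[f == ff])) for ff in np.unique(f)}

    ci: dict[str, dict] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws: dict[str, list] = {"t0": [], "dx": [], "f_max": []}
        for _ in range(n_boot):
            idx = rng.integers(0, f.size, size=f.size)
            try:
                p, _ = _fit_once(f[idx], logt[idx], knots, kbt)
            except ValueError:
                continue
            draws["t0"].append(p.t0)
            draws["dx"].append(p.dx)
            draws["f_max"].append(p.f_max)
        for key, vals in draws.items():
            arr = np.asarray(vals)
            ci[key] = {}
            for level in levels:
                alpha = 100.0 * (1.0 - level) / 2.0
                if arr.size:
                    ci[key][level] = (float(np.percentile(arr, alpha)),
                                      float(np.percentile(arr, 100 - alpha)))
                else:
                    ci[key][level] = (math.nan, math.nan)

    return RestartFit(params=params, sse=sse, medians=medians, ci=ci)


def backtrack_extent(dx: float, rise: float = RISE_PER_BP_NM) -> float:
    """Backtrack depth in nucleotides implied by dx: dx / rise."""
    if dx < 0:
        raise ValueError("dx must be >= 0")
    if rise <= 0:
        raise ValueError("rise must be > 0")
    return dx / rise
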