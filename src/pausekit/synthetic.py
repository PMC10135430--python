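"""Synthetic data with the statistical structure the analyses assume.

Every input the pipeline consumes can be generated here: Gillespie
trajectories of single polymerases over a template with site-specific
rates and off-pathway pause states; gel band-intensity time courses
(lane = timepoint) with multiplicative lognormal quantification noise;
optical-tweezers position signals built by pushing a trajectory through
the extensible WLC forward model and sampling at the instrument rate;
restart times scattered lognormally around the piecewise Arrhenius law;
and two-condition per-position base-count matrices with specified error
rates.

The generators are exact (event-driven exponential dwells, direct
multinomial draws) and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gel as gelmod
from .restart import RestartModelParams, restart_time
from .traces import DEFAULT_SAMPLE_RATE_HZ, TraceSignal, WLCParams, \
    extension_from_contour

__all__ = [
    "PauseSiteParams",
    "TemplateSpec",
    "TrajectoryPath",
    "simulate_trajectories",
    "trajectories_to_gel",
    "trajectory_to_signal",
    "simulate_restart_times",
    "simulate_base_counts",
    "simulate_renewal_pause",
]

ALPHABET = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PauseSiteParams:
    """Off-pathway rates at one pause-prone position (s^-1)."""

    kp: float
    k_escape: float
    k_slow_to_sluggish: float = 0.0
    k_sluggish_escape: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kp, self.k_escape, self.k_slow_to_sluggish,
               self.k_sluggish_escape) < 0:
            raise ValueError("rates must be >= 0")
        if self.kp > 0 and self.k_escape <= 0 and self.k_slow_to_sluggish <= 0:
            raise ValueError("a pause state must have an exit rate")
        if self.k_slow_to_sluggish > 0 and self.k_sluggish_escape <= 0:
            raise ValueError("k_sluggish_escape required when slow->sluggish")


@dataclass(frozen=True)
class TemplateSpec:
    """Abstract transcription template.

    ``kn`` is the default single-nucleotide addition rate; ``site_rates``
    overrides it at given positions (e.g. slow sites under limiting rNTP);
    ``pause_sites`` maps positions to off-pathway rates; a terminator at
    ``terminator_position`` releases the polymerase with probability
    ``p_terminate`` when reached.  Positions are 1-based template indices.
    """

    length: int
    kn: float
    site_rates: dict = field(default_factory=dict)
    pause_sites: dict = field(default_factory=dict)
    terminator_position: int | None = None
    p_terminate: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("template length must be >= 1")
        if self.kn <= 0:
            raise ValueError("kn must be > 0")
        for pos in list(self.site_rates) + list(self.pause_sites):
            if not 1 <= pos <= self.length:
                raise ValueError(f"position {pos} outside [1, {self.length}]")
        if not 0.0 <= self.p_terminate <= 1.0:
            raise ValueError("p_terminate must be in [0, 1]")


@dataclass
class TrajectoryPath:
    """Event path of a single polymerase.

    ``events`` is an ordered list of (position, entry_time, state) with
    state in {"elongating", "slow", "sluggish"}; positions advance by one
    between consecutive elongation events.  ``outcome`` is "runoff",
    "terminated" or "censored"; ``end_time`` the time of that outcome.
    """

    events: list
    outcome: str
    end_time: float

    def position_at(self, t: float):
        """(position, band) at time t; band is the gel row the molecule
        occupies ("terminated"/"runoff" once the outcome time has passed)."""
        if t >= self.end_time and self.outcome in ("terminated", "runoff"):
            band = (gelmod.TERMINATION if self.outcome == "terminated"
                    else gelmod.RUNOFF)
            return self.events[-1][0], band
        times = [e[1] for e in self.events]
        i = bisect.bisect_right(times, t) - 1
        i = max(i, 0)
        return self.events[i][0], "en_route"


def _simulate_one(template: TemplateSpec, t_max: float,
                  rng: np.random.Generator) -> TrajectoryPath:
    t = 0.0
    pos = 1
    events = [(pos, 0.0, "elongating")]
    while True:
        kn = template.site_rates.get(pos, template.kn)
        site = template.pause_sites.get(pos)
        kp = site.kp if site is not None else 0.0
        ktot = kn + kp
        t += rng.exponential(1.0 / ktot)
        if kp > 0 and rng.random() < kp / ktot:
            # off-pathway: slow pause, possibly deepening to sluggish
            events.append((pos, t, "slow"))
            k_out = site.k_escape + site.k_slow_to_sluggish
            t += rng.exponential(1.0 / k_out)
            if (site.k_slow_to_sluggish > 0
                    and rng.random() < site.k_slow_to_sluggish / k_out):
                events.append((pos, t, "sluggish"))
                t += rng.exponential(1.0 / site.k_sluggish_escape)
            events.append((pos, t, "elongating"))
            continue  # re-compete at the same position
        # on-pathway addition completes; maybe terminate, else advance
        if (template.terminator_position is not None
                and pos == template.terminator_position
                and rng.random() < template.p_terminate):
            return TrajectoryPath(events, "terminated", t)
        if pos >= template.length:
            return TrajectoryPath(events, "runoff", t)
        pos += 1
        events.append((pos, t, "elongating"))
        if t > t_max:
            return TrajectoryPath(events, "censored", t)


def simulate_trajectories(template: TemplateSpec, n: int, t_max: float,
                          seed=None) -> list[TrajectoryPath]:
    """Exact stochastic simulation of ``n`` polymerases over the template.

    Dwells are exponential; at pause sites entry competes with elongation
    as a Gillespie branching, and after each escape the polymerase
    re-competes at the same position (pause re-entry).  Trajectories not
    finished by ``t_max`` are marked censored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    rng = np.random.default_rng(seed)
    return [_simulate_one(template, t_max, rng) for _ in range(n)]


def trajectories_to_gel(paths, timepoints, noise_cv: float = 0.10,
                        seed=None, template: TemplateSpec | None = None,
                        time_unit: str = "s") -> gelmod.GelTimeCourse:
    """Bin trajectories into a band-intensity matrix, one lane per timepoint.

    Intensity at (position, t) is the number of molecules occupying that
    band at t; terminated molecules accumulate in a "termination" band,
    runoff molecules in a "runoff" band.  Multiplicative lognormal noise of
    coefficient of variation ``noise_cv`` emulates densitometry error.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be nonempty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    length = (template.length if template is not None
              else max(e[0] for p in paths for e in p.events))
    labels = [str(i) for i in range(1, length + 1)]
    labels += [gelmod.TERMINATION, gelmod.RUNOFF]
    counts = np.zeros((len(labels), len(timepoints)))
    row = {lab: i for i, lab in enumerate(labels)}
    for p in paths:
        for j, t in enumerate(timepoints):
            pos, band = p.position_at(t)
            key = band if band in (gelmod.TERMINATION, gelmod.RUNOFF) else str(pos)
            counts[row[key], j] += 1

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                              size=counts.shape)
        counts = counts * noise

    band_labels = {gelmod.TERMINATION: gelmod.TERMINATION,
                   gelmod.RUNOFF: gelmod.RUNOFF}
    intensities = pd.DataFrame(counts, index=labels,
                               columns=[float(t) for t in timepoints])
    return gelmod.GelTimeCourse(intensities=intensities,
                                band_labels=band_labels, time_unit=time_unit)


def trajectory_to_signal(
    path: TrajectoryPath,
    wlc: WLCParams = WLCParams(),
    force_pn: float = 10.0,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    noise_sd_nm: float = 1.0,
    seed=None,
    handle_bp: float = 3000.0,
    duration_s: float | None = None,
    assisting: bool = True,
) -> TraceSignal:
    """Forward-model an optical-tweezers record from one trajectory.

    The bp position series (sampled at ``sample_rate_hz``, default the
    1333 Hz acquisition rate) is offset by the DNA handle contour
    (``handle_bp``), converted to tether extension through the extensible
    WLC at the held force, and corrupted with Gaussian measurement noise.
    In the assisting geometry transcription lengthens the tether; in the
    opposing geometry it shortens it.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be > 0")
    if force_pn <= 0:
        raise ValueError("force must be > 0")
    t_end = duration_s if duration_s is not None else path.end_time
    time = np.arange(0.0, t_end, 1.0 / sample_rate_hz)
    ev_times = np.array([e[1] for e in path.events])
    ev_pos = np.array([e[0] for e in path.events], dtype=float)
    idx = np.clip(np.searchsorted(ev_times, time, side="right") - 1, 0, None)
    pos = ev_pos[idx]
    sign = 1.0 if assisting else -1.0
    contour_bp = handle_bp + sign * pos
    distance = extension_from_contour(contour_bp, force_pn, wlc)
    if noise_sd_nm > 0:
        rng = np.random.default_rng(seed)
        distance = distance + rng.normal(0.0, noise_sd_nm, size=distance.shape)
    return TraceSignal(time_s=time, distance_nm=np.asarray(distance),
                       force_pn=force_pn)


def simulate_restart_times(forces, params: RestartModelParams,
                           n_per_force: int = 10, sigma_log: float = 0.5,
                           seed=None) -> pd.DataFrame:
    """Restart times scattered lognormally around the Arrhenius median.

    At each force the model value is the median; times are that median
    multiplied by exp(sigma_log * Z).  Returns a tidy table
    (tether_id, force_pn, restart_time_s).
    """
    if n_per_force < 1:
        raise ValueError("n_per_force must be >= 1")
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    tether = 0
    for f in forces:
        median = restart_time(float(f), params)
        z = rng.normal(0.0, 1.0, size=n_per_force) if sigma_log > 0 \
            else np.zeros(n_per_force)
        for zi in z:
            rows.append((tether, float(f), median * np.exp(sigma_log * zi)))
            tether += 1
    return pd.DataFrame(rows, columns=["tether_id", "force_pn",
                                       "restart_time_s"])


def simulate_renewal_pause(k_escape: float, efficiency: float, n: int,
                           seed=None) -> np.ndarray:
    """Total paused time per pausing event in the re-entry renewal process.

    Starting paused, each episode lasts Exp(k_escape); after escaping, the
    polymerase re-enters the pause with probability ``efficiency``.  The
    mean of the returned totals is 1 / (k_escape * (1 - efficiency)) — the
    independent stochastic counterpart of the apparent-duration formula.
    """
    rng = np.random.default_rng(seed)
    # episodes per event ~ Geometric(1-E); total = Gamma(episodes, 1/k)
    n_episodes = rng.geometric(1.0 - efficiency, size=n)
    return rng.gamma(shape=n_episodes, scale=1.0 / k_escape)


def _validate_reference(reference: str) -> str:
    ref = reference.upper().replace("U", "T")
    bad = set(ref) - set(ALPHABET)
    if bad:
        raise ValueError(f"reference contains non-ACGT/U symbols: {sorted(bad)}")
    return ref


def _profile_at(profile, position: int, ref_base: str):
    """(error_rate, substitution distribution over non-reference bases)."""
    entry = profile.get(position, 0.0) if isinstance(profile, dict) else profile
    if isinstance(entry, tuple):
        rate, subs = entry
    else:
        rate, subs = float(entry), None
    alts = [b for b in ALPHABET if b != ref_base]
    if subs is None:
        probs = np.full(3, 1.0 / 3.0)
    else:
        probs = np.array([subs.get(b, 0.0) for b in alts], dtype=float)
        s = probs.sum()
        probs = probs / s if s > 0 else np.full(3, 1.0 / 3.0)
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"error rate at position {position} outside [0, 1]")
    return rate, alts, probs


def simulate_base_counts(reference: str, error_profile_minus,
                         error_profile_plus, depth: int, seed=None):
    """Two-condition per-position base counts plus per-read mismatch totals.

    ``error_profile_*`` is either a scalar rate or a map
    position -> rate | (rate, {base: prob}) giving the per-position
    misincorporation rate and substitution spectrum.  Each condition draws
    ``depth`` reads; errors are independent across positions, so the
    per-read mismatch totals follow the product (Poisson-binomial) model.

    Returns ``(counts_minus, counts_plus, mismatches_minus,
    mismatches_plus)`` where counts are :class:`pausekit.misinc.
    BaseCountMatrix` and mismatches are int arrays of per-read totals.
    """
    from .misinc import BaseCountMatrix

    if depth < 1:
        raise ValueError("depth must be >= 1")
    ref = _validate_reference(reference)
    rng = np.random.default_rng(seed)

    results = []
    for label, profile in (("minus", error_profile_minus),
                           ("plus", error_profile_plus)):
        counts = np.zeros((len(ref), 4), dtype=np.int64)
        mismatches = np.zeros(depth, dtype=np.int64)
        for i, base in enumerate(ref):
            rate, alts, probs = _profile_at(profile, i + 1, base)
            errs = rng.random(depth) < rate
            n_err = int(errs.sum())
            counts[i, ALPHABET.index(base)] += depth - n_err
            if n_err:
                alt_draws = rng.choice(3, size=n_err, p=probs)
                for j in range(3):
                    counts[i, ALPHABET.index(alts[j])] += int((alt_draws == j).sum())
                mismatches[errs] += 1
        matrix = BaseCountMatrix(
            counts=pd.DataFrame(counts, index=np.arange(1, len(ref) + 1),
                                columns=list(ALPHABET)),
            reference=ref, condition=label)
        results.append((matrix, mismatches))
    (m_minus, mm_minus), (m_plus, mm_plus) = results
    return m_minus, m_plus, mm_minus, mm_plus
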