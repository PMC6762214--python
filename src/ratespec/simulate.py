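"""Stochastic trajectory generators for non-Poisson reaction networks.

All simulators share the same conventions:

* ``SimRun`` fixes the master seed, trajectory count, total simulated
  time, recording step and burn-in.  Counts are recorded by *sampling the
  instantaneous molecule number at grid times* (not by binning events),
  matching the definition of the number spectrum as the transform of the
  instantaneous count autocovariance.
* Each trajectory draws from an independent random substream spawned from
  the master seed, so results for trajectory ``i`` do not change when
  ``n_traj`` changes.
* Products decay with first-order kinetics: each molecule receives an
  independent exponential lifetime at birth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.signal import lfilter

from .datatypes import TrajectoryEnsemble
from .reaction_times import (
    DichotomousRate,
    GammaDist,
    EnzymeTurnover,
    ModulatedRate,
    OnOffModel,
    ReactionTimeModel,
    SingleExponential,
)

__all__ = [
    "SimRun",
    "KtlDistribution",
    "GeneExpressionParams",
    "simulate_renewal_birth_death",
    "simulate_enzyme_network",
    "simulate_modulated_rate",
    "simulate_synchronized_counting",
    "simulate_gene_expression",
]


@dataclass(frozen=True)
class SimRun:
    """Run plumbing: seed, ensemble size, window, recording grid, burn-in."""

    seed: int
    n_traj: int
    t_total: float
    dt_record: float
    burn_in: float = 0.0

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if not self.dt_record > 0:
            raise ValueError("dt_record must be > 0")
        if not (self.t_total > self.burn_in >= 0):
            raise ValueError("need t_total > burn_in >= 0")

    @property
    def record_times(self) -> np.ndarray:
        n = int(np.floor((self.t_total - self.burn_in) / self.dt_record)) + 1
        return self.burn_in + self.dt_record * np.arange(n)

    def child_rngs(self) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.seed).spawn(self.n_traj)
        return [np.random.Generator(np.random.PCG64(s)) for s in seqs]


def _counts_on_grid(
    births: np.ndarray, deaths: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Molecule number at each grid time from sorted-free event times."""
    b = np.sort(births)
    d = np.sort(deaths)
    return (
        np.searchsorted(b, times, side="right")
        - np.searchsorted(d, times, side="right")
    ).astype(np.int64)


def _renewal_epochs(
    model: ReactionTimeModel, t_end: float, rng: np.random.Generator
) -> np.ndarray:
    """Event epochs of a renewal process on [0, t_end], first event at the
    first completed waiting time (synchronized start at t = 0)."""
    mean_t = model.mean_time
    epochs: list[np.ndarray] = []
    t = 0.0
    # draw in batches sized from the expected count
    while t < t_end:
        n = int((t_end - t) / mean_t * 1.25) + 64
        gaps = model.sample(n, rng)
        new = t + np.cumsum(gaps)
        epochs.append(new)
        t = new[-1]
    all_epochs = np.concatenate(epochs)
    return all_epochs[all_epochs <= t_end]


def _check_burn_in(run: SimRun, timescale: float, label: str) -> None:
    if run.burn_in < 5.0 * timescale:
        warnings.warn(
            f"burn_in = {run.burn_in:g} is below 5x the slowest {label} "
            f"timescale ({timescale:g}); stationarity is at risk",
            stacklevel=3,
        )


def simulate_renewal_birth_death(
    model: ReactionTimeModel, gamma: float, run: SimRun
) -> TrajectoryEnsemble:
    """Renewal creation + first-order decay.

    Creation epochs form a renewal sequence with inter-event times from
    the reaction-time distribution; every product lives an independent
    exponential(gamma) time.  Stationary mean count is ``<R>/gamma``.
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    _check_burn_in(run, max(model.mean_time, 1.0 / gamma), "creation/decay")
    times = run.record_times
    counts = np.empty((run.n_traj, times.size), dtype=np.int64)
    for i, rng in enumerate(run.child_rngs()):
        births = _renewal_epochs(model, run.t_total, rng)
        deaths = births + rng.exponential(1.0 / gamma, size=births.size)
        counts[i] = _counts_on_grid(births, deaths, times)
    return TrajectoryEnsemble(
        counts=counts, dt=run.dt_record, t0=times[0], species_label="product",
        provenance={"model": type(model).__name__, "gamma": gamma,
                    "seed": run.seed, "burn_in": run.burn_in,
                    "simulator": "renewal_birth_death"},
    )


def simulate_enzyme_network(
    k1S: float,
    es_lifetime: GammaDist,
    p2: float,
    n_enzymes: int,
    gamma_z: float,
    run: SimRun,
) -> TrajectoryEnsemble:
    """Products of ``n_enzymes`` independent single-enzyme turnover streams.

    Each enzyme cycles through association (exponential ``k1S``), a
    complex lifetime from ``es_lifetime`` and a catalysis/dissociation
    fate with probability ``p2``; the independent streams are superposed
    into one product pool with decay rate ``gamma_z``.
    """
    if n_enzymes < 1:
        raise ValueError("n_enzymes must be >= 1")
    single = EnzymeTurnover(k1S=k1S, es_lifetime=es_lifetime, p2=p2)
    _check_burn_in(run, max(single.mean_time, 1.0 / gamma_z), "turnover/decay")
    times = run.record_times
    counts = np.empty((run.n_traj, times.size), dtype=np.int64)
    for i, rng in enumerate(run.child_rngs()):
        births = np.concatenate(
            [_renewal_epochs(single, run.t_total, rng) for _ in range(n_enzymes)]
        )
        deaths = births + rng.exponential(1.0 / gamma_z, size=births.size)
        counts[i] = _counts_on_grid(births, deaths, times)
    return TrajectoryEnsemble(
        counts=counts, dt=run.dt_record, t0=times[0], species_label="product",
        provenance={"model": "enzyme_network", "n_enzymes": n_enzymes,
                    "k1S": k1S, "p2": p2, "a": es_lifetime.a,
                    "b": es_lifetime.b, "gamma": gamma_z, "seed": run.seed,
                    "burn_in": run.burn_in},
    )


def _ou_path(
    lam: float, var: float, n_steps: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact-update stationary OU path of length ``n_steps + 1``.

    ``G(t+dt) = G(t) e^{-lam dt} + sqrt(var (1 - e^{-2 lam dt})) N(0,1)``,
    started from the stationary marginal.
    """
    rho = np.exp(-lam * dt)
    g0 = rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
    if n_steps == 0:
        return np.array([g0])
    w = rng.normal(0.0, np.sqrt(var * (1.0 - rho**2)), size=n_steps)
    path, _ = lfilter([1.0], [1.0, -rho], w, zi=np.array([rho * g0]))
    return np.concatenate(([g0], path))


def simulate_modulated_rate(
    rate: ModulatedRate,
    gamma_z: float,
    thinning_dt: float,
    run: SimRun,
) -> TrajectoryEnsemble:
    """Thinning simulation of a state-dependent creation rate.

    The hidden coordinate Gamma follows the exact OU update on the
    thinning grid; at each step a creation event fires when an independent
    uniform draw falls below ``R(Gamma) * dt``.  Aborts if the acceptance
    probability ever exceeds 0.1 (thinning no longer accurate).
    """
    if not gamma_z > 0:
        raise ValueError("gamma_z must be > 0")
    if not thinning_dt > 0:
        raise ValueError("thinning_dt must be > 0")
    _check_burn_in(
        run, max(1.0 / rate.lam, 1.0 / rate.k0, 1.0 / gamma_z), "modulation/decay"
    )
    n_steps = int(np.ceil(run.t_total / thinning_dt))
    times = run.record_times
    counts = np.empty((run.n_traj, times.size), dtype=np.int64)
    for i, rng in enumerate(run.child_rngs()):
        g = _ou_path(rate.lam, rate.gamma_var, n_steps, thinning_dt, rng)
        p_accept = rate.rate(g) * thinning_dt
        if p_accept.max() > 0.1:
            raise ValueError(
                f"R * thinning_dt reached {p_accept.max():.3f} > 0.1; "
                "decrease thinning_dt"
            )
        fired = rng.random(g.size) < p_accept
        births = np.flatnonzero(fired) * thinning_dt
        deaths = births + rng.exponential(1.0 / gamma_z, size=births.size)
        counts[i] = _counts_on_grid(births, deaths, times)
    return TrajectoryEnsemble(
        counts=counts, dt=run.dt_record, t0=times[0], species_label="product",
        provenance={"model": "modulated_rate", "k0": rate.k0,
                    "alpha": rate.alpha, "lam": rate.lam, "gamma": gamma_z,
                    "thinning_dt": thinning_dt, "seed": run.seed,
                    "burn_in": run.burn_in},
    )


def simulate_synchronized_counting(
    model: ReactionTimeModel, run: SimRun
) -> tuple[np.ndarray, np.ndarray]:
    """Degradation-free mean cumulative event count ``<n(t)>*``.

    Counting starts at a completed event (t = 0), so the first completed
    waiting time is the first count.  Returns ``(times, n_star_mean)``;
    the long-time slope of the mean is ``<R> = 1/<t>``.
    """
    n_points = int(np.floor(run.t_total / run.dt_record)) + 1
    times = run.dt_record * np.arange(n_points)
    total = np.zeros(n_points)
    for rng in run.child_rngs():
        epochs = _renewal_epochs(model, run.t_total, rng)
        total += np.searchsorted(epochs, times, side="right")
    return times, total / run.n_traj


@dataclass(frozen=True)
class KtlDistribution:
    """Static cell-to-cell translation-coefficient distribution.

    ``kind="two_point"``: ``mean (1 +/- sqrt(eta2))`` with equal weight;
    ``kind="lognormal"``: lognormal with the given mean and relative
    variance.  ``eta2 = 0`` collapses to the constant ``mean``.
    """

    mean: float
    eta2: float = 0.0
    kind: str = "two_point"

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError("mean k_TL must be > 0")
        if self.eta2 < 0:
            raise ValueError("eta2 must be >= 0")
        if self.kind not in ("two_point", "lognormal"):
            raise ValueError("kind must be 'two_point' or 'lognormal'")
        if self.kind == "two_point" and self.eta2 > 1:
            raise ValueError("two-point distribution requires eta2 <= 1")

    def draw(self, rng: np.random.Generator) -> float:
        if self.eta2 == 0:
            return self.mean
        if self.kind == "two_point":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            return self.mean * (1.0 + sign * np.sqrt(self.eta2))
        s2 = np.log1p(self.eta2)
        return float(self.mean * np.exp(rng.normal(0.0, np.sqrt(s2)) - s2 / 2.0))


@dataclass(frozen=True)
class GeneExpressionParams:
    """Two-stage gene-expression cascade parameters.

    Promoter switches between on (transcribing) and off states; while on,
    transcription fires at ``k_TX`` (constant) or at an OU-modulated rate;
    mRNA decays at ``gamma_m``; translation fires at total rate
    ``k_TL * m(t)``; protein decays at ``gamma_p``.  Rates in 1/min by
    convention for gene models.
    """

    promoter: OnOffModel
    transcription: Union[float, ModulatedRate, DichotomousRate]
    gamma_m: float
    k_TL: Union[float, KtlDistribution]
    gamma_p: float
    thinning_dt: float | None = None

    def __post_init__(self) -> None:
        if not (self.gamma_m > 0 and self.gamma_p > 0):
            raise ValueError("gamma_m and gamma_p must be > 0")
        if isinstance(self.transcription, (int, float)):
            if not self.transcription > 0:
                raise ValueError("k_TX must be > 0")
        elif not isinstance(self.transcription, (ModulatedRate, DichotomousRate)):
            raise TypeError(
                "transcription must be a rate, a ModulatedRate, or a DichotomousRate"
            )
        if isinstance(self.k_TL, (int, float)) and not self.k_TL > 0:
            raise ValueError("k_TL must be > 0")

    @property
    def mean_k_TX(self) -> float:
        if isinstance(self.transcription, (ModulatedRate, DichotomousRate)):
            return self.transcription.mean_rate
        return float(self.transcription)

    @property
    def mean_k_TL(self) -> float:
        return self.k_TL.mean if isinstance(self.k_TL, KtlDistribution) else float(self.k_TL)

    @property
    def mean_mrna(self) -> float:
        return self.mean_k_TX * self.promoter.duty_fraction / self.gamma_m

    @property
    def mean_protein(self) -> float:
        return self.mean_k_TL * self.mean_mrna / self.gamma_p


def _promoter_on_intervals(
    promoter: OnOffModel, t_end: float, rng: np.random.Generator
) -> np.ndarray:
    """On-intervals [(start, stop), ...] covering [0, t_end].

    The trajectory starts in the on state with probability equal to the
    duty fraction (burn-in removes the residual dwell-time bias).
    """
    intervals = []
    t = 0.0
    state_on = rng.random() < promoter.duty_fraction
    # batch dwell draws for speed
    n_cycles = int(t_end / (promoter.tau_on + promoter.tau_off) * 1.5) + 16
    on_d = promoter.on_lifetime.sample(n_cycles, rng)
    off_d = promoter.off_lifetime.sample(n_cycles, rng)
    i_on = i_off = 0
    while t < t_end:
        if state_on:
            if i_on >= on_d.size:
                on_d = promoter.on_lifetime.sample(n_cycles, rng)
                i_on = 0
            d = on_d[i_on]
            i_on += 1
            intervals.append((t, min(t + d, t_end)))
        else:
            if i_off >= off_d.size:
                off_d = promoter.off_lifetime.sample(n_cycles, rng)
                i_off = 0
            d = off_d[i_off]
            i_off += 1
        t += d
        state_on = not state_on
    return np.array(intervals) if intervals else np.empty((0, 2))


def _poisson_times_in_intervals(
    intervals: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if intervals.size == 0:
        return np.empty(0)
    durations = intervals[:, 1] - intervals[:, 0]
    n_per = rng.poisson(rate * durations)
    starts = np.repeat(intervals[:, 0], n_per)
    durs = np.repeat(durations, n_per)
    return np.sort(starts + durs * rng.random(starts.size))


def _events_in_on_state(
    times: np.ndarray, intervals: np.ndarray
) -> np.ndarray:
    """Keep event times that fall inside any on-interval."""
    if intervals.size == 0 or times.size == 0:
        return np.empty(0)
    starts = intervals[:, 0]
    stops = intervals[:, 1]
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = (idx >= 0) & (times < stops[np.clip(idx, 0, stops.size - 1)])
    return times[ok]


def _intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersections of two sorted, disjoint interval sets (n x 2 arrays)."""
    if a.size == 0 or b.size == 0:
        return np.empty((0, 2))
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out) if out else np.empty((0, 2))


def _piecewise_poisson_times(
    event_times: np.ndarray,
    deltas: np.ndarray,
    rate_per_unit: float,
    t_end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Arrival times of a Poisson process whose rate is ``rate_per_unit *
    level(t)`` with ``level`` piecewise constant (cumsum of ``deltas`` at
    ``event_times``)."""
    knots = np.concatenate(([0.0], event_times, [t_end]))
    levels = np.concatenate(([0.0], np.cumsum(deltas)))
    durations = np.diff(knots)
    lam = rate_per_unit * levels * durations
    n_per = rng.poisson(np.maximum(lam, 0.0))
    starts = np.repeat(knots[:-1], n_per)
    durs = np.repeat(durations, n_per)
    return np.sort(starts + durs * rng.random(starts.size))


def simulate_gene_expression(
    params: GeneExpressionParams,
    run: SimRun,
    record: str = "both",
):
    """Simulate the two-stage promoter -> mRNA -> protein cascade.

    Gene state alternates between on and off dwell times; while on,
    transcription is Poisson at ``k_TX`` (constant case, exact) or an
    OU-modulated thinned process (vibrant case, Gamma keeps relaxing
    through off periods).  mRNA decays at ``gamma_m``; translation is an
    inhomogeneous Poisson process at rate ``k_TL * m(t)`` (exact between
    mRNA events); protein decays at ``gamma_p``.  ``record`` is one of
    ``"mRNA"``, ``"protein"``, ``"both"``.
    """
    if record not in ("mRNA", "protein", "both"):
        raise ValueError("record must be 'mRNA', 'protein', or 'both'")
    vibrant = isinstance(params.transcription, ModulatedRate)
    dichotomous = isinstance(params.transcription, DichotomousRate)
    if vibrant and params.thinning_dt is None:
        raise ValueError("OU-modulated transcription requires thinning_dt")
    slow = max(
        1.0 / params.gamma_m, 1.0 / params.gamma_p,
        params.promoter.tau_on + params.promoter.tau_off,
        1.0 / params.transcription.lam if (vibrant or dichotomous) else 0.0,
    )
    _check_burn_in(run, slow, "cascade")
    times = run.record_times
    m_counts = np.empty((run.n_traj, times.size), dtype=np.int64)
    p_counts = np.empty((run.n_traj, times.size), dtype=np.int64)
    for i, rng in enumerate(run.child_rngs()):
        intervals = _promoter_on_intervals(params.promoter, run.t_total, rng)
        if vibrant:
            mod: ModulatedRate = params.transcription
            dt_thin = params.thinning_dt
            n_steps = int(np.ceil(run.t_total / dt_thin))
            g = _ou_path(mod.lam, mod.gamma_var, n_steps, dt_thin, rng)
            p_accept = mod.rate(g) * dt_thin
            if p_accept.max() > 0.1:
                raise ValueError(
                    f"k_TX * thinning_dt reached {p_accept.max():.3f} > 0.1; "
                    "decrease thinning_dt"
                )
            fired = rng.random(g.size) < p_accept
            candidates = np.flatnonzero(fired) * dt_thin
            m_births = _events_in_on_state(candidates, intervals)
        elif dichotomous:
            di: DichotomousRate = params.transcription
            high_state = OnOffModel(
                on_lifetime=SingleExponential(di.nu_high),
                off_lifetime=SingleExponential(di.nu_low),
            )
            high_intervals = _promoter_on_intervals(high_state, run.t_total, rng)
            base = (
                _poisson_times_in_intervals(intervals, di.r_low, rng)
                if di.r_low > 0 else np.empty(0)
            )
            extra = _poisson_times_in_intervals(
                _intersect_intervals(intervals, high_intervals),
                di.r_high - di.r_low, rng,
            )
            m_births = np.sort(np.concatenate((base, extra)))
        else:
            m_births = _poisson_times_in_intervals(
                intervals, float(params.transcription), rng
            )
        m_deaths = m_births + rng.exponential(1.0 / params.gamma_m, m_births.size)
        m_counts[i] = _counts_on_grid(m_births, m_deaths, times)

        if record != "mRNA":
            k_tl = (
                params.k_TL.draw(rng)
                if isinstance(params.k_TL, KtlDistribution)
                else float(params.k_TL)
            )
            ev = np.concatenate((m_births, np.sort(m_deaths)))
            deltas = np.concatenate((np.ones(m_births.size), -np.ones(m_deaths.size)))
            order = np.argsort(ev, kind="stable")
            p_births = _piecewise_poisson_times(
                ev[order], deltas[order], k_tl, run.t_total, rng
            )
            p_deaths = p_births + rng.exponential(1.0 / params.gamma_p, p_births.size)
            p_counts[i] = _counts_on_grid(p_births, p_deaths, times)

    prov = {"model": "gene_expression", "seed": run.seed,
            "burn_in": run.burn_in, "gamma_m": params.gamma_m,
            "gamma_p": params.gamma_p, "mean_k_TX": params.mean_k_TX,
            "mean_k_TL": params.mean_k_TL,
            "tau_on": params.promoter.tau_on,
            "tau_off": params.promoter.tau_off}
    mrna = TrajectoryEnsemble(
        counts=m_counts, dt=run.dt_record, t0=times[0],
        species_label="mRNA", provenance=dict(prov, gamma=params.gamma_m),
    )
    if record == "mRNA":
        return mrna
    protein = TrajectoryEnsemble(
        counts=p_counts, dt=run.dt_record, t0=times[0],
        species_label="protein", provenance=dict(prov, gamma=params.gamma_p),
    )
    if record == "protein":
        return protein
    return mrna, protein
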