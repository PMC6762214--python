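"""Reaction-time distributions and fluctuating-rate models.

A renewal reaction process is fully characterised by its reaction-time
distribution ``psi(t)`` — the law of the i.i.d. waiting times between
consecutive product-creation events.  Each model here exposes

* ``transform(omegas)``: the one-sided Fourier transform
  ``psi~(omega) = int_0^inf dt e^{-i omega t} psi(t)`` (so ``psi~(0) = 1``
  and ``|psi~| <= 1``),
* ``mean_time``: the mean reaction time ``<t> = 1/<R>``,
* ``sample(n, rng)``: i.i.d. draws of reaction times.

The concrete variants cover single-exponential, sequential multi-step
(hypoexponential / Erlang), parallel multi-channel (hyperexponential),
gamma-distributed, and generalized enzyme-turnover processes, plus the
on/off promoter model and the conformation-modulated (lognormal-rate,
Ornstein-Uhlenbeck driven) rate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReactionTimeModel",
    "SingleExponential",
    "MultiStep",
    "MultiChannel",
    "GammaDist",
    "EnzymeTurnover",
    "OnOffModel",
    "ModulatedRate",
    "DichotomousRate",
]


class ReactionTimeModel:
    """Abstract reaction-time distribution interface."""

    @property
    def mean_time(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def mean_rate(self) -> float:
        """Mean event rate ``<R> = 1/<t>`` of the renewal process."""
        return 1.0 / self.mean_time

    def transform(self, omegas: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def laplace(self, s: np.ndarray) -> np.ndarray:
        """Laplace transform ``psi^(s)``; ``psi^(i omega) == psi~(omega)``."""
        return self.transform(np.asarray(s) / 1j)


@dataclass(frozen=True)
class SingleExponential(ReactionTimeModel):
    """Poisson (single-step) reaction: ``psi(t) = k e^{-kt}``."""

    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("rate k must be > 0")

    @property
    def mean_time(self) -> float:
        return 1.0 / self.k

    def transform(self, omegas):
        w = np.asarray(omegas, dtype=complex)
        return self.k / (self.k + 1j * w)

    def sample(self, n, rng):
        return rng.exponential(1.0 / self.k, size=n)


@dataclass(frozen=True)
class MultiStep(ReactionTimeModel):
    """Sequential l-step process: sum of independent exponentials.

    Equal rates give the Erlang distribution; timing is sub-Poisson
    (more regular than exponential), so the renewal-rate spectrum is
    negative at low frequency and non-monotonic.
    """

    rates: tuple[float, ...]

    def __init__(self, rates) -> None:
        rates = tuple(float(k) for k in np.atleast_1d(rates))
        if len(rates) == 0 or any(k <= 0 for k in rates):
            raise ValueError("need at least one positive rate")
        object.__setattr__(self, "rates", rates)

    @property
    def mean_time(self) -> float:
        return float(sum(1.0 / k for k in self.rates))

    def transform(self, omegas):
        w = np.asarray(omegas, dtype=complex)
        out = np.ones_like(w)
        for k in self.rates:
            out = out * (k / (k + 1j * w))
        return out

    def sample(self, n, rng):
        t = np.zeros(n)
        for k in self.rates:
            t += rng.exponential(1.0 / k, size=n)
        return t


@dataclass(frozen=True)
class MultiChannel(ReactionTimeModel):
    """Parallel channels: exponential(k_i) chosen with probability p_i.

    The hyperexponential mixture is super-Poisson (bursty); its
    renewal-rate spectrum is positive and monotone decreasing.
    """

    probs: tuple[float, ...]
    rates: tuple[float, ...]

    def __init__(self, probs, rates) -> None:
        probs = tuple(float(p) for p in np.atleast_1d(probs))
        rates = tuple(float(k) for k in np.atleast_1d(rates))
        if len(probs) != len(rates) or len(probs) == 0:
            raise ValueError("probs and rates must have equal nonzero length")
        if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
            raise ValueError("probs must be nonnegative and sum to 1")
        if any(k <= 0 for k in rates):
            raise ValueError("rates must be > 0")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "rates", rates)

    @property
    def mean_time(self) -> float:
        return float(sum(p / k for p, k in zip(self.probs, self.rates)))

    def transform(self, omegas):
        w = np.asarray(omegas, dtype=complex)
        out = np.zeros_like(w)
        for p, k in zip(self.probs, self.rates):
            out = out + p * k / (k + 1j * w)
        return out

    def sample(self, n, rng):
        idx = rng.choice(len(self.rates), size=n, p=self.probs)
        scales = 1.0 / np.asarray(self.rates)
        return rng.exponential(scales[idx])


@dataclass(frozen=True)
class GammaDist(ReactionTimeModel):
    """Gamma-distributed reaction time: ``t^{a-1} e^{-t/b} / Gamma(a) b^a``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("shape a and scale b must be > 0")

    @property
    def mean_time(self) -> float:
        return self.a * self.b

    def transform(self, omegas):
        w = np.asarray(omegas, dtype=complex)
        return (1.0 + 1j * w * self.b) ** (-self.a)

    def sample(self, n, rng):
        return rng.gamma(self.a, self.b, size=n)


@dataclass(frozen=True)
class EnzymeTurnover(ReactionTimeModel):
    """Generalized single-enzyme turnover time.

    One turnover = repeated rounds of substrate association
    (exponential with pseudo-first-order rate ``k1S = k_1 [S]``) followed by
    an enzyme-substrate complex lifetime drawn from ``es_lifetime``; each
    round ends in catalysis with probability ``p2`` (else dissociation and
    another round).  The turnover-time transform is the geometric
    resummation

        ``psi~ = p2 phi1~ phiES~ / (1 - (1 - p2) phi1~ phiES~)``.
    """

    k1S: float
    es_lifetime: ReactionTimeModel
    p2: float

    def __post_init__(self) -> None:
        if not self.k1S > 0:
            raise ValueError("association rate k1S must be > 0")
        if not (0 < self.p2 <= 1):
            raise ValueError("catalysis probability p2 must be in (0, 1]")

    @property
    def mean_time(self) -> float:
        return (1.0 / self.k1S + self.es_lifetime.mean_time) / self.p2

    def transform(self, omegas):
        w = np.asarray(omegas, dtype=complex)
        phi1 = self.k1S / (self.k1S + 1j * w)
        phi_es = self.es_lifetime.transform(omegas)
        cycle = phi1 * phi_es
        return self.p2 * cycle / (1.0 - (1.0 - self.p2) * cycle)

    def sample(self, n, rng):
        # number of association/complex rounds per turnover is geometric(p2);
        # the sum of n_r exponential(k1S) times is Gamma(n_r, 1/k1S).
        n_rounds = rng.geometric(self.p2, size=n)
        t_assoc = rng.gamma(n_rounds.astype(float), 1.0 / self.k1S)
        if isinstance(self.es_lifetime, GammaDist):
            a, b = self.es_lifetime.a, self.es_lifetime.b
            t_es = rng.gamma(n_rounds * a, b)
        else:
            total = int(n_rounds.sum())
            draws = self.es_lifetime.sample(total, rng)
            edges = np.concatenate(([0], np.cumsum(n_rounds)))
            t_es = np.add.reduceat(draws, edges[:-1])
        return t_assoc + t_es


@dataclass(frozen=True)
class OnOffModel:
    """Two-state promoter: alternating active/inactive periods.

    ``on_lifetime`` and ``off_lifetime`` are the dwell-time laws of the
    active and inactive gene states; their means give the duty fraction
    ``tau_on / (tau_on + tau_off)`` = mean of the 0/1 state variable.
    """

    on_lifetime: ReactionTimeModel
    off_lifetime: ReactionTimeModel

    @property
    def tau_on(self) -> float:
        return self.on_lifetime.mean_time

    @property
    def tau_off(self) -> float:
        return self.off_lifetime.mean_time

    @property
    def duty_fraction(self) -> float:
        return self.tau_on / (self.tau_on + self.tau_off)


@dataclass(frozen=True)
class ModulatedRate:
    """Rate coefficient modulated by a hidden Ornstein-Uhlenbeck coordinate.

    ``R(Gamma) = k0 exp(-alpha Gamma)`` with Gamma a stationary Gaussian
    process of variance ``gamma_var`` and exponential autocorrelation
    ``<Gamma(t)Gamma(0)> = gamma_var * exp(-lam t)``.  The stationary rate
    is lognormal:

        ``<R>   = k0 exp(alpha^2 gamma_var / 2)``
        ``eta2  = <dR^2>/<R>^2 = exp(alpha^2 gamma_var) - 1``.
    """

    k0: float
    alpha: float
    lam: float
    gamma_var: float = 1.0

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError("base rate k0 must be > 0")
        if not self.lam > 0:
            raise ValueError("relaxation rate lam must be > 0")
        if not self.gamma_var >= 0:
            raise ValueError("gamma_var must be >= 0")

    @classmethod
    def from_moments(cls, mean_rate: float, eta2: float, lam: float) -> "ModulatedRate":
        """Construct the lognormal model with given mean rate and relative variance."""
        if not mean_rate > 0:
            raise ValueError("mean_rate must be > 0")
        if not eta2 >= 0:
            raise ValueError("eta2 must be >= 0")
        a2 = np.log1p(eta2)  # alpha^2 gamma_var with gamma_var = 1
        k0 = mean_rate * np.exp(-a2 / 2.0)
        return cls(k0=k0, alpha=float(np.sqrt(a2)), lam=lam, gamma_var=1.0)

    @property
    def coupling2(self) -> float:
        """``alpha^2 <Gamma^2>``, the log-rate variance."""
        return self.alpha**2 * self.gamma_var

    @property
    def mean_rate(self) -> float:
        return self.k0 * np.exp(self.coupling2 / 2.0)

    @property
    def eta2(self) -> float:
        """Relative variance of the rate, ``exp(alpha^2 <Gamma^2>) - 1``."""
        return float(np.expm1(self.coupling2))

    def rate(self, gamma_values: np.ndarray) -> np.ndarray:
        return self.k0 * np.exp(-self.alpha * np.asarray(gamma_values))


@dataclass(frozen=True)
class DichotomousRate:
    """Two-state Markov rate: exactly exponential rate TCF, bounded values.

    The rate jumps between ``r_low`` and ``r_high``; the dwell time in each
    state is exponential (``nu_low``, ``nu_high`` are the leaving rates).
    Stationary occupancies are ``p_high = nu_low/(nu_low + nu_high)`` and
    the fluctuation TCF is ``<dR(t)dR(0)> = var * exp(-lam t)`` with
    ``lam = nu_low + nu_high`` — the same exponential-TCF abstraction as a
    weakly coupled Ornstein-Uhlenbeck modulation, but exactly and with a
    bounded rate, so it can be simulated without thinning error.
    """

    r_low: float
    r_high: float
    nu_low: float
    nu_high: float

    def __post_init__(self) -> None:
        if not (self.r_low >= 0 and self.r_high > self.r_low):
            raise ValueError("need 0 <= r_low < r_high")
        if not (self.nu_low > 0 and self.nu_high > 0):
            raise ValueError("switching rates must be > 0")

    @classmethod
    def from_moments(
        cls, mean_rate: float, eta2: float, lam: float
    ) -> "DichotomousRate":
        """Zero-low-state construction with given mean, relative variance
        and relaxation rate: ``p_high = 1/(1 + eta2)``."""
        if not (mean_rate > 0 and eta2 > 0 and lam > 0):
            raise ValueError("mean_rate, eta2, lam must be > 0")
        p_high = 1.0 / (1.0 + eta2)
        return cls(
            r_low=0.0,
            r_high=mean_rate / p_high,
            nu_low=lam * p_high,
            nu_high=lam * (1.0 - p_high),
        )

    @property
    def lam(self) -> float:
        return self.nu_low + self.nu_high

    @property
    def p_high(self) -> float:
        return self.nu_low / self.lam

    @property
    def mean_rate(self) -> float:
        return self.p_high * self.r_high + (1.0 - self.p_high) * self.r_low

    @property
    def eta2(self) -> float:
        p = self.p_high
        var = p * (1.0 - p) * (self.r_high - self.r_low) ** 2
        return var / self.mean_rate**2
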