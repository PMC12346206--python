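"""Stochastic input distributions for cohort generation and cost simulation.

Each uncertain quantity — a unit cost, a therapy duration, a recurrence
probability — is declared as a :class:`DistributionSpec` naming a parametric
family and its parameters.  The same spec type drives both the synthetic
cohort generator (which additionally uses right-skewed log-normal and
over-dispersed negative-binomial families) and the Monte Carlo cost engine
(restricted to the five families conventional in probabilistic sensitivity
analysis: triangular, normal, uniform, beta, bernoulli).

Two truncation mechanisms exist and are deliberately distinct:

* ``truncate_at_zero`` — resample until nonnegative.  Used for physically
  nonnegative quantities modelled with a normal (e.g. a surgical cost).
* ``bounds=(lo, hi)`` — clip to a closed interval.  Used by the cohort
  generator to respect the observed min–max range of a summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

FAMILIES = (
    "triangular",
    "normal",
    "uniform",
    "beta",
    "bernoulli",
    "lognormal",
    "negbinom",
)

#: Families allowed as Monte Carlo engine inputs.
MC_FAMILIES = ("triangular", "normal", "uniform", "beta", "bernoulli")

_REQUIRED_PARAMS = {
    "triangular": ("min", "mode", "max"),
    "normal": ("mean", "sd"),
    "uniform": ("low", "high"),
    "beta": ("alpha", "beta"),
    "bernoulli": ("p",),
    "lognormal": ("mean", "sd"),
    "negbinom": ("mean", "sd", "shift"),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A named stochastic input: family, parameters, units, truncation."""

    name: str
    family: str
    params: dict = field(default_factory=dict)
    units: str = ""
    truncate_at_zero: bool = False
    bounds: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        missing = [k for k in _REQUIRED_PARAMS[self.family] if k not in self.params]
        if missing:
            raise ConfigurationError(
                f"{self.name}: {self.family} needs parameters {missing}"
            )
        p = self.params
        fam = self.family
        if fam == "triangular":
            if not p["min"] <= p["mode"] <= p["max"]:
                raise ConfigurationError(
                    f"{self.name}: triangular requires min <= mode <= max"
                )
        elif fam == "normal":
            if p["sd"] <= 0:
                raise ConfigurationError(f"{self.name}: normal requires sd > 0")
        elif fam == "uniform":
            if not p["low"] < p["high"]:
                raise ConfigurationError(f"{self.name}: uniform requires low < high")
        elif fam == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ConfigurationError(
                    f"{self.name}: beta requires alpha > 0 and beta > 0"
                )
        elif fam == "bernoulli":
            if not 0.0 <= p["p"] <= 1.0:
                raise ConfigurationError(f"{self.name}: bernoulli requires p in [0,1]")
        elif fam == "lognormal":
            if p["mean"] <= 0 or p["sd"] <= 0:
                raise ConfigurationError(
                    f"{self.name}: lognormal requires mean > 0 and sd > 0"
                )
        elif fam == "negbinom":
            mu = p["mean"] - p["shift"]
            if mu <= 0:
                raise ConfigurationError(
                    f"{self.name}: negbinom requires mean > shift"
                )
            if p["sd"] ** 2 <= mu:
                raise ConfigurationError(
                    f"{self.name}: negbinom requires variance > mean - shift "
                    "(over-dispersion)"
                )
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo <= hi:
                raise ConfigurationError(f"{self.name}: bounds must satisfy lo <= hi")

    # Closed-form moments of the untruncated family; used by tests and
    # convergence diagnostics.
    def mean(self) -> float:
        p = self.params
        fam = self.family
        if fam == "triangular":
            return (p["min"] + p["mode"] + p["max"]) / 3.0
        if fam == "normal" or fam == "lognormal" or fam == "negbinom":
            return float(p["mean"])
        if fam == "uniform":
            return (p["low"] + p["high"]) / 2.0
        if fam == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        return float(p["p"])  # bernoulli

    def var(self) -> float:
        p = self.params
        fam = self.family
        if fam == "triangular":
            a, m, b = p["min"], p["mode"], p["max"]
            return (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0
        if fam == "normal" or fam == "lognormal" or fam == "negbinom":
            return float(p["sd"]) ** 2
        if fam == "uniform":
            return (p["high"] - p["low"]) ** 2 / 12.0
        if fam == "beta":
            a, b = p["alpha"], p["beta"]
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        return p["p"] * (1.0 - p["p"])  # bernoulli


def _raw(spec: DistributionSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    p = spec.params
    fam = spec.family
    if fam == "triangular":
        a, m, b = float(p["min"]), float(p["mode"]), float(p["max"])
        if a == b:
            return np.full(n, a)
        # inverse-CDF transform of a uniform draw
        u = rng.random(n)
        c = (m - a) / (b - a)
        left = a + np.sqrt(u * (b - a) * (m - a))
        right = b - np.sqrt((1.0 - u) * (b - a) * (b - m))
        return np.where(u < c, left, right)
    if fam == "normal":
        return rng.normal(p["mean"], p["sd"], n)
    if fam == "uniform":
        return rng.uniform(p["low"], p["high"], n)
    if fam == "beta":
        return rng.beta(p["alpha"], p["beta"], n)
    if fam == "bernoulli":
        return (rng.random(n) < p["p"]).astype(float)
    if fam == "lognormal":
        # parameters are the arithmetic mean/sd of the target variable
        mean, sd = float(p["mean"]), float(p["sd"])
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), n)
    # negbinom: shifted count with target arithmetic mean/sd
    mean, sd, shift = float(p["mean"]), float(p["sd"]), float(p["shift"])
    mu = mean - shift
    var = sd * sd
    r = mu * mu / (var - mu)
    prob = r / (r + mu)
    return shift + rng.negative_binomial(r, prob, n).astype(float)


def draw(
    spec: DistributionSpec, rng: np.random.Generator, size: int | None = None
) -> float | np.ndarray:
    """Draw from ``spec``; vectorised when ``size`` is given.

    Deterministic for a fixed generator state.  ``truncate_at_zero``
    resamples negatives; ``bounds`` clips.
    """
    n = 1 if size is None else int(size)
    x = _raw(spec, rng, n)
    if spec.truncate_at_zero:
        bad = x < 0.0
        rounds = 0
        while bad.any():
            x[bad] = _raw(spec, rng, int(bad.sum()))
            bad = x < 0.0
            rounds += 1
            if rounds > 1000:
                raise ConfigurationError(
                    f"{spec.name}: truncation at zero rejects essentially all mass"
                )
    if spec.bounds is not None:
        x = np.clip(x, spec.bounds[0], spec.bounds[1])
    return float(x[0]) if size is None else x


def sample(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from ``spec`` (scalar convenience wrapper over :func:`draw`)."""
    return float(draw(spec, rng))


def _integer_event(r: int, p: float) -> bool:
    """Two-digit random-number event rule: event iff r falls in 00..round(100p).

    Retained as a documented compatibility mode only: at p = 0.66 the rule
    fires on 67 of the 100 equally likely integers (00–66 inclusive), a
    1-percentage-point bias relative to p.
    """
    return r <= int(round(100.0 * p))


def sample_event(
    p: float, rng: np.random.Generator, scheme: str = "uniform"
) -> bool:
    """Bernoulli event draw with probability ``p``.

    The default ``uniform`` scheme is exact: event iff a uniform(0,1) draw
    is below ``p``.  The ``integer`` scheme reproduces the classical
    two-digit random-number table rule (see :func:`_integer_event`) and is
    biased by up to 1/100.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"event probability {p} outside [0, 1]")
    if scheme == "uniform":
        return bool(rng.random() < p)
    if scheme == "integer":
        if p == 0.0:
            return False
        if p == 1.0:
            return True
        return _integer_event(int(rng.integers(0, 100)), p)
    raise ConfigurationError(f"unknown event scheme {scheme!r}")
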