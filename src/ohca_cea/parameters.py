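"""Model parameters: distribution fitting and probabilistic draws.

Every substantive input to the care-pathway model is a named parameter with a
point estimate (its mean), an optional 95% confidence interval, and a sampling
distribution family.  Probabilities and utility weights are modelled with beta
distributions, costs and durations with gamma distributions; parameters printed
without an interval are held fixed during probabilistic sensitivity analysis.

Distributions are fitted by the method of moments: the 95% CI is converted to a
standard deviation under a symmetric normal approximation, ``sd = (hi - lo) /
3.92``, and the (mean, sd) pair is matched exactly by the fitted gamma or beta
moments.  The default registry ships with the package as a YAML file
(``data/parameters.yaml``) and can be replaced or overridden by the user.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CI_WIDTH_SD",
    "ParameterError",
    "ParameterSpec",
    "ParameterSet",
    "ci_sd",
    "fit_gamma",
    "fit_beta",
    "load_specs",
    "default_specs",
    "point_estimates",
    "sample_parameters",
]

#: Width of a symmetric 95% normal interval in standard deviations (2 x 1.96).
CI_WIDTH_SD = 3.92

_FAMILIES = ("gamma", "beta", "fixed")


class ParameterError(ValueError):
    """Invalid parameter specification or infeasible distribution moments."""


def ci_sd(ci_low: float, ci_high: float) -> float:
    """Standard deviation implied by a symmetric 95% CI: ``(hi - lo) / 3.92``."""
    if ci_high <= ci_low:
        raise ParameterError(f"inverted or degenerate CI ({ci_low}, {ci_high})")
    return (ci_high - ci_low) / CI_WIDTH_SD


def fit_gamma(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Fit a gamma distribution to a mean and 95% CI by moment matching.

    Returns ``(shape, scale)`` with ``shape * scale == mean`` and
    ``sqrt(shape) * scale == (ci_high - ci_low) / 3.92``.
    """
    if mean <= 0:
        raise ParameterError(f"gamma mean must be positive, got {mean}")
    if not (ci_low <= mean <= ci_high):
        raise ParameterError(f"mean {mean} outside CI ({ci_low}, {ci_high})")
    sd = ci_sd(ci_low, ci_high)
    var = sd * sd
    return mean * mean / var, var / mean


def fit_beta(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Fit a beta distribution to a mean and 95% CI by moment matching.

    Returns ``(alpha, beta)`` with mean ``alpha / (alpha + beta)`` equal to the
    input mean and variance ``((ci_high - ci_low) / 3.92)**2``.  Raises
    :class:`ParameterError` if the implied variance is infeasible, i.e. at
    least ``mean * (1 - mean)``.
    """
    if not 0 < mean < 1:
        raise ParameterError(f"beta mean must lie in (0, 1), got {mean}")
    if not (0 < ci_low <= mean <= ci_high < 1):
        raise ParameterError(f"CI ({ci_low}, {ci_high}) invalid for beta mean {mean}")
    var = ci_sd(ci_low, ci_high) ** 2
    if var >= mean * (1 - mean):
        raise ParameterError(
            f"variance {var:.6g} >= mean(1-mean) = {mean * (1 - mean):.6g}: "
            "no beta distribution has these moments"
        )
    k = mean * (1 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input: mean, optional 95% CI, distribution family."""

    name: str
    mean: float
    ci_low: float | None = None
    ci_high: float | None = None
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ParameterError(f"{self.name}: CI must give both bounds or neither")
        if self.family == "fixed":
            if self.ci_low is not None:
                raise ParameterError(f"{self.name}: fixed parameters carry no CI")
            return
        if self.ci_low is None:
            raise ParameterError(f"{self.name}: family {self.family} requires a CI")
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ParameterError(
                f"{self.name}: mean {self.mean} outside CI "
                f"({self.ci_low}, {self.ci_high})"
            )
        if self.family == "beta" and not (0 <= self.ci_low and self.ci_high <= 1):
            raise ParameterError(f"{self.name}: beta support is [0, 1]")
        if self.family == "gamma" and self.ci_low < 0:
            raise ParameterError(f"{self.name}: gamma support is non-negative")
        self.fitted()  # fail fast on infeasible moments

    @property
    def sd(self) -> float:
        """Standard deviation implied by the CI (0 for fixed parameters)."""
        if self.family == "fixed":
            return 0.0
        return ci_sd(self.ci_low, self.ci_high)

    def fitted(self) -> tuple[float, float] | None:
        """Fitted distribution parameters, or None for fixed parameters."""
        if self.family == "gamma":
            return fit_gamma(self.mean, self.ci_low, self.ci_high)
        if self.family == "beta":
            return fit_beta(self.mean, self.ci_low, self.ci_high)
        return None

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one realization from the fitted sampling distribution."""
        if self.family == "gamma":
            shape, scale = self.fitted()
            return float(rng.gamma(shape, scale))
        if self.family == "beta":
            alpha, beta = self.fitted()
            return float(rng.beta(alpha, beta))
        return float(self.mean)


@dataclass(frozen=True)
class ParameterSet(Mapping):
    """One realization of every model parameter (a point or a Monte-Carlo draw).

    Behaves as an immutable mapping from parameter name to value.
    """

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given parameters overridden."""
        unknown = set(overrides) - set(self.values)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return ParameterSet({**self.values, **overrides})

    def validate_against(self, specs: Iterable[ParameterSpec]) -> None:
        """Check the registry matches exactly and realizations respect support."""
        specs = list(specs)
        names = [s.name for s in specs]
        if set(names) != set(self.values):
            missing = set(names) - set(self.values)
            extra = set(self.values) - set(names)
            raise ParameterError(f"registry mismatch: missing={missing} extra={extra}")
        for spec in specs:
            v = self.values[spec.name]
            if spec.family == "beta" and not 0.0 <= v <= 1.0:
                raise ParameterError(f"{spec.name}: probability {v} outside [0, 1]")
            if v < 0.0:
                raise ParameterError(f"{spec.name}: negative realization {v}")


def _spec_from_entry(entry: Mapping) -> ParameterSpec:
    ci = entry.get("ci")
    lo, hi = (None, None) if ci is None else (float(ci[0]), float(ci[1]))
    return ParameterSpec(
        name=str(entry["name"]),
        mean=float(entry["mean"]),
        ci_low=lo,
        ci_high=hi,
        family=str(entry.get("family", "fixed")),
    )


def load_specs(path: str | Path) -> list[ParameterSpec]:
    """Read a parameter registry from a YAML file (``parameters:`` list)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ParameterError(f"{path}: expected a top-level 'parameters' list")
    specs = [_spec_from_entry(e) for e in doc["parameters"]]
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        dupes = {n for n in names if names.count(n) > 1}
        raise ParameterError(f"duplicate parameter name(s): {sorted(dupes)}")
    return specs


def default_specs() -> list[ParameterSpec]:
    """The built-in parameter registry shipped with the package."""
    ref = resources.files("ohca_cea").joinpath("data/parameters.yaml")
    with resources.as_file(ref) as path:
        return load_specs(path)


def point_estimates(specs: Iterable[ParameterSpec]) -> ParameterSet:
    """Deterministic parameter set with every parameter at its mean."""
    return ParameterSet({s.name: float(s.mean) for s in specs})


def sample_parameters(
    specs: Iterable[ParameterSpec],
    rng: np.random.Generator | int,
) -> ParameterSet:
    """Draw one Monte-Carlo realization of every parameter.

    ``rng`` may be a :class:`numpy.random.Generator` or an integer seed.
    Parameters are drawn in registry order, so an identical seed yields an
    identical parameter set.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ParameterSet({s.name: s.sample(rng) for s in specs})
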