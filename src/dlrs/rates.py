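"""The iid-Gamma relaxed molecular clock.

Each edge of the gene tree gets an independent substitution rate r drawn from
a Gamma distribution parameterized by its mean m and variance v (shape m^2/v,
scale v/m).  A gene edge of length l (substitutions/site) realized over a time
span t has rate r = l/t, and the DP multiplies the density rho(l/t) in once
per gene edge over the edge's full realized span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RateParams:
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.variance <= 0:
            raise ValueError("rate mean and variance must be positive")

    @property
    def shape(self) -> float:
        return self.mean**2 / self.variance

    @property
    def scale(self) -> float:
        return self.variance / self.mean


def rate_density(r, p: RateParams):
    """Gamma pdf with mean/variance parameterization; 0 outside (0, inf).

    Accepts scalars or numpy arrays and is vectorized (the DP evaluates it on
    whole matrices of candidate rates at once).
    """
    a, s = p.shape, p.scale
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    logc = -math.lgamma(a) - a * math.log(s)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out[pos] = np.exp(logc + (a - 1.0) * np.log(r[pos]) - r[pos] / s)
    if out.ndim == 0:
        return float(out)
    return out


def edge_rate(length: float, duration: float) -> float:
    """The realized substitution rate l/t of a gene edge spanning time t."""
    if length <= 0:
        raise ValueError("gene edge lengths must be positive")
    if duration <= 0:
        raise ValueError(
            "a gene vertex and its parent cannot be realized at the same time"
        )
    return length / duration


def sample_rates(p: RateParams, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.gamma(shape=p.shape, scale=p.scale, size=n)
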