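"""Joint DLRS model parameters: theta = (lambda, mu, m, v, M)."""

from __future__ import annotations

from dataclasses import dataclass, field

from .birth_death import BDParams
from .rates import RateParams
from .substitution import SubstModel


@dataclass
class ModelParams:
    lam: float          # duplication rate
    mu: float           # loss rate
    rate_mean: float    # mean edge substitution rate m
    rate_var: float     # variance of edge substitution rates v
    subst_model: SubstModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError("duplication/loss rates must be nonnegative")
        if self.rate_mean <= 0 or self.rate_var <= 0:
            raise ValueError("rate mean and variance must be positive")

    @property
    def bd(self) -> BDParams:
        return BDParams(self.lam, self.mu)

    @property
    def rates(self) -> RateParams:
        return RateParams(self.rate_mean, self.rate_var)

    def substitution(self) -> SubstModel:
        if self.subst_model is None:
            self.subst_model = SubstModel("JTT")
        return self.subst_model

    def replace(self, **kw) -> "ModelParams":
        vals = dict(
            lam=self.lam, mu=self.mu, rate_mean=self.rate_mean,
            rate_var=self.rate_var, subst_model=self.subst_model,
        )
        vals.update(kw)
        return ModelParams(**vals)
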