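"""The parametric disease model.

A single-locus diallelic model: disease-allele frequency ``q`` and a
penetrance vector ``(f0, f1, f2)`` giving the probability of being affected
with 0, 1 or 2 copies of the disease allele.  ``f0`` is the phenocopy rate.
For a dominant model ``f1 == f2``.

The population prevalence is

    K = f0 (1-q)^2 + f1 2 q (1-q) + f2 q^2

and for a dominant, phenocopy-free model the allele frequency implied by a
given prevalence is the closed-form root q = 1 - sqrt(1 - K / f1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pedio import Phenotype

__all__ = ["DiseaseModel", "from_prevalence", "penetrance_prob", "InfeasibleModelError"]


class InfeasibleModelError(ValueError):
    """Prevalence/penetrance combination with no valid allele frequency."""


@dataclass(frozen=True)
class DiseaseModel:
    q: float
    f0: float = 0.0
    f1: float = 0.8
    f2: float = 0.8

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("disease allele frequency q must lie in (0, 1)")
        for name in ("f0", "f1", "f2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"penetrance {name} must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("model implies a prevalence outside (0, 1)")

    @property
    def is_dominant(self) -> bool:
        return self.f1 == self.f2

    @property
    def prevalence(self) -> float:
        q = self.q
        return self.f0 * (1 - q) ** 2 + self.f1 * 2 * q * (1 - q) + self.f2 * q * q

    @property
    def penetrances(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


def from_prevalence(K: float, penetrance: float, mode: str = "dominant") -> DiseaseModel:
    """Dominant model with ``f0 = 0``, ``f1 = f2 = penetrance`` and the
    allele frequency solving ``K = penetrance * (2q(1-q) + q^2)``.
    """
    if mode != "dominant":
        raise ValueError(f"unsupported inheritance mode {mode!r}")
    if not 0.0 < K < 1.0:
        raise InfeasibleModelError("prevalence must lie in (0, 1)")
    if not 0.0 < penetrance <= 1.0:
        raise InfeasibleModelError("penetrance must lie in (0, 1]")
    if K >= penetrance:
        raise InfeasibleModelError(
            f"prevalence {K} >= penetrance {penetrance}: no allele frequency "
            "in (0, 1) can produce this prevalence"
        )
    q = 1.0 - math.sqrt(1.0 - K / penetrance)
    return DiseaseModel(q=q, f0=0.0, f1=penetrance, f2=penetrance)


def penetrance_prob(model: DiseaseModel, copies: int, phenotype: Phenotype) -> float:
    """P(observed phenotype | number of disease-allele copies).

    Unknown phenotype contributes no information (probability 1).
    """
    if copies not in (0, 1, 2):
        raise ValueError("copies must be 0, 1 or 2")
    if phenotype is Phenotype.UNKNOWN:
        return 1.0
    f = model.penetrances[copies]
    return f if phenotype is Phenotype.AFFECTED else 1.0 - f
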