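"""Genetic models and cohort simulation under Hardy-Weinberg equilibrium.

A single biallelic quantitative-trait locus has alleles A (major) and B
(minor, risk).  Genotype dosage counts copies of B: 0 = AA, 1 = AB, 2 = BB.
The trait is normal within genotype with a genotype-specific mean: the
reference genotype has mean 1 and the risk genotypes have mean delta (or
delta**2 for the homozygote under the multiplicative model); delta = 1 is
the null of no association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class GeneticModel(str, Enum):
    """Mode of inheritance, i.e. the pattern of genotype trait means."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    MULTIPLICATIVE = "multiplicative"

    @classmethod
    def coerce(cls, value: "GeneticModel | str") -> "GeneticModel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown genetic model {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class EffectSpec:
    """Effect size of the risk genotype.

    Parameters
    ----------
    delta
        Mean trait value of the non-reference genotype (the reference
        genotype has mean 1); ``delta == 1`` encodes the null hypothesis.
    sd
        Within-genotype phenotype standard deviation (default 1; trait
        means are on the reference-mean-1 scale, so sd is in the same
        unit).
    """

    delta: float
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")

    @property
    def is_null(self) -> bool:
        return self.delta == 1.0


@dataclass(frozen=True)
class PopulationSpec:
    """Complete description of a simulated cohort-generating population."""

    n: int
    maf: float
    model: GeneticModel
    effect: EffectSpec

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        object.__setattr__(self, "model", GeneticModel.coerce(self.model))


@dataclass
class Cohort:
    """Paired genotype dosages and quantitative phenotypes for n individuals."""

    genotypes: np.ndarray
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.genotypes.ndim != 1 or self.phenotypes.ndim != 1:
            raise ValueError("genotypes and phenotypes must be 1-D")
        if len(self.genotypes) != len(self.phenotypes):
            raise ValueError("genotypes and phenotypes must have equal length")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype dosages must be in {0, 1, 2}")
        if np.isnan(self.phenotypes).any():
            raise ValueError("simulated cohorts may not contain missing phenotypes")

    def __len__(self) -> int:
        return len(self.genotypes)


def genotype_means(model: GeneticModel | str, delta: float) -> tuple[float, float, float]:
    """Trait means (mu_AA, mu_AB, mu_BB) implied by the inheritance model.

    dominant -> (1, delta, delta); recessive -> (1, 1, delta);
    multiplicative -> (1, delta, delta**2).
    """
    if not delta > 0:
        raise ValueError(f"delta must be positive, got {delta}")
    model = GeneticModel.coerce(model)
    if model is GeneticModel.DOMINANT:
        return (1.0, delta, delta)
    if model is GeneticModel.RECESSIVE:
        return (1.0, 1.0, delta)
    return (1.0, delta, delta * delta)


def genotype_frequencies(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies (f_AA, f_AB, f_BB) = (q^2, 2pq, p^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    p = maf
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n genotype dosages: two independent Bernoulli(maf) alleles each."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n}")
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    return rng.binomial(2, maf, size=n).astype(np.int8)


def simulate_phenotypes(
    genotypes: np.ndarray,
    model: GeneticModel | str,
    effect: EffectSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw phenotypes y_i ~ Normal(mu_{g_i}, sd^2), independent across individuals."""
    genotypes = np.asarray(genotypes)
    if genotypes.size == 0:
        raise ValueError("genotypes must be nonempty")
    mu = np.asarray(genotype_means(model, effect.delta))
    return rng.normal(mu[genotypes], effect.sd)


def simulate_cohort(spec: PopulationSpec, rng: np.random.Generator) -> Cohort:
    """Simulate one cohort: HWE genotypes, then normal phenotypes given genotype."""
    g = simulate_genotypes(spec.n, spec.maf, rng)
    y = simulate_phenotypes(g, spec.model, spec.effect, rng)
    return Cohort(genotypes=g, phenotypes=y)
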