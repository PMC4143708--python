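"""Mendelian transmission law for autosomal biallelic variants.

Everything downstream of trio genotypes rests on the conditional
distribution of the offspring allele dosage given the two parental
dosages.  Each parent transmits one of its two alleles independently and
uniformly at random, so a parent with coded-allele dosage g transmits the
coded allele with probability g/2.  The conditional mean E(X | Xp) is
therefore (gf + gm)/2 under additive coding, and the conditional variance
is 1/4 per heterozygous parent.

This module also provides the parental minor-allele-frequency estimator
and the Beta-density variant weights used by the kernel tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DOSAGES = (0, 1, 2)

__all__ = [
    "DOSAGES",
    "TransmissionTable",
    "TRANSMISSION_TABLE",
    "offspring_distribution",
    "expected_dosage",
    "conditional_variance",
    "expected_dosage_matrix",
    "conditional_variance_matrix",
    "mendelian_error_mask",
    "parental_maf",
    "beta_weights",
    "WeightSpec",
]


def _check_dosage(g: int) -> None:
    if g not in (0, 1, 2):
        raise ValueError(f"parental dosage must be in {{0, 1, 2}}, got {g!r}")


def offspring_distribution(gf: int, gm: int) -> np.ndarray:
    """P(offspring dosage = k | parental dosages gf, gm) for k in {0, 1, 2}.

    Each parent transmits the coded allele with probability dosage/2,
    independently of the other parent.
    """
    _check_dosage(gf)
    _check_dosage(gm)
    pf, pm = gf / 2.0, gm / 2.0
    return np.array(
        [
            (1.0 - pf) * (1.0 - pm),
            pf * (1.0 - pm) + (1.0 - pf) * pm,
            pf * pm,
        ]
    )


def expected_dosage(gf: int, gm: int) -> float:
    """Conditional mean offspring dosage; equals (gf + gm) / 2."""
    dist = offspring_distribution(gf, gm)
    return float(dist @ np.array([0.0, 1.0, 2.0]))


def conditional_variance(gf: int, gm: int) -> float:
    """Conditional variance of the offspring dosage: 1/4 per het parent."""
    dist = offspring_distribution(gf, gm)
    mean = dist @ np.array([0.0, 1.0, 2.0])
    return float(dist @ np.array([0.0, 1.0, 4.0]) - mean**2)


@dataclass(frozen=True)
class TransmissionTable:
    """Enumerated transmission law for all 9 parental dosage pairs."""

    probabilities: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    variances: dict = field(default_factory=dict)

    @classmethod
    def build(cls) -> "TransmissionTable":
        probs, means, variances = {}, {}, {}
        for gf in DOSAGES:
            for gm in DOSAGES:
                probs[(gf, gm)] = offspring_distribution(gf, gm)
                means[(gf, gm)] = expected_dosage(gf, gm)
                variances[(gf, gm)] = conditional_variance(gf, gm)
        return cls(probs, means, variances)


TRANSMISSION_TABLE = TransmissionTable.build()


def expected_dosage_matrix(paternal: np.ndarray, maternal: np.ndarray) -> np.ndarray:
    """Vectorized E(X | Xp) = (gf + gm)/2; NaN propagates from missing parents."""
    return 0.5 * (np.asarray(paternal, dtype=float) + np.asarray(maternal, dtype=float))


def conditional_variance_matrix(paternal: np.ndarray, maternal: np.ndarray) -> np.ndarray:
    """Vectorized Var(X | Xp) = 0.25 x (number of heterozygous parents)."""
    pat = np.asarray(paternal, dtype=float)
    mat = np.asarray(maternal, dtype=float)
    var = 0.25 * ((pat == 1).astype(float) + (mat == 1).astype(float))
    var[np.isnan(pat) | np.isnan(mat)] = np.nan
    return var


def mendelian_error_mask(
    paternal: np.ndarray, maternal: np.ndarray, offspring: np.ndarray
) -> np.ndarray:
    """True where the observed offspring dosage is impossible given the parents.

    Cells with any missing member are False (missingness handled separately).
    """
    pat = np.asarray(paternal, dtype=float)
    mat = np.asarray(maternal, dtype=float)
    off = np.asarray(offspring, dtype=float)
    pf, pm = pat / 2.0, mat / 2.0
    p0 = (1.0 - pf) * (1.0 - pm)
    p1 = pf + pm - 2.0 * pf * pm
    p2 = pf * pm
    prob = np.where(off == 0, p0, np.where(off == 1, p1, p2))
    complete = ~(np.isnan(pat) | np.isnan(mat) | np.isnan(off))
    return complete & (prob == 0)


def parental_maf(paternal: np.ndarray, maternal: np.ndarray) -> np.ndarray:
    """Coded-allele frequency estimated from the parents only.

    f_j = (coded alleles among non-missing parents at j)
          / (2 x number of non-missing parental genotypes at j).

    Variants where every parental genotype is missing get NaN; callers must
    exclude them from testing.
    """
    pat = np.atleast_2d(np.asarray(paternal, dtype=float))
    mat = np.atleast_2d(np.asarray(maternal, dtype=float))
    stacked = np.vstack([pat, mat])
    n_obs = np.sum(~np.isnan(stacked), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        counts = np.nansum(stacked, axis=0)
        freqs = np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)
    return freqs


def beta_weights(frequencies: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Variant weights w_j = Beta density(f_j; a, b).

    The convention a=1, b=25 upweights rare variants sharply while leaving
    common variants with near-zero weight.  Weights are finite for
    0 < f < 1; monomorphic variants (f = 0) must be excluded upstream when
    a < 1 (the density diverges there).
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"Beta shape parameters must be positive, got a={a}, b={b}")
    f = np.asarray(frequencies, dtype=float)
    if np.any(np.isnan(f)):
        raise ValueError("cannot weight variants with undefined frequency (all parents missing)")
    if a < 1 and np.any(f == 0):
        raise ValueError(
            "Beta weight is infinite at frequency 0 when a < 1; "
            "exclude monomorphic variants before weighting"
        )
    return stats.beta.pdf(f, a, b)


@dataclass
class WeightSpec:
    """Beta-weight parameters plus the per-variant frequencies and weights."""

    a: float
    b: float
    frequencies: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.weights = beta_weights(self.frequencies, self.a, self.b)
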