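"""Synthetic trio cohorts with known truth.

Parental genotypes are drawn under Hardy-Weinberg equilibrium from a
configurable minor-allele-frequency spectrum (a 1/f-shaped rare tail plus
a uniform common component); offspring genotypes follow by Mendelian
transmission, so the cohort contains zero Mendelian errors by
construction.  Two correlated quantitative traits share a genetic
component built from a sparse causal-effect vector whose magnitudes can
grow with rarity (|beta_j| = c |log10 f_j|) and whose signs follow a
configurable direction mixture; a third, pure-noise trait provides the
null for type-I-error studies.  An optional two-subpopulation mode
(Balding-Nichols allele-frequency divergence plus a trait mean offset)
creates population stratification with no genetic effect, the classic
confounding scenario that transmission-based tests must resist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trio_data import GenotypeMatrix, PhenotypeTable, Trio, TrioCohort

__all__ = [
    "StratificationConfig",
    "SimConfig",
    "SimTruth",
    "simulate_mafs",
    "simulate_parents",
    "simulate_offspring",
    "simulate_effects",
    "simulate_traits",
    "generate_cohort",
    "resample_phenotypes",
    "write_cohort",
]


@dataclass
class StratificationConfig:
    """Two-subpopulation confounding: allele-frequency divergence + trait offset.

    Subpopulation frequencies are drawn around each base frequency with a
    Balding-Nichols Beta model at the given Fst; both parents of a trio
    come from the same subpopulation.  The trait offset (in residual-SD
    units) is added to every trait, including the null trait, so that
    trait and ancestry are confounded without any genetic effect.
    """

    fst: float = 0.1
    trait_offset: float = 1.0
    prop_pop1: float = 0.5


@dataclass
class SimConfig:
    """Generative parameters for a synthetic trio cohort.

    Defaults mirror the scale of the motivating study: 93 trios and a
    gene-sized region of ~30 variants, 80% of them rare (MAF <= 0.05).
    ``effect_scale`` is the c in |beta_j| = c |log10 f_j| (or the common
    magnitude under the constant effect model); ``direction_mix`` is the
    proportion of causal effects with positive sign.  Trait2 shares
    trait1's genetic component scaled by ``trait_sharing`` with residual
    correlation ``residual_corr`` — a stand-in for a highly correlated
    blood-pressure pair — and ``null_trait`` is always pure noise.
    """

    n_trios: int = 93
    n_variants: int = 30
    proportion_rare: float = 0.8
    rare_maf_min: float | None = None  # default 1/(4 n_trios)
    rare_maf_max: float = 0.05
    common_maf_max: float = 0.5
    causal_fraction: float = 0.2
    effect_model: str = "log_maf"  # or "constant"
    effect_scale: float = 0.5
    direction_mix: float = 0.5
    trait_sharing: float = 0.8
    residual_corr: float = 0.6
    noise_sd: float = 1.0
    intercept: float = 0.0
    stratification: StratificationConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.proportion_rare <= 1:
            raise ValueError("proportion_rare must be in [0, 1]")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must be in [0, 1]")
        if not -1 < self.residual_corr < 1:
            raise ValueError("residual_corr must be in (-1, 1)")
        if not 0 < self.rare_maf_max < self.common_maf_max <= 0.5:
            raise ValueError("need 0 < rare_maf_max < common_maf_max <= 0.5")
        if isinstance(self.stratification, dict):
            self.stratification = StratificationConfig(**self.stratification)


@dataclass
class SimTruth:
    """Answer sheet for a simulated cohort."""

    variant_ids: list[str]
    maf: np.ndarray
    causal: np.ndarray  # bool
    beta_trait1: np.ndarray
    beta_trait2: np.ndarray
    subpop: np.ndarray | None = None  # per-trio labels under stratification
    subpop_maf: np.ndarray | None = None  # (2, m) under stratification


def simulate_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the MAF spectrum: 1/f-shaped rare tail + uniform common body.

    Each variant is independently rare with probability
    ``proportion_rare``; rare frequencies have density proportional to
    1/f on (rare_maf_min, rare_maf_max], a caricature of the neutral
    site-frequency spectrum.
    """
    m = config.n_variants
    fmin = config.rare_maf_min or 1.0 / (4 * config.n_trios)
    is_rare = rng.random(m) < config.proportion_rare
    rare = fmin * (config.rare_maf_max / fmin) ** rng.random(m)  # inverse-CDF of 1/f
    common = config.rare_maf_max + rng.random(m) * (config.common_maf_max - config.rare_maf_max)
    return np.where(is_rare, rare, common)


def simulate_parents(
    frequencies: np.ndarray,
    n_trios: int,
    stratification: StratificationConfig | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Parental dosages under HWE; returns (paternal, maternal, subpop, subpop_maf)."""
    f = np.asarray(frequencies, dtype=float)
    m = f.size
    if stratification is None:
        pat = rng.binomial(2, f, size=(n_trios, m)).astype(float)
        mat = rng.binomial(2, f, size=(n_trios, m)).astype(float)
        return pat, mat, None, None
    fst = stratification.fst
    # Balding-Nichols: subpopulation frequencies around the base frequency
    shape1 = f * (1 - fst) / fst
    shape2 = (1 - f) * (1 - fst) / fst
    sub_f = np.vstack([rng.beta(shape1, shape2), rng.beta(shape1, shape2)])
    sub_f = np.clip(sub_f, 1e-6, 1 - 1e-6)
    subpop = (rng.random(n_trios) < stratification.prop_pop1).astype(int)
    fmat = sub_f[subpop]  # (n_trios, m): each trio's parents share a subpopulation
    pat = rng.binomial(2, fmat).astype(float)
    mat = rng.binomial(2, fmat).astype(float)
    return pat, mat, subpop, sub_f


def simulate_offspring(
    paternal: np.ndarray, maternal: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One allele from each parent: transmit probability = dosage / 2."""
    pat = np.asarray(paternal)
    mat = np.asarray(maternal)
    return (
        rng.binomial(1, pat / 2.0).astype(float) + rng.binomial(1, mat / 2.0).astype(float)
    )


def simulate_effects(
    maf: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Causal flags and per-trait effect vectors.

    Causal variants are a Bernoulli(causal_fraction) subset; magnitudes
    follow the configured rule and signs are + with probability
    ``direction_mix``.  Trait2 effects are trait1 effects scaled by the
    sharing factor (shared causal set).
    """
    m = maf.size
    causal = rng.random(m) < config.causal_fraction
    if config.effect_model == "log_maf":
        magnitude = config.effect_scale * np.abs(np.log10(maf))
    elif config.effect_model == "constant":
        magnitude = np.full(m, config.effect_scale)
    else:
        raise ValueError(f"unknown effect_model {config.effect_model!r}")
    sign = np.where(rng.random(m) < config.direction_mix, 1.0, -1.0)
    beta1 = np.where(causal, sign * magnitude, 0.0)
    beta2 = config.trait_sharing * beta1
    return causal, beta1, beta2


def simulate_traits(
    offspring: np.ndarray,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Two correlated traits plus a pure-noise null trait.

    trait1 = b0 + X beta1 + e1, trait2 = b0 + X beta2 + e2 with
    corr(e1, e2) = residual_corr; null_trait = independent noise.  Under
    stratification every trait gets the subpopulation mean offset.
    """
    n = offspring.shape[0]
    sd = config.noise_sd
    r = config.residual_corr
    cov = sd**2 * np.array([[1.0, r], [r, 1.0]])
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    e_null = rng.normal(0.0, sd, size=n)
    g1 = offspring @ truth.beta_trait1
    g2 = offspring @ truth.beta_trait2
    offset = np.zeros(n)
    if config.stratification is not None and truth.subpop is not None:
        offset = config.stratification.trait_offset * sd * truth.subpop
    traits = pd.DataFrame(
        {
            "trait1": config.intercept + g1 + eps[:, 0] + offset,
            "trait2": config.intercept + g2 + eps[:, 1] + offset,
            "null_trait": e_null + offset,
        }
    )
    return PhenotypeTable(traits=traits)


def _rng_from(config: SimConfig, seed: int | None, rng: np.random.Generator | None):
    if rng is not None:
        return rng
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required: set SimConfig.seed or pass seed=/rng=")
    return np.random.default_rng(seed)


def generate_cohort(
    config: SimConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrioCohort, SimTruth]:
    """Generate a full synthetic cohort; deterministic given the seed."""
    rng = _rng_from(config, seed, rng)
    n, m = config.n_trios, config.n_variants
    maf = simulate_mafs(config, rng)
    pat, mat, subpop, sub_f = simulate_parents(maf, n, config.stratification, rng)
    off = simulate_offspring(pat, mat, rng)
    causal, beta1, beta2 = simulate_effects(maf, config, rng)
    variant_ids = [f"V{j + 1:04d}" for j in range(m)]
    truth = SimTruth(
        variant_ids=variant_ids,
        maf=maf,
        causal=causal,
        beta_trait1=beta1,
        beta_trait2=beta2,
        subpop=subpop,
        subpop_maf=sub_f,
    )
    phenotypes = simulate_traits(off, truth, config, rng)
    genotypes = GenotypeMatrix(
        variant_ids=variant_ids,
        offspring=off,
        paternal=pat,
        maternal=mat,
        positions=np.arange(1, m + 1) * 100,
        chroms=["3"] * m,
        coded_allele=["ALT"] * m,
    )
    trios = [
        Trio(
            father_id=f"F{i + 1}",
            mother_id=f"M{i + 1}",
            offspring_id=f"O{i + 1}",
            family_id=f"FAM{i + 1}",
            index=i,
        )
        for i in range(n)
    ]
    return TrioCohort(trios=trios, genotypes=genotypes, phenotypes=phenotypes), truth


def resample_phenotypes(
    cohort: TrioCohort,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> TrioCohort:
    """Fresh phenotype noise on fixed genotypes (replicate-style resampling)."""
    phen = simulate_traits(cohort.genotypes.offspring, truth, config, rng)
    return TrioCohort(trios=cohort.trios, genotypes=cohort.genotypes, phenotypes=phen)


# ---------------------------------------------------------------------------
# Text outputs for the CLI round trip

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_cohort(cohort: TrioCohort, truth: SimTruth, prefix: str) -> dict[str, str]:
    """Write <prefix>.vcf/.ped/.pheno.tsv/.truth.tsv; returns the paths."""
    paths = {
        "vcf": f"{prefix}.vcf",
        "ped": f"{prefix}.ped",
        "pheno": f"{prefix}.pheno.tsv",
        "truth": f"{prefix}.truth.tsv",
    }
    g = cohort.genotypes
    samples: list[str] = []
    for t in cohort.trios:
        samples.extend([t.father_id, t.mother_id, t.offspring_id])
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=3>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, vid in enumerate(g.variant_ids):
            chrom = g.chroms[j] if g.chroms else "3"
            gts = []
            for i, _t in enumerate(cohort.trios):
                for d in (g.paternal[i, j], g.maternal[i, j], g.offspring[i, j]):
                    gts.append("./." if np.isnan(d) else _GT[d])
            fh.write(
                f"{chrom}\t{int(g.positions[j])}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    with open(paths["ped"], "w") as fh:
        for t in cohort.trios:
            fh.write(f"{t.family_id} {t.father_id} 0 0 1 0\n")
            fh.write(f"{t.family_id} {t.mother_id} 0 0 2 0\n")
            fh.write(f"{t.family_id} {t.offspring_id} {t.father_id} {t.mother_id} 0 0\n")
    pheno = cohort.phenotypes.traits.copy()
    pheno.insert(0, "iid", [t.offspring_id for t in cohort.trios])
    pheno.to_csv(paths["pheno"], sep="\t", index=False)
    tdf = pd.DataFrame(
        {
            "variant_id": truth.variant_ids,
            "maf": truth.maf,
            "causal": truth.causal.astype(int),
            "beta_trait1": truth.beta_trait1,
            "beta_trait2": truth.beta_trait2,
        }
    )
    tdf.to_csv(paths["truth"], sep="\t", index=False)
    return paths
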