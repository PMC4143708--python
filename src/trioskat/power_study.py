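"""Scenario grids, empirical type-I error / power estimation, and the
GEE-based cross-scenario power comparison.

The study design crosses trait (two correlated quantitative traits) x
method (variance-component SKAT vs collapsing burden) x variant stratum
(rare only, common only, all), giving 12 scenarios, optionally further
crossed with the proportion of causal variants retained in the tested set
(signal dilution at 10%, 25%, 50% -> 36 scenarios).  Rejection counts per
gene and scenario over replicates form a PowerTable; power differences
across scenario factors are then compared with a binomial-logit marginal
model fitted by generalized estimating equations, clustering the repeated
scenarios of a gene with an exchangeable working correlation and robust
(sandwich) standard errors:

    logit p_ij = b0 + b1 I(trait1) + b2 I(common) + b3 I(common and rare)
                 + b4 I(SKAT)   [+ b5 * causal proportion, adjusted model]
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulator, skat_core
from .simulator import SimConfig, SimTruth

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "build_grid",
    "dilute_signal",
    "run_scenarios",
    "estimate_type1_error",
    "PowerComparisonResult",
    "gee_power_comparison",
]

DEFAULT_PROPORTIONS = (0.10, 0.25, 0.50)


@dataclass(frozen=True)
class Scenario:
    trait: str
    method: str  # "skat" | "burden"
    stratum: str  # "rare" | "common" | "all"
    proportion: float | None = None  # causal proportion in the tested set


def build_grid(
    proportions: tuple[float, ...] | None = None,
    traits: tuple[str, ...] = ("trait1", "trait2"),
    methods: tuple[str, ...] = ("skat", "burden"),
    strata: tuple[str, ...] = ("rare", "common", "all"),
) -> list[Scenario]:
    """The 12-cell scenario grid, or 36 cells when crossed with proportions."""
    cells = [
        Scenario(trait=t, method=m, stratum=s)
        for t in traits
        for m in methods
        for s in strata
    ]
    if proportions is None:
        return cells
    return [
        Scenario(trait=c.trait, method=c.method, stratum=c.stratum, proportion=p)
        for c in cells
        for p in proportions
    ]


def dilute_signal(
    truth: SimTruth, target_proportion: float, rng: np.random.Generator
) -> list[str]:
    """Fix the causal set, dilute with random noncausal variants.

    Returns all causal variants plus k noncausal variants sampled without
    replacement, k = round(n_causal (1 - pi) / pi), so the causal
    proportion of the returned set is as close as possible to pi.
    """
    if not 0 < target_proportion <= 1:
        raise ValueError("target_proportion must lie in (0, 1]")
    ids = np.asarray(truth.variant_ids)
    causal_ids = ids[truth.causal]
    noncausal_ids = ids[~truth.causal]
    if causal_ids.size == 0:
        raise ValueError("gene has no causal variants; cannot dilute signal")
    k = int(round(causal_ids.size * (1 - target_proportion) / target_proportion))
    if k > noncausal_ids.size:
        logger.warning(
            "only %d noncausal variants available (needed %d for proportion %.2f); using all",
            noncausal_ids.size, k, target_proportion,
        )
        k = noncausal_ids.size
    chosen = rng.choice(noncausal_ids, size=k, replace=False) if k else np.array([], dtype=ids.dtype)
    keep = set(causal_ids) | set(chosen)
    return [v for v in truth.variant_ids if v in keep]


def run_scenarios(
    config: SimConfig,
    grid: list[Scenario],
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    n_genes: int = 1,
    regenerate_genotypes: bool = False,
    weights: tuple[float, float] = (1.0, 25.0),
    maf_threshold: float = 0.05,
) -> pd.DataFrame:
    """Estimate per-gene, per-scenario rejection rates over replicates.

    Each gene is an independently generated region with its own causal
    truth.  By default genotypes are fixed per gene and only phenotype
    noise is redrawn across replicates (the shared-genotype replicate
    design); set ``regenerate_genotypes`` to redraw genotypes too.
    Diluted variant subsets are drawn once per gene and proportion and
    held fixed across replicates.  Untestable cells (empty stratum) are
    excluded from the counts for that replicate.

    Returns a DataFrame with columns gene, trait, method, stratum,
    proportion, n_reps, n_tested, rejections, power.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.SeedSequence(seed)
    gene_seqs = master.spawn(n_genes)
    rows = []
    for gidx, gseq in enumerate(gene_seqs):
        gene = f"G{gidx + 1}"
        gene_rng = np.random.default_rng(gseq)
        cohort, truth = simulator.generate_cohort(config, rng=gene_rng)
        subsets: dict[float, list[str]] = {}
        for cell in grid:
            if cell.proportion is not None and cell.proportion not in subsets:
                subsets[cell.proportion] = dilute_signal(truth, cell.proportion, gene_rng)
        rejections = {cell: 0 for cell in grid}
        n_tested = {cell: 0 for cell in grid}
        for _rep in range(n_reps):
            if regenerate_genotypes:
                cohort, truth = simulator.generate_cohort(config, rng=gene_rng)
                for p in list(subsets):
                    subsets[p] = dilute_signal(truth, p, gene_rng)
            else:
                cohort = simulator.resample_phenotypes(cohort, truth, config, gene_rng)
            for cell in grid:
                variants = subsets.get(cell.proportion) if cell.proportion else None
                result = skat_core.run_test(
                    cohort,
                    trait=cell.trait,
                    variants=variants,
                    gene=gene,
                    stratum=cell.stratum,
                    method=cell.method,
                    weights=weights,
                    maf_threshold=maf_threshold,
                )
                if not result.testable:
                    continue
                n_tested[cell] += 1
                if result.p_value <= alpha:
                    rejections[cell] += 1
        for cell in grid:
            nt = n_tested[cell]
            rows.append(
                {
                    "gene": gene,
                    "trait": cell.trait,
                    "method": cell.method,
                    "stratum": cell.stratum,
                    "proportion": cell.proportion,
                    "n_reps": n_reps,
                    "n_tested": nt,
                    "rejections": rejections[cell],
                    "power": rejections[cell] / nt if nt else np.nan,
                }
            )
    return pd.DataFrame(rows)


def estimate_type1_error(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    methods: tuple[str, ...] = ("skat", "burden"),
    stratum: str = "all",
    regenerate_genotypes: bool = True,
    weights: tuple[float, float] = (1.0, 25.0),
) -> dict[str, float]:
    """Empirical rejection rate of the pure-noise trait at level alpha.

    Fresh null cohorts are generated per replicate by default, so the
    rate averages over genotype configurations as well as trait noise.
    """
    grid = [Scenario(trait="null_trait", method=m, stratum=stratum) for m in methods]
    table = run_scenarios(
        config,
        grid,
        n_reps=n_reps,
        alpha=alpha,
        seed=seed,
        n_genes=1,
        regenerate_genotypes=regenerate_genotypes,
        weights=weights,
    )
    return {row["method"]: row["power"] for _, row in table.iterrows()}


@dataclass
class PowerComparisonResult:
    """GEE binomial-logit comparison of power across scenario factors."""

    params: pd.Series
    robust_se: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    joint_stratum_stat: float
    joint_stratum_df: int
    joint_stratum_p: float
    n_genes: int
    n_cells: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "robust_se": self.robust_se.to_numpy(),
                "wald_z": self.wald_z.to_numpy(),
                "p": self.p_values.to_numpy(),
            }
        )


def _gee_fit_is_sane(res) -> bool:
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        return False
    # |logit| beyond ~50 or a zero robust SE on a nonzero coefficient means
    # the unguarded update diverged
    if np.max(np.abs(params)) > 50:
        return False
    return bool(np.all(bse[np.abs(params) > 1e-8] > 0))


def _fit_binomial_gee(prop: np.ndarray, X: pd.DataFrame, groups: np.ndarray,
                      n_trials: np.ndarray):
    """Binomial-logit GEE with exchangeable gene clusters and sandwich SEs.

    statsmodels' alternating mean/correlation updates have no step control
    and can diverge when the within-gene correlation is large; in that
    case the correlation parameter is estimated once from an
    independence-start iteration, frozen, and the mean model refitted
    (a one-step GEE — same asymptotics, stable numerics).
    """
    import statsmodels.api as sm

    fam = sm.families.Binomial()

    def _fit(cov_struct, update_dep=True, start=None):
        model = sm.GEE(prop, X, groups=groups, family=fam, cov_struct=cov_struct,
                       weights=n_trials, update_dep=update_dep)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(start_params=start)

    res = _fit(sm.cov_struct.Exchangeable())
    if _gee_fit_is_sane(res):
        return res
    ind = _fit(sm.cov_struct.Independence())
    if not _gee_fit_is_sane(ind):
        raise ValueError("GEE fit did not converge; check the power table for degeneracy")
    cs = sm.cov_struct.Exchangeable()
    model = sm.GEE(prop, X, groups=groups, family=fam, cov_struct=cs,
                   weights=n_trials)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(maxiter=1, start_params=np.asarray(ind.params))
    alpha = float(np.nan_to_num(np.asarray(cs.dep_params, dtype=float)))
    alpha = min(max(alpha, 0.0), 0.95)
    frozen = sm.cov_struct.Exchangeable()
    frozen.dep_params = alpha
    res = _fit(frozen, update_dep=False, start=np.asarray(ind.params))
    if not _gee_fit_is_sane(res):
        raise ValueError("GEE fit did not converge; check the power table for degeneracy")
    return res


def gee_power_comparison(table: pd.DataFrame, adjusted: bool = False) -> PowerComparisonResult:
    """Fit logit p_ij = b0 + b1 I(trait1) + b2 I(common) + b3 I(all) + b4 I(skat)
    (+ proportion, if adjusted) by GEE with gene clusters.

    Each gene contributes its scenario cells as correlated binomial
    measurements y_ij ~ Binomial(n_reps, p_ij) (proportion endog with the
    trial count as weight); the working correlation is exchangeable within
    gene and inference uses robust sandwich standard errors.  The joint
    Wald test of the two stratum indicators (b2, b3) summarizes the
    overall variant-stratum effect.
    """
    import statsmodels.api as sm

    df = table.dropna(subset=["power"]).copy()
    if df["gene"].nunique() < 2:
        raise ValueError("need scenario results for at least 2 genes")
    if ((df["rejections"] == 0) | (df["rejections"] == df["n_tested"])).all():
        raise ValueError(
            "every cell has power exactly 0 or 1; the binomial logit model is degenerate"
        )

    terms = ["intercept", "trait1", "common", "common_and_rare", "skat"]
    design_rows = []
    for _, row in df.iterrows():
        x = [
            1.0,
            1.0 if row["trait"] == "trait1" else 0.0,
            1.0 if row["stratum"] == "common" else 0.0,
            1.0 if row["stratum"] == "all" else 0.0,
            1.0 if row["method"] == "skat" else 0.0,
        ]
        if adjusted:
            x.append(float(row["proportion"]))
        design_rows.append(x)
    if adjusted:
        terms = terms + ["proportion"]
    X = pd.DataFrame(design_rows, columns=terms)
    n_trials = df["n_tested"].to_numpy(dtype=float)
    prop = df["rejections"].to_numpy(dtype=float) / n_trials
    res = _fit_binomial_gee(prop, X, df["gene"].to_numpy(), n_trials)
    contrast = np.zeros((2, len(terms)))
    contrast[0, terms.index("common")] = 1.0
    contrast[1, terms.index("common_and_rare")] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank warnings on degenerate contrasts
        joint = res.wald_test(contrast, scalar=True)
    return PowerComparisonResult(
        params=res.params,
        robust_se=res.bse,
        wald_z=res.params / res.bse,
        p_values=res.pvalues,
        joint_stratum_stat=float(joint.statistic),
        joint_stratum_df=contrast.shape[0],
        joint_stratum_p=float(joint.pvalue),
        n_genes=df["gene"].nunique(),
        n_cells=len(df),
    )
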