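"""Family-based SKAT / burden / rho-kernel score test for trio cohorts.

The model is a GLMM h(mu_i) = C_i alpha + X_i beta for the offspring trait,
with variant effects beta_j treated as independent random variables of mean
zero and variance w_j^2 tau.  Testing "no genetic effect" is testing
H0: tau = 0, and the score statistic is the quadratic form

    Q_rho = (Y - mu0)' (X - E(X|Xp)) W R_rho W (X - E(X|Xp))' (Y - mu0)

where E(X|Xp) is the Mendelian conditional expectation of the offspring
dosage given the parents, W = diag(w_j) holds Beta-density weights from the
parental allele frequencies, and R_rho = (1-rho) I + rho 11' interpolates
between the variance-component kernel (rho=0, SKAT) and the collapsing
burden kernel (rho=1, the FBAT statistic).  Conditioning the genotype
scores on the parental genotypes is what makes the test a transmission
disequilibrium test, robust to population structure.

Under H0, conditionally on parents and trait, Q converges to a mixture
sum_j lambda_j chi2_1 whose weights are the eigenvalues of W R_rho W V,
with V = Cov((X - E(X|Xp))' (Y - mu0) | Xp, Y).  P-values are computed by
numerically inverting the characteristic function of the mixture, falling
back to moment matching when the inversion is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from . import transmission
from .trio_data import GenotypeMatrix, TrioCohort, partition_variants

__all__ = [
    "NullModel",
    "CenteredScores",
    "KernelSpec",
    "TestResult",
    "CFInversionError",
    "fit_null_model",
    "center_genotypes",
    "compute_statistic",
    "null_eigenvalues",
    "pvalue_cf_inversion",
    "pvalue_moment_matching",
    "mixture_pvalue",
    "run_test",
]

EIGEN_TRUNCATION = 1e-10  # relative to the largest eigenvalue


class CFInversionError(RuntimeError):
    """Characteristic-function inversion failed; fall back to moment matching."""


@dataclass
class NullModel:
    """Null (no-genetic-effect) fit of the trait on the covariates."""

    trait_type: str  # "continuous" | "dichotomous"
    alpha_hat: np.ndarray
    mu0: np.ndarray
    residuals: np.ndarray


def fit_null_model(Y: np.ndarray, C: np.ndarray, trait_type: str = "continuous") -> NullModel:
    """Fit mu0 = C alpha (continuous, least squares) or logit^-1(C alpha).

    The score test only needs the null residuals Y - mu0.
    """
    Y = np.asarray(Y, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != Y.shape[0]:
        raise ValueError(f"covariate rows {C.shape[0]} != trait length {Y.shape[0]}")
    k = C.shape[1]
    if Y.shape[0] < k + 1:
        raise ValueError("need at least one more trio than covariates")
    if np.linalg.matrix_rank(C) < k:
        raise ValueError("covariate matrix is rank deficient")
    if trait_type == "continuous":
        alpha, *_ = np.linalg.lstsq(C, Y, rcond=None)
        mu0 = C @ alpha
    elif trait_type == "dichotomous":
        if not set(np.unique(Y)) <= {0.0, 1.0}:
            raise ValueError("dichotomous trait must take values in {0, 1}")
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                fit = sm.GLM(Y, C, family=sm.families.Binomial()).fit()
            except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
                if "eparation" in str(exc) or isinstance(exc, PerfectSeparationWarning):
                    raise ValueError(
                        "logistic null model is separable; drop or coarsen covariates"
                    ) from exc
                raise
        alpha = np.asarray(fit.params)
        mu0 = np.asarray(fit.fittedvalues)
        if np.any(mu0 <= 0) or np.any(mu0 >= 1):
            mu0 = np.clip(mu0, 1e-12, 1 - 1e-12)
    else:
        raise ValueError(f"trait_type must be continuous or dichotomous, got {trait_type!r}")
    return NullModel(trait_type=trait_type, alpha_hat=np.asarray(alpha), mu0=mu0,
                     residuals=Y - mu0)


@dataclass
class CenteredScores:
    """Transmission-centered genotype scores X - E(X|Xp).

    Cells with a missing member or a Mendelian inconsistency carry no
    transmission information and are zeroed in both the score and its
    conditional variance.
    """

    scores: np.ndarray  # (N, m), entries in [-2, 2]
    variances: np.ndarray  # (N, m), Var(X_ij | Xp) under Mendelian transmission
    n_mendelian_errors: int = 0


def center_genotypes(g: GenotypeMatrix) -> CenteredScores:
    expected = transmission.expected_dosage_matrix(g.paternal, g.maternal)
    scores = g.offspring - expected
    var = transmission.conditional_variance_matrix(g.paternal, g.maternal)
    mendel = transmission.mendelian_error_mask(g.paternal, g.maternal, g.offspring)
    n_errors = int(mendel.sum())
    invalid = np.isnan(scores) | np.isnan(var) | mendel
    scores = np.where(invalid, 0.0, scores)
    var = np.where(invalid, 0.0, var)
    return CenteredScores(scores=scores, variances=var, n_mendelian_errors=n_errors)


@dataclass
class KernelSpec:
    """rho-kernel: weights w_j and exchangeable effect correlation R_rho."""

    rho: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite and nonnegative")

    @property
    def R(self) -> np.ndarray:
        m = len(self.weights)
        return (1 - self.rho) * np.eye(m) + self.rho * np.ones((m, m))

    def wrw(self) -> np.ndarray:
        """W R_rho W as a dense symmetric matrix."""
        w = self.weights
        return (1 - self.rho) * np.diag(w**2) + self.rho * np.outer(w, w)


def compute_statistic(residuals: np.ndarray, scores: CenteredScores, kernel: KernelSpec) -> float:
    """Q = r' S W R_rho W S' r with r the null residuals, S the centered scores."""
    if scores.scores.shape[1] == 0:
        raise ValueError("no testable variants")
    r = np.asarray(residuals, dtype=float)
    u = scores.scores.T @ r  # per-variant score sums
    wu = kernel.weights * u
    q = (1 - kernel.rho) * float(wu @ wu) + kernel.rho * float(wu.sum()) ** 2
    return max(q, 0.0)


def null_eigenvalues(
    residuals: np.ndarray,
    scores: CenteredScores,
    kernel: KernelSpec,
    covariance: str = "mendelian",
) -> np.ndarray:
    """Eigenvalue weights of the null chi-square mixture of Q.

    V = Cov(S' r | Xp, Y) = sum_i r_i^2 v_i, with v_i the conditional
    covariance of trio i's score vector.  ``mendelian`` takes v_i diagonal
    (per-variant transmission variances, independent transmissions given
    parents — exact for variants in linkage equilibrium); ``empirical``
    uses the observed outer products s_i s_i' instead, appropriate for
    linked variants.  Returns eigenvalues of W R_rho W V, clipped at zero
    and truncated below 1e-10 of the maximum.
    """
    r = np.asarray(residuals, dtype=float)
    r2 = r**2
    wrw = kernel.wrw()
    if covariance == "mendelian":
        v_diag = r2 @ scores.variances  # (m,)
        sqrt_v = np.sqrt(np.maximum(v_diag, 0.0))
        B = wrw * np.outer(sqrt_v, sqrt_v)
    elif covariance == "empirical":
        V = scores.scores.T @ (r2[:, None] * scores.scores)
        evals, evecs = np.linalg.eigh(V)
        evals = np.maximum(evals, 0.0)
        sqrt_V = (evecs * np.sqrt(evals)) @ evecs.T
        B = sqrt_V @ wrw @ sqrt_V
    else:
        raise ValueError(f"unknown covariance estimator {covariance!r}")
    lam = np.linalg.eigvalsh(B)
    lam = np.maximum(lam, 0.0)
    lmax = lam.max() if lam.size else 0.0
    if lmax == 0.0:
        return np.array([0.0])
    return np.sort(lam[lam > EIGEN_TRUNCATION * lmax])[::-1]


def _phi(u: float, lam: np.ndarray) -> float:
    return 0.5 * float(np.sum(np.arctan(lam * u)))


def _inv_urho(u: float, lam: np.ndarray) -> float:
    return float(np.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2))) / u)


def pvalue_cf_inversion(q: float, lam: np.ndarray, accuracy: float = 1e-9) -> float:
    """P(sum_j lambda_j chi2_1 > q) by inversion of the characteristic function.

    Gil-Pelaez / Imhof-form integral

        p = 1/2 + (1/pi) int_0^inf sin(theta(u)) / (u rho(u)) du,
        theta(u) = 1/2 sum_j arctan(lambda_j u) - q u / 2,
        rho(u)   = prod_j (1 + lambda_j^2 u^2)^(1/4).

    The head of the integral (u <= 1) is smooth and handled by ordinary
    adaptive quadrature; the oscillatory tail is split via
    sin(theta) = sin(phi) cos(qu/2) - cos(phi) sin(qu/2) and integrated
    with Fourier-weighted quadrature, which extrapolates over cycles and
    keeps the slowly decaying tail accurate even for a single component.
    Raises CFInversionError when the quadrature error estimate or the
    resulting probability is unusable; callers fall back to moment
    matching.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    q = float(q)

    def head(u: float) -> float:
        return np.sin(_phi(u, lam) - 0.5 * q * u) * _inv_urho(u, lam)

    def tail_sin_phi(u: float) -> float:
        return np.sin(_phi(u, lam)) * _inv_urho(u, lam)

    def tail_cos_phi(u: float) -> float:
        return np.cos(_phi(u, lam)) * _inv_urho(u, lam)

    cut = 1.0 / max(np.sqrt(lam.max()), 1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        i_head, e_head = integrate.quad(head, 0.0, cut, limit=200, epsabs=accuracy * 0.1,
                                        epsrel=1e-10)
        if q > 0:
            i_cos, e_cos = integrate.quad(tail_sin_phi, cut, np.inf, weight="cos",
                                          wvar=0.5 * q, limlst=200, limit=200,
                                          epsabs=accuracy * 0.1)
            i_sin, e_sin = integrate.quad(tail_cos_phi, cut, np.inf, weight="sin",
                                          wvar=0.5 * q, limlst=200, limit=200,
                                          epsabs=accuracy * 0.1)
            integral = i_head + i_cos - i_sin
            abserr = e_head + e_cos + e_sin
        else:
            i_tail, e_tail = integrate.quad(head, cut, np.inf, limit=500,
                                            epsabs=accuracy * 0.1, epsrel=1e-10)
            integral = i_head + i_tail
            abserr = e_head + e_tail
    p = 0.5 + integral / np.pi
    if not np.isfinite(p) or abserr > max(accuracy * 10, 0.01 * abs(p)):
        raise CFInversionError(f"quadrature error {abserr:.2e} too large for p={p:.3e}")
    if p <= 0.0 or p >= 1.0 + 1e-8:
        raise CFInversionError(f"inversion returned p={p:.3e} outside (0, 1)")
    return min(p, 1.0)


def pvalue_moment_matching(q: float, lam: np.ndarray) -> float:
    """Liu-type moment matching of the chi-square mixture.

    The first cumulants of sum lambda_j chi2_1 are matched to a (possibly
    noncentral) scaled chi-square surrogate; exact when only one component
    is present.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2 * (df + 2 * delta))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(x, df, delta)
    else:
        p = stats.chi2.sf(x, df)
    return float(min(max(p, 0.0), 1.0))


def mixture_pvalue(q: float, lam: np.ndarray) -> tuple[float, str]:
    """CF inversion with automatic moment-matching fallback."""
    lam = np.asarray(lam, dtype=float)
    if np.all(lam <= 0):
        return 1.0, "degenerate"
    try:
        return pvalue_cf_inversion(q, lam), "cf_inversion"
    except CFInversionError:
        return pvalue_moment_matching(q, lam), "moment_matching"


@dataclass
class TestResult:
    """Outcome of one region-based test of H0: tau = 0."""

    gene: str
    trait: str
    method: str
    rho: float
    stratum: str
    n_trios: int
    n_variants: int
    statistic: float | None
    eigenvalues: np.ndarray | None
    p_value: float | None
    p_method: str
    hypothesis: str = "H0: tau=0"
    n_mendelian_errors: int = 0

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def _method_rho(method: str) -> float:
    if method == "skat":
        return 0.0
    if method == "burden":
        return 1.0
    if method.startswith("rho="):
        return float(method.split("=", 1)[1])
    raise ValueError(f"method must be 'skat', 'burden' or 'rho=<x>', got {method!r}")


def run_test(
    cohort: TrioCohort,
    trait: str,
    variants: list[str] | None = None,
    gene: str = "all",
    stratum: str = "all",
    method: str = "skat",
    weights: tuple[float, float] = (1.0, 25.0),
    maf_threshold: float = 0.05,
    trait_type: str | None = None,
    covariance: str = "mendelian",
) -> TestResult:
    """Run one family-based region test.

    Pipeline: restrict to the gene's variants, drop monomorphic/untyped
    variants, apply the MAF stratum filter, compute Beta weights from the
    parental MAFs of the retained variants, fit the null trait model,
    form the score statistic and its null mixture weights, and compute the
    p-value (CF inversion with moment-matching fallback).  An empty
    stratum yields an untestable result rather than an exception.
    """
    rho = _method_rho(method)
    g = cohort.genotypes if variants is None else cohort.genotypes.subset(variants)
    part = partition_variants(g, maf_threshold)
    if stratum == "rare":
        keep = part.rare
    elif stratum == "common":
        keep = part.common
    elif stratum == "all":
        keep = part.rare + part.common
    else:
        raise ValueError(f"stratum must be rare, common or all, got {stratum!r}")
    keep_set = set(keep)
    keep = [v for v in g.variant_ids if v in keep_set]  # preserve order

    base = dict(gene=gene, trait=trait, method=method, rho=rho, stratum=stratum,
                n_trios=cohort.n_trios)
    if not keep:
        return TestResult(**base, n_variants=0, statistic=None, eigenvalues=None,
                          p_value=None, p_method="untestable")

    g = g.subset(keep)
    freqs = g.parental_maf()
    w = transmission.beta_weights(freqs, *weights)

    Y = cohort.phenotypes.trait(trait)
    if trait_type is None:
        vals = set(np.unique(Y[~np.isnan(Y)]))
        trait_type = "dichotomous" if vals <= {0.0, 1.0} else "continuous"
    null = fit_null_model(Y, cohort.phenotypes.covariates, trait_type)

    scores = center_genotypes(g)
    kernel = KernelSpec(rho=rho, weights=w)
    q = compute_statistic(null.residuals, scores, kernel)
    lam = null_eigenvalues(null.residuals, scores, kernel, covariance=covariance)
    p, p_method = mixture_pvalue(q, lam)
    return TestResult(**base, n_variants=g.n_variants, statistic=q, eigenvalues=lam,
                      p_value=p, p_method=p_method,
                      n_mendelian_errors=scores.n_mendelian_errors)
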