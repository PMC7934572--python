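"""Mixed-model association scan with GRM random effect and BH-FDR control.

Model: y = Xβ₀ + g + e with g ~ N(0, σg²K) and e ~ N(0, σe²I); K is the
VanRaden genomic relationship matrix and X holds an intercept plus leading
ordination axes of the marker panel.  Variance components are estimated
once by REML under the null (the EMMAX/P3D approximation) via the spectral
decomposition of K, then reused for every marker: each marker is tested by
generalized least squares in the whitened space with a Wald χ²₁ statistic.
Genome-wide significance is controlled by Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .vcfio import GenotypePanel

__all__ = [
    "KinshipMatrix",
    "LMMFit",
    "AssociationResult",
    "compute_grm",
    "fit_null_lmm",
    "association_scan",
    "bh_fdr",
    "manhattan_table",
]


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix with sample ids."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        if k.shape != (len(self.sample_ids),) * 2:
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        self.matrix = (k + k.T) / 2.0

    def check_psd(self, tol: float = 1e-8) -> np.ndarray:
        evals = np.linalg.eigvalsh(self.matrix)
        if evals.min() < -tol * max(abs(evals.max()), 1.0):
            raise ValueError(f"kinship matrix not PSD: min eigenvalue {evals.min()}")
        return evals


@dataclass
class LMMFit:
    """Null-model REML fit: variance components and spectral cache."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    beta_fixed: np.ndarray
    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)

    @property
    def delta(self) -> float:
        """λ = σe²/σg² (∞ when σg² = 0)."""
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class AssociationResult:
    """Per-variant scan output plus the scan-level FDR decision."""

    table: pd.DataFrame  # chrom, pos, variant_id, beta, se, wald, p, flagged
    q: float | None = None
    threshold: float | None = None  # largest significant p, None when no hit

    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]


def compute_grm(panel: GenotypePanel) -> KinshipMatrix:
    """VanRaden method-1 GRM: K = ZZᵀ / (2·Σ p_j(1−p_j)).

    Requires a complete (imputed) dosage matrix; Z is the column-centered
    dosage matrix with p_j the observed alt-allele frequency.
    """
    d = panel.dosages
    if np.isnan(d).any():
        raise ValueError("GRM requires a complete (imputed) dosage matrix")
    if panel.n_variants < 2:
        raise ValueError("GRM requires at least 2 variants")
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all variants are monomorphic; GRM denominator is zero")
    z = d - 2.0 * p[None, :]
    return KinshipMatrix(list(panel.samples), (z @ z.T) / denom)


def _reml_neg_loglik(log10_delta, s, uy, ux):
    """−2·REML log-likelihood profile in δ = σe²/σg² (constants dropped)."""
    delta = 10.0 ** log10_delta
    w = 1.0 / (s + delta)
    n, p = ux.shape
    xtwx = ux.T @ (w[:, None] * ux)
    xtwy = ux.T @ (w * uy)
    beta = np.linalg.solve(xtwx, xtwy)
    r = uy - ux @ beta
    rss = float(np.sum(w * r * r))
    sigma_g2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma_g2)
        + np.sum(np.log(s + delta))
        + logdet_xtwx
        + (n - p)
    )
    return -ll, beta, sigma_g2


def fit_null_lmm(
    y: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    grid: int = 100,
    bounds: tuple[float, float] = (-5.0, 5.0),
) -> LMMFit:
    """REML fit of the null mixed model by 1-D search over log10(δ).

    The search is a bounded grid refined by Brent minimization to 1e-6 and
    is fully deterministic.  ``covariates`` (n × c, without intercept) are
    appended to an intercept column; a rank-deficient design is an error.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        x = np.hstack([x, np.asarray(covariates, dtype=float).reshape(n, -1)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    kinship.check_psd()

    s, u = np.linalg.eigh(kinship.matrix)
    s = np.clip(s, 0.0, None)
    uy = u.T @ y
    ux = u.T @ x

    lo, hi = bounds
    grid_pts = np.linspace(lo, hi, grid)
    vals = [_reml_neg_loglik(g, s, uy, ux)[0] for g in grid_pts]
    i = int(np.argmin(vals))
    a = grid_pts[max(i - 1, 0)]
    b = grid_pts[min(i + 1, grid - 1)]
    res = minimize_scalar(
        lambda g: _reml_neg_loglik(g, s, uy, ux)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best = res.x if res.fun <= vals[i] else grid_pts[i]
    nll, beta, sigma_g2 = _reml_neg_loglik(best, s, uy, ux)
    delta = 10.0 ** best
    sigma_e2 = sigma_g2 * delta
    return LMMFit(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        loglik=float(-nll),
        beta_fixed=beta,
        eigenvalues=s,
        eigenvectors=u,
    )


def association_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    fit: LMMFit | None = None,
    q: float | None = None,
) -> AssociationResult:
    """Per-marker Wald tests with variance components fixed from the null.

    Each marker is tested by GLS in the whitened space (rotate by K's
    eigenvectors, scale rows by (s_i·σg² + σe²)^−1/2 via δ), residualizing
    marker and phenotype against the fixed-effect design.  Markers with
    zero variance after whitening get p = 1 and a flag.  When ``q`` is
    given, BH-FDR significance at level q is attached.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if fit is None:
        fit = fit_null_lmm(y, covariates, kinship)
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        x = np.hstack([x, np.asarray(covariates, dtype=float).reshape(n, -1)])

    delta = fit.delta
    s, u = fit.eigenvalues, fit.eigenvectors
    if np.isinf(delta):  # σg²=0: weights collapse to OLS up to scale
        w = np.ones_like(s)
        resid_var = fit.sigma_e2
    else:
        w = 1.0 / np.sqrt(s + delta)
        resid_var = fit.sigma_g2

    ystar = w * (u.T @ y)
    xstar = w[:, None] * (u.T @ x)
    qmat, _ = np.linalg.qr(xstar)
    y_r = ystar - qmat @ (qmat.T @ ystar)

    gstar = w[:, None] * (u.T @ panel.dosages)
    g_r = gstar - qmat @ (qmat.T @ gstar)
    denom = np.sum(g_r * g_r, axis=0)

    flagged = denom < 1e-12
    safe = np.where(flagged, 1.0, denom)
    beta = (g_r.T @ y_r) / safe
    se = np.sqrt(resid_var / safe)
    wald = (beta / se) ** 2
    p = chi2.sf(wald, df=1)
    beta[flagged] = 0.0
    wald[flagged] = 0.0
    p[flagged] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"].values,
            "pos": panel.variants["pos"].values,
            "variant_id": panel.variant_ids().values,
            "beta": beta,
            "se": se,
            "wald": wald,
            "p": p,
            "flagged": flagged,
        }
    )
    result = AssociationResult(table=table)
    if q is not None:
        sig, thr = bh_fdr(table["p"].to_numpy(), q=q)
        table["significant"] = sig
        result.q = q
        result.threshold = thr
    else:
        table["significant"] = False
    return result


def bh_fdr(pvalues: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, float | None]:
    """Benjamini–Hochberg step-up at level q.

    Returns (boolean significance mask, p-value threshold).  The threshold
    is the largest p(i) with p(i) ≤ i·q/m; None when nothing is significant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return np.zeros(m, dtype=bool), None
    k = passing[-1]
    threshold = float(ranked[k])
    return p <= threshold, threshold


def manhattan_table(result: AssociationResult) -> pd.DataFrame:
    """Tidy per-variant table sorted by chrom then pos, with −log10(p)."""
    t = result.table.copy()
    t["neg_log10_p"] = -np.log10(t["p"])
    return t.sort_values(["chrom", "pos"], ignore_index=True)[
        ["chrom", "pos", "variant_id", "beta", "se", "p", "neg_log10_p", "significant"]
    ]
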