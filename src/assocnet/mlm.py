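"""EMMAX-style mixed-linear-model association scan and permutation thresholds.

The null model is y = Xb + u + e with u ~ N(0, var_g * K) and
e ~ N(0, var_e * I).  The variance ratio delta = var_e / var_g is profiled out
of the restricted likelihood on the eigenbasis of the covariate-projected
kinship (one eigendecomposition per (X, K) pair), maximized on a log grid with
golden-section refinement.  Per-marker tests then hold the variance components
fixed (the population-parameters-previously-determined approximation) and run
generalized least squares in the decorrelated basis, reporting a two-sided
Wald t P value with df = n - rank(X) - 1.

Permutation thresholds shuffle the phenotype, re-fit delta per shuffle (cheap
on the cached eigenbasis), re-scan, and take the empirical alpha-quantile of
the genome-wide minimum P value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, KinshipMatrix, GenotypeError

__all__ = [
    "NullModelFit",
    "AssocScan",
    "PermThreshold",
    "MixedModelGWAS",
    "fit_null_mlm",
    "gwas_scan",
    "derive_permutation_threshold",
    "genomic_inflation",
]

RIDGE = 1e-6
_DELTA_GRID = np.logspace(-5, 5, 100)


@dataclass
class NullModelFit:
    """Converged variance components of the kinship null model."""

    var_g: float
    var_e: float
    delta: float
    reml_loglik: float

    def __post_init__(self):
        if self.var_g < 0 or self.var_e < 0:
            raise GenotypeError("variance components must be >= 0")


@dataclass
class AssocScan:
    """Per-variant association results for one trait in one population context.

    ``table`` columns: id, chrom, pos, effect, se, p, tested.  Variants that
    are monomorphic in context carry tested=False and NaN statistics.
    """

    trait: str
    context: str
    table: pd.DataFrame
    n: int
    covariates: str = "intercept+3PC"

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def min_p(self) -> float:
        tested = self.table.loc[self.table["tested"], "p"]
        return float(tested.min()) if len(tested) else np.nan


@dataclass
class PermThreshold:
    """Permutation-derived genome-wide significance threshold."""

    trait: str
    n_perm: int
    minus_log10_minp: np.ndarray
    alpha: float
    threshold: float

    def __post_init__(self):
        self.minus_log10_minp = np.asarray(self.minus_log10_minp, dtype=float)
        if self.minus_log10_minp.size != self.n_perm:
            raise GenotypeError("min-P sample length must equal n_perm")


def _check_design(X: np.ndarray):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the caller
        r = np.linalg.qr(X, mode="r")
        bad = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max()))
        raise GenotypeError(f"covariate matrix is rank-deficient (columns {bad.tolist()})")


class MixedModelGWAS:
    """Reusable scan engine for one (genotypes, covariates, kinship) context.

    Caches the kinship eigendecomposition and the rotated genotype matrix so
    that many traits or permutations can be scanned cheaply.

    Parameters
    ----------
    G : GenotypeMatrix
        Complete (imputed) genotypes; variants already QC-filtered.
    X : ndarray (n, c), optional
        Fixed-effect design including the intercept.  Defaults to intercept
        plus the first ``n_pcs`` genotype principal components.
    K : KinshipMatrix or ndarray, optional
        Defaults to simple-matching kinship computed from ``G``.
    """

    def __init__(self, G: GenotypeMatrix, X=None, K=None, n_pcs: int = 3, ridge: float = RIDGE):
        from .genotypes import genotype_pca, kinship_simple_matching

        self.G = G
        n = G.n_accessions
        if np.isnan(G.dosages).any():
            raise GenotypeError("scan requires complete genotypes; impute first")
        if K is None:
            K = kinship_simple_matching(G)
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        if Kv.shape != (n, n):
            raise GenotypeError("kinship shape does not match accession count")
        if X is None:
            pcs = genotype_pca(G, n_components=n_pcs) if n_pcs > 0 else np.empty((n, 0))
            X = np.column_stack([np.ones(n), pcs])
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise GenotypeError("covariate rows must match accession count")
        _check_design(X)
        self.X = X
        self.n = n
        self.c = X.shape[1]

        Kr = Kv + ridge * np.eye(n)
        # full rotation for the scan
        d, U = np.linalg.eigh(Kr)
        self._d = np.maximum(d, 0.0)
        self._U = U
        self._UX = U.T @ X
        self._UG = U.T @ G.dosages
        # projected eigenbasis for REML in delta
        Q, _ = np.linalg.qr(X)
        SKS = Kr - Q @ (Q.T @ Kr) - (Kr @ Q) @ Q.T + Q @ (Q.T @ Kr @ Q) @ Q.T
        xi, Up = np.linalg.eigh((SKS + SKS.T) / 2.0)
        keep = np.argsort(xi)[::-1][: n - self.c]
        self._xi = np.maximum(xi[keep], 0.0)
        self._Up = Up[:, keep]
        # in-context polymorphism
        self._poly = G.dosages.std(axis=0) > 0

    # -- REML ------------------------------------------------------------
    def _reml_ll(self, log_delta: float, eta2: np.ndarray) -> float:
        delta = np.exp(log_delta)
        q = self.n - self.c
        denom = self._xi + delta
        s = float(np.sum(eta2 / denom))
        return 0.5 * (q * (np.log(q / (2 * np.pi)) - 1.0 - np.log(s)) - np.sum(np.log(denom)))

    def fit_null(self, y) -> NullModelFit:
        """Profile the restricted likelihood over delta = var_e / var_g."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise GenotypeError("phenotype length mismatch")
        if not np.isfinite(y).all():
            raise GenotypeError("non-finite phenotype values")
        eta2 = (self._Up.T @ y) ** 2
        grid = np.log(_DELTA_GRID)
        ll = np.array([self._reml_ll(g, eta2) for g in grid])
        if not np.isfinite(ll).any():
            raise GenotypeError("restricted likelihood non-finite on the whole grid")
        k = int(np.nanargmax(ll))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        # golden-section refinement to relative tolerance 1e-6
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        x1 = b - gr * (b - a)
        x2 = a + gr * (b - a)
        f1, f2 = self._reml_ll(x1, eta2), self._reml_ll(x2, eta2)
        while (b - a) > 1e-6 * max(1.0, abs(a) + abs(b)):
            if f1 < f2:
                a, x1, f1 = x1, x2, f2
                x2 = a + gr * (b - a)
                f2 = self._reml_ll(x2, eta2)
            else:
                b, x2, f2 = x2, x1, f1
                x1 = b - gr * (b - a)
                f1 = self._reml_ll(x1, eta2)
        log_delta = (a + b) / 2.0
        delta = float(np.exp(log_delta))
        q = self.n - self.c
        var_g = float(np.sum(eta2 / (self._xi + delta)) / q)
        var_e = delta * var_g
        return NullModelFit(var_g, var_e, delta, self._reml_ll(log_delta, eta2))

    # -- scan ------------------------------------------------------------
    def _weights(self, fit: NullModelFit) -> np.ndarray:
        v = fit.var_g * self._d + fit.var_e
        if fit.var_g == 0 and fit.var_e == 0:
            raise GenotypeError("degenerate variance components")
        if fit.var_g == 0:
            return np.full(self.n, 1.0 / np.sqrt(fit.var_e))
        return 1.0 / np.sqrt(v)

    def scan(self, y, fit: NullModelFit | None = None, trait: str = "trait", context: str = "full_population") -> AssocScan:
        """GLS effect, SE and two-sided Wald-t P value per variant."""
        y = np.asarray(y, dtype=float)
        if fit is None:
            fit = self.fit_null(y)
        w = self._weights(fit)
        ys = w * (self._U.T @ y)
        Xs = w[:, None] * self._UX
        Gs = w[:, None] * self._UG
        Q, _ = np.linalg.qr(Xs)
        yr = ys - Q @ (Q.T @ ys)
        Gr = Gs - Q @ (Q.T @ Gs)
        gtg = np.einsum("ij,ij->j", Gr, Gr)
        gty = Gr.T @ yr
        yty = float(yr @ yr)
        df = self.n - self.c - 1
        if df < 1:
            raise GenotypeError("not enough residual degrees of freedom")
        tested = self._poly & (gtg > 1e-12 * max(yty, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(tested, gty / gtg, np.nan)
            sse = yty - np.where(tested, gty**2 / gtg, 0.0)
            sigma2 = np.maximum(sse, 0.0) / df
            se = np.sqrt(np.where(tested, sigma2 / gtg, np.nan))
            tval = beta / se
        p = 2.0 * stats.t.sf(np.abs(tval), df)
        p = np.where(tested, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
        table = pd.DataFrame(
            {
                "id": self.G.ids,
                "chrom": [v.chrom for v in self.G.variants],
                "pos": [v.pos for v in self.G.variants],
                "effect": beta,
                "se": se,
                "p": p,
                "tested": tested,
            }
        )
        return AssocScan(trait=trait, context=context, table=table, n=self.n,
                         covariates=f"custom({self.c} cols)")

    # -- permutation threshold -------------------------------------------
    def permutation_threshold(self, y, n_perm: int = 1000, alpha: float = 0.05,
                              seed: int = 0, trait: str = "trait") -> PermThreshold:
        """Empirical genome-wide threshold from phenotype permutations.

        Each permutation breaks the genotype-phenotype link, re-fits the null
        variance components, re-scans every variant, and records the
        genome-wide minimum P; the threshold is the alpha-quantile of that
        min-P sample.
        """
        if n_perm < 20:
            warnings.warn("n_perm < 20: permutation quantile is unstable")
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(seed)
        minp = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(y)
            fit = self.fit_null(yp)
            minp[b] = self.scan(yp, fit=fit).min_p()
        thr = float(np.quantile(minp, alpha))
        return PermThreshold(trait, n_perm, -np.log10(minp), alpha, thr)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_null_mlm(y, X, K) -> NullModelFit:
    """REML fit of the kinship null model for a phenotype and covariates."""
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = Kv.shape[0]
    dummy = GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [],
        np.empty((n, 0)),
    )
    engine = MixedModelGWAS(dummy, X=np.asarray(X, float), K=Kv)
    return engine.fit_null(y)


def gwas_scan(y, G: GenotypeMatrix, X, fit: NullModelFit, K=None, trait="trait",
              context="full_population") -> AssocScan:
    """One-shot scan with variance components held fixed from ``fit``."""
    engine = MixedModelGWAS(G, X=X, K=K)
    return engine.scan(y, fit=fit, trait=trait, context=context)


def derive_permutation_threshold(y, G: GenotypeMatrix, X, K, n_perm: int = 1000,
                                 alpha: float = 0.05, seed: int = 0) -> PermThreshold:
    engine = MixedModelGWAS(G, X=X, K=K)
    return engine.permutation_threshold(y, n_perm=n_perm, alpha=alpha, seed=seed)


def genomic_inflation(pvals) -> float:
    """Genomic-inflation factor lambda: median test chi2 over its null median."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise GenotypeError("no finite P values")
    chi2 = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
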