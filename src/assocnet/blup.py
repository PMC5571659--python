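"""Cross-environment BLUP, heritability, trait typing, trait correlations.

The multi-environment model is

    y_ijk = mu + env_j + line_i + (line x env)_ij + e_ijk

with environments fixed and line, line-by-environment and residual terms
random.  Variance components are estimated by EM-REML on the mixed-model
equations; line predictions (BLUPs) solve the equations at the converged
components and are the environment-free measure of line performance used as
the association phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeError, KinshipMatrix

__all__ = [
    "BlupResult",
    "TraitMeta",
    "MultiEnvBLUP",
    "fit_multienv_blup",
    "estimate_h2",
    "classify_trait_type",
    "trait_correlations",
    "read_phenotypes",
    "write_phenotypes",
    "validate_phenotypes",
]

PHENO_COLUMNS = ["accession", "environment", "replicate", "trait", "value"]


def validate_phenotypes(tbl: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in tbl.columns]
    if missing:
        raise GenotypeError(f"phenotype table lacks column(s) {missing}")
    keys = tbl[["accession", "environment", "replicate", "trait"]]
    if keys.duplicated().any():
        raise GenotypeError("duplicate (accession, environment, replicate, trait) keys")
    return tbl


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def write_phenotypes(tbl: pd.DataFrame, path) -> None:
    validate_phenotypes(tbl).to_csv(path, sep="\t", index=False)


@dataclass
class TraitMeta:
    trait: str
    declared_type: str | None = None  # binary | normal_quant | skewed_quant | binary_like_quant
    favorable_allele_map: dict | None = None


@dataclass
class BlupResult:
    blups: pd.Series  # per-accession line-effect predictions
    var_line: float
    var_gxe: float
    var_resid: float
    fixed_effects: pd.Series  # mean + per-environment effects
    converged: bool
    n_iter: int


class MultiEnvBLUP:
    """EM-REML fit of the two-random-component multi-environment model.

    Fitted attributes: ``blups_``, ``var_line_``, ``var_gxe_``, ``var_resid_``,
    ``fixed_effects_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 average_replicates: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.average_replicates = average_replicates

    def fit(self, tbl: pd.DataFrame, trait: str) -> "MultiEnvBLUP":
        validate_phenotypes(tbl)
        sub = tbl[(tbl["trait"] == trait) & tbl["value"].notna()].copy()
        if sub.empty:
            raise GenotypeError(f"no records for trait {trait!r}")
        sub["value"] = pd.to_numeric(sub["value"])
        if self.average_replicates:
            sub = (
                sub.groupby(["accession", "environment"], as_index=False)["value"].mean()
            )
        lines = sorted(sub["accession"].unique())
        envs = sorted(sub["environment"].unique())
        if len(lines) < 2:
            raise GenotypeError("need >= 2 accessions")
        y = sub["value"].to_numpy(dtype=float)
        n = y.size
        li = pd.Categorical(sub["accession"], categories=lines).codes
        ei = pd.Categorical(sub["environment"], categories=envs).codes
        q1 = len(lines)
        # fixed: intercept + environment contrasts (first env as reference)
        X = np.zeros((n, len(envs)))
        X[:, 0] = 1.0
        for j in range(1, len(envs)):
            X[ei == j, j] = 1.0
        p = np.linalg.matrix_rank(X)

        Z1 = np.zeros((n, q1))
        Z1[np.arange(n), li] = 1.0
        use_gxe = len(envs) > 1
        if use_gxe:
            cells = li * len(envs) + ei
            used = np.unique(cells)
            remap = {c: k for k, c in enumerate(used)}
            q2 = len(used)
            Z2 = np.zeros((n, q2))
            Z2[np.arange(n), [remap[c] for c in cells]] = 1.0
            Z = np.hstack([Z1, Z2])
        else:
            q2 = 0
            Z = Z1

        W = np.hstack([X, Z])
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)
        nf = X.shape[1]

        vy = y.var(ddof=1) if n > 1 else 1.0
        s1 = s2 = se = max(vy / 3.0, 1e-8)
        if not use_gxe:
            s2 = 0.0
        converged = False
        it = 0
        sol = np.zeros(W.shape[1])
        for it in range(1, self.max_iter + 1):
            C = WtW.copy()
            idx1 = slice(nf, nf + q1)
            C[idx1, idx1] += np.eye(q1) * (se / s1)
            if use_gxe:
                idx2 = slice(nf + q1, nf + q1 + q2)
                C[idx2, idx2] += np.eye(q2) * (se / s2)
            Cinv = np.linalg.pinv(C)
            sol = Cinv @ Wty
            u1 = sol[idx1]
            se_new = (yty - float(sol @ Wty)) / (n - p)
            se_new = max(se_new, 1e-12)
            tr1 = float(np.trace(Cinv[idx1, idx1]))
            s1_new = (float(u1 @ u1) + se_new * tr1) / q1
            if use_gxe:
                u2 = sol[idx2]
                tr2 = float(np.trace(Cinv[idx2, idx2]))
                s2_new = (float(u2 @ u2) + se_new * tr2) / q2
            else:
                s2_new = 0.0
            delta = max(abs(s1_new - s1), abs(s2_new - s2), abs(se_new - se))
            scale = max(s1, s2, se, 1e-12)
            s1, s2, se = max(s1_new, 1e-12), s2_new, se_new
            if delta / scale < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"EM-REML did not converge in {self.max_iter} iterations")

        # final solve of the mixed-model equations at the stored components
        C = WtW.copy()
        C[idx1, idx1] += np.eye(q1) * (se / s1)
        if use_gxe:
            C[idx2, idx2] += np.eye(q2) * (se / s2)
        sol = np.linalg.pinv(C) @ Wty

        self.var_line_ = float(s1)
        self.var_gxe_ = float(s2)
        self.var_resid_ = float(se)
        self.blups_ = pd.Series(sol[nf:nf + q1], index=lines, name=trait)
        self.fixed_effects_ = pd.Series(sol[:nf], index=["mean"] + [f"env:{e}" for e in envs[1:]])
        self.converged_ = converged
        self.n_iter_ = it
        self.n_obs_ = n
        return self

    def result(self) -> BlupResult:
        return BlupResult(
            blups=self.blups_,
            var_line=self.var_line_,
            var_gxe=self.var_gxe_,
            var_resid=self.var_resid_,
            fixed_effects=self.fixed_effects_,
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


def fit_multienv_blup(tbl: pd.DataFrame, trait: str, tol: float = 1e-6,
                      max_iter: int = 500) -> BlupResult:
    """Cross-environment BLUP of line performance for one trait."""
    return MultiEnvBLUP(tol=tol, max_iter=max_iter).fit(tbl, trait).result()


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def estimate_h2(y, K: KinshipMatrix) -> float:
    """Narrow-sense heritability from the kinship mixed model.

    The kinship is centered and trace-rescaled (Gower normalization) before
    the REML fit so that var_g is on the per-individual phenotypic scale; the
    returned value is var_g / (var_g + var_e).
    """
    from .mlm import fit_null_mlm

    y = np.asarray(y, dtype=float)
    if y.var() <= 0:
        raise GenotypeError("phenotype has zero variance")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = Kv.shape[0]
    if y.size != n:
        raise GenotypeError("phenotype not aligned to kinship")
    P = np.eye(n) - np.full((n, n), 1.0 / n)
    scale = np.trace(P @ Kv @ P) / (n - 1)
    if scale <= 0:
        raise GenotypeError("kinship has no off-mean structure")
    X = np.ones((n, 1))
    fit = fit_null_mlm(y, X, Kv / scale)
    return fit.var_g / (fit.var_g + fit.var_e)


# ---------------------------------------------------------------------------
# trait typing and correlations
# ---------------------------------------------------------------------------

def classify_trait_type(values, binary_like_cutoff: float = 0.8,
                        skew_cutoff: float = 1.0) -> str:
    """Assign one of the four distribution classes used for thresholds.

    binary: exactly two distinct values; binary_like_quant: one modal value
    holds more than ``binary_like_cutoff`` of observations; skewed_quant:
    |sample skewness| > ``skew_cutoff``; else normal_quant.
    """
    vals = pd.Series(values).dropna()
    if len(vals) < 20:
        raise GenotypeError("need >= 20 non-missing observations to classify")
    uniq = vals.unique()
    if len(uniq) == 1:
        raise GenotypeError("constant trait is unclassifiable")
    if len(uniq) == 2:
        return "binary"
    num = pd.to_numeric(vals)
    modal_share = num.value_counts(normalize=True).iloc[0]
    if modal_share > binary_like_cutoff:
        return "binary_like_quant"
    if abs(stats.skew(num.to_numpy())) > skew_cutoff:
        return "skewed_quant"
    return "normal_quant"


def trait_correlations(values: pd.DataFrame, traits=None, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between traits.

    ``values`` is either a wide accession x trait frame, or a long phenotype
    table (then per-accession means are used).  Binary traits must already be
    0/1 encoded.  Pairs with fewer than ``min_pairs`` complete observations
    are flagged missing (NaN).
    """
    if set(PHENO_COLUMNS) <= set(values.columns):
        wide = values.pivot_table(index="accession", columns="trait", values="value",
                                  aggfunc="mean")
    else:
        wide = values
    if traits is not None:
        wide = wide[list(traits)]
    corr = wide.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
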