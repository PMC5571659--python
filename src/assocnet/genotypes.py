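"""Genotype containers, I/O, QC, imputation, kinship, PCA, and pairwise LD.

Dosages count copies of the alternate allele (0/1/2) with ``numpy.nan`` for
missing calls.  The panel is assumed to come from a selfing species, so
heterozygous calls are rare but are carried through as dosage 1.  Coordinates
are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "KinshipMatrix",
    "LdValue",
    "GenotypeError",
    "LdUndefinedError",
    "ImputationError",
    "load_genotypes",
    "write_genotypes_tsv",
    "filter_variants",
    "impute_knn",
    "KNNGenotypeImputer",
    "kinship_simple_matching",
    "GenotypePCA",
    "genotype_pca",
    "ld_r2",
    "pairwise_r2",
]


class GenotypeError(ValueError):
    """Malformed genotype input or violated precondition."""


class LdUndefinedError(GenotypeError):
    """LD requested for a monomorphic dosage vector."""


class ImputationError(GenotypeError):
    """Imputation impossible (e.g. a variant missing in every accession)."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with a 1-based coordinate."""

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "C"
    id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise GenotypeError(f"variant position must be >= 1, got {self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}_{self.pos}")


@dataclass
class GenotypeMatrix:
    """Accessions x variants dosage matrix.

    Parameters
    ----------
    accessions : list of str
        Ordered, unique sample labels.
    variants : list of VariantRecord
        Ordered variant records; within each chromosome positions must be
        strictly increasing.
    dosages : ndarray of shape (n_accessions, n_variants)
        Alternate-allele dosages in {0, 1, 2}; missing calls are ``nan``.
    """

    accessions: list
    variants: list
    dosages: np.ndarray

    def __post_init__(self):
        self.accessions = list(self.accessions)
        self.variants = list(self.variants)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.accessions) or m != len(self.variants):
            raise GenotypeError(
                f"dosage grid {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.variants)} variants"
            )
        if len(set(self.accessions)) != n:
            raise GenotypeError("duplicate accession labels")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise GenotypeError("duplicate variant ids")
        prev = {}
        for v in self.variants:
            if v.chrom in prev and v.pos <= prev[v.chrom]:
                raise GenotypeError(
                    f"variants on {v.chrom} not sorted by strictly increasing pos at {v.id}"
                )
            prev[v.chrom] = v.pos
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise GenotypeError("dosages must be in {0, 1, 2} or nan")
        self._index = {vid: j for j, vid in enumerate(ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def ids(self) -> list:
        return [v.id for v in self.variants]

    def variant_index(self, vid: str) -> int:
        try:
            return self._index[vid]
        except KeyError:
            raise GenotypeError(f"unknown variant id {vid!r}") from None

    def dosage(self, vid: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(vid)]

    # -- per-variant summaries -------------------------------------------
    def alt_freq(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    # -- subsetting -------------------------------------------------------
    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.accessions, [self.variants[j] for j in idx], self.dosages[:, idx]
        )

    def take_accessions(self, labels) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        rows = [pos[a] for a in labels]
        return GenotypeMatrix(list(labels), self.variants, self.dosages[rows])


@dataclass
class KinshipMatrix:
    """Square symmetric pairwise-similarity matrix with unit diagonal."""

    accessions: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise GenotypeError("kinship shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GenotypeError("kinship must be symmetric")
        if self.values.min() < -1e-10 or self.values.max() > 1 + 1e-10:
            raise GenotypeError("kinship values must lie in [0, 1]")


@dataclass(frozen=True)
class LdValue:
    id_a: str
    id_b: str
    r2: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _load_vcf(path, on_multiallelic="skip"):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeError("duplicate sample labels in VCF header")
    variants, cols = [], []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if on_multiallelic == "skip":
                n_skipped += 1
                continue
            raise GenotypeError(
                f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} (record {i + 1})"
            )
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples))
        for s, g in enumerate(gts):
            a = [x for x in g[:-1] if x >= 0]
            col[s] = np.nan if len(a) < 2 else float(sum(a))
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID or "")
        )
        cols.append(col)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP record(s)")
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosages)


def _parse_variant_id(vid: str) -> VariantRecord:
    # dosage-TSV ids follow the "Chr01_12345" convention
    chrom, _, pos = vid.rpartition("_")
    if not chrom or not pos.isdigit():
        raise GenotypeError(f"cannot parse chrom/pos from variant id {vid!r}")
    return VariantRecord(chrom, int(pos), id=vid)


def _load_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        raise GenotypeError("duplicate sample labels in dosage TSV")
    variants = [_parse_variant_id(str(c)) for c in df.columns]
    return GenotypeMatrix([str(a) for a in df.index], variants, df.to_numpy(dtype=float))


def load_genotypes(path, format=None, on_multiallelic="skip") -> GenotypeMatrix:
    """Load a GenotypeMatrix from a VCF or a dosage TSV.

    ``format`` is inferred from the file suffix when not given.  VCF records
    that are not biallelic SNPs are skipped (with a warning) or rejected
    depending on ``on_multiallelic`` ("skip" | "error").
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _load_vcf(path, on_multiallelic=on_multiallelic)
    if format == "tsv":
        return _load_tsv(path)
    raise GenotypeError(f"unknown genotype format {format!r}")


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    """Write the dosage-TSV dialect: header = variant ids, rows = accessions."""
    df = pd.DataFrame(G.dosages, index=G.accessions, columns=G.ids)
    # keep integer dosages readable; missing as NA
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f", index_label="accession")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_variants(G: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.1) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and missing rate < ``miss_max``."""
    keep = (G.maf() >= maf_min - 1e-12) & (G.missing_rate() < miss_max)
    return G.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------

def _pairwise_allele_distance(dosages: np.ndarray):
    """Mean |g_i - g_j| / 2 over co-observed variants, via indicator matmuls.

    Returns (D, C): the distance matrix and the co-observed counts.
    """
    M = (~np.isnan(dosages)).astype(float)
    I0 = np.where(np.nan_to_num(dosages) == 0, 1.0, 0.0) * M
    I1 = np.where(np.nan_to_num(dosages, nan=-1) == 1, 1.0, 0.0)
    I2 = np.where(np.nan_to_num(dosages) == 2, 1.0, 0.0)
    C = M @ M.T
    cross02 = I0 @ I2.T
    cross01 = I0 @ I1.T
    cross12 = I1 @ I2.T
    S = 2.0 * (cross02 + cross02.T) + (cross01 + cross01.T + cross12 + cross12.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = S / (2.0 * C)
    return D, C


class KNNGenotypeImputer:
    """k-nearest-neighbour dosage imputation.

    The accession-accession distance is the mean of |g_i - g_j| / 2 over
    variants observed in both accessions; pairs of missing cells are ignored.
    Each missing cell is replaced by the rounded mean dosage of the ``k``
    nearest accessions that carry an observed call at that variant, with
    neighbour-distance ties broken by accession order.  Observed cells are
    never modified.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise GenotypeError("k must be >= 1")
        self.k = k

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        if G.n_accessions < self.k + 1:
            raise GenotypeError(
                f"need at least k+1={self.k + 1} accessions, have {G.n_accessions}"
            )
        X = G.dosages.copy()
        miss_mask = np.isnan(X)
        if not miss_mask.any():
            return replace(G, dosages=X)
        all_missing = miss_mask.all(axis=0)
        if all_missing.any():
            bad = [G.variants[j].id for j in np.flatnonzero(all_missing)]
            raise ImputationError(f"variant(s) missing in all accessions: {bad}")
        D, C = _pairwise_allele_distance(X)
        # accessions with no co-observed variants are maximally distant
        D = np.where(C > 0, D, np.inf)
        np.fill_diagonal(D, np.inf)
        order = np.arange(G.n_accessions)
        for j in np.flatnonzero(miss_mask.any(axis=0)):
            observed = np.flatnonzero(~miss_mask[:, j])
            for i in np.flatnonzero(miss_mask[:, j]):
                cand = observed
                rank = np.lexsort((order[cand], D[i, cand]))
                nn = cand[rank[: self.k]]
                mean = X[nn, j].mean()
                X[i, j] = np.clip(np.floor(mean + 0.5), 0.0, 2.0)
        return replace(G, dosages=X)


def impute_knn(G: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    return KNNGenotypeImputer(k=k).transform(G)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship_simple_matching(G: GenotypeMatrix) -> KinshipMatrix:
    """Simple-matching kinship: entry(i,j) = mean over variants of 1 - |g_i - g_j|/2.

    Requires a complete (imputed) matrix.  Identical rows score 1; fully
    opposite homozygotes score 0.
    """
    if np.isnan(G.dosages).any():
        raise GenotypeError("kinship requires a complete matrix; impute first")
    if G.n_accessions < 2:
        raise GenotypeError("kinship needs >= 2 accessions")
    X = G.dosages - 1.0  # in {-1, 0, 1}
    m = G.n_variants
    sq = (X * X).sum(axis=1)
    # sum (x_i - x_j)^2 = |x_i|^2 + |x_j|^2 - 2 x_i.x_j
    G2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    # |a-b| = (a-b)^2 except for the (-1, 1) pairs where (a-b)^2 = 4 but |a-b| = 2
    Ineg = (X < -0.5).astype(float)
    Ipos = (X > 0.5).astype(float)
    opp = Ineg @ Ipos.T
    abssum = G2 - 2.0 * (opp + opp.T)
    K = 1.0 - abssum / (2.0 * m)
    K = np.clip((K + K.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(list(G.accessions), K)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class GenotypePCA:
    """PCA of the centered dosage matrix (scikit-learn backed).

    Fitted attributes
    -----------------
    scores_ : ndarray (n_accessions, n_components)
        Component scores ordered by decreasing explained variance.
    explained_variance_ratio_ : ndarray (n_components,)
    """

    def __init__(self, n_components: int = 3, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, G: GenotypeMatrix) -> "GenotypePCA":
        from sklearn.decomposition import PCA

        X = np.asarray(G.dosages, dtype=float)
        if np.isnan(X).any():
            raise GenotypeError("PCA requires a complete matrix; impute first")
        Xc = X - X.mean(axis=0)
        if self.scale:
            sd = Xc.std(axis=0)
            Xc = Xc / np.where(sd > 0, sd, 1.0)
        rank = min(Xc.shape)
        if self.n_components > rank:
            raise GenotypeError(
                f"n_components={self.n_components} exceeds rank bound {rank}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="auto", random_state=0)
        self.scores_ = pca.fit_transform(Xc)
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.components_ = pca.components_
        return self

    def fit_transform(self, G: GenotypeMatrix) -> np.ndarray:
        return self.fit(G).scores_


def genotype_pca(G: GenotypeMatrix, n_components: int = 3, scale: bool = False) -> np.ndarray:
    """Per-accession principal-component scores of the centered dosages."""
    return GenotypePCA(n_components=n_components, scale=scale).fit_transform(G)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _r2_vectors(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    x, y = a[ok], b[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        raise LdUndefinedError("monomorphic dosage vector; r2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2(G: GenotypeMatrix, a: str, b: str) -> LdValue:
    """Squared Pearson correlation of dosages over jointly observed accessions."""
    return LdValue(a, b, _r2_vectors(G.dosage(a), G.dosage(b)))


def pairwise_r2(G: GenotypeMatrix, ids) -> np.ndarray:
    """Pairwise r2 grid for a list of variant ids (pairwise-complete)."""
    ids = list(ids)
    k = len(ids)
    out = np.ones((k, k))
    vecs = [G.dosage(v) for v in ids]
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = _r2_vectors(vecs[i], vecs[j])
        # a variant with itself: defined only if polymorphic
        _r2_vectors(vecs[i], vecs[i])
    return out
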