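"""Synthetic genotype panels and phenotypes.

The panel generator emulates a selfing-species diversity collection: a few
hundred inbred accessions drawn from diverged subpopulations, genotypes built
from a small pool of founder haplotypes per LD block (so nearby variants are
strongly correlated), a minor-allele-frequency floor, and near-zero
heterozygosity.  Trait generators layer additive, background-conditional
(epistatic) and environment/GxE effects on top, with residual noise scaled so
the realized sample heritability hits its target exactly.

All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VariantRecord, GenotypeError

__all__ = [
    "PanelConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_additive_trait",
    "simulate_epistatic_trait",
    "simulate_multienv",
]

# founder haplotypes per subpopulation per LD block; a small pool mimics the
# limited local haplotype diversity of selfing germplasm collections
_N_FOUNDERS = 6
# per-cell probability of re-drawing the allele from the subpopulation
# frequency, breaking perfect within-block haplotype identity
_HAP_NOISE = 0.02
_BP_SPACING = 50_000


@dataclass(frozen=True)
class PanelConfig:
    """Study-condition defaults for the synthetic diversity panel.

    Defaults emulate the analysed collection: 809 accessions, 20,000
    genome-wide SNPs on 20 chromosomes, three subpopulations at
    Balding-Nichols-level divergence 0.10, LD blocks of 10 variants,
    MAF >= 0.05, heterozygosity ~0.17%.
    """

    n_accessions: int = 809
    n_variants: int = 20_000
    n_chromosomes: int = 20
    n_subpops: int = 3
    fst_like_divergence: float = 0.10
    ld_block_length: int = 10
    maf_floor: float = 0.05
    het_rate: float = 0.0017
    seed: int = 0

    def __post_init__(self):
        for name in ("n_accessions", "n_variants", "n_chromosomes", "n_subpops", "ld_block_length"):
            if getattr(self, name) < 1:
                raise GenotypeError(f"{name} must be positive")
        for name in ("fst_like_divergence", "het_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise GenotypeError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.maf_floor < 0.5:
            raise GenotypeError("maf_floor must lie in [0, 0.5)")
        if self.n_chromosomes > self.n_variants:
            raise GenotypeError("more chromosomes than variants")


@dataclass
class SimTruth:
    """Ground truth of a simulated trait."""

    causal_ids: list
    effects: np.ndarray
    variance_explained: np.ndarray
    h2: float
    epistatic_pairs: list = field(default_factory=list)
    genetic_values: np.ndarray | None = None

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)


def _draw_freq(rng, size, lo, hi):
    """Ancestral allele frequencies from a U-shaped spectrum truncated to [lo, hi]."""
    p = rng.beta(0.8, 0.8, size=size)
    bad = (p < lo) | (p > hi)
    while bad.any():
        p[bad] = rng.beta(0.8, 0.8, size=int(bad.sum()))
        bad = (p < lo) | (p > hi)
    return p


def simulate_panel(cfg: PanelConfig) -> GenotypeMatrix:
    """Generate an inbred diversity panel with subpopulation structure and LD blocks."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_accessions, cfg.n_variants
    S, F, L = cfg.n_subpops, cfg.fst_like_divergence, cfg.ld_block_length

    # contiguous, near-equal subpopulation assignment
    subpop = (np.arange(n) * S) // n

    # chromosome sizes and variant records
    sizes = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    sizes[: m % cfg.n_chromosomes] += 1
    variants = []
    for c, sz in enumerate(sizes):
        chrom = f"Chr{c + 1:02d}"
        for k in range(sz):
            variants.append(VariantRecord(chrom, (k + 1) * _BP_SPACING))

    dosages = np.empty((n, m))
    start = 0
    for sz in sizes:
        stop = start + sz
        for b0 in range(start, stop, L):
            b1 = min(b0 + L, stop)
            _fill_block(rng, dosages, subpop, b0, b1, S, F, cfg.maf_floor)
        start = stop

    # sprinkle heterozygotes
    if cfg.het_rate > 0:
        het = rng.random((n, m)) < cfg.het_rate
        dosages[het] = 1.0

    return GenotypeMatrix([f"acc{i + 1:04d}" for i in range(n)], variants, dosages)


def _fill_block(rng, dosages, subpop, b0, b1, S, F, maf_floor):
    n = dosages.shape[0]
    w = b1 - b0
    assign = rng.integers(0, _N_FOUNDERS, size=n)
    p_anc = _draw_freq(rng, w, max(maf_floor, 0.01), 1 - max(maf_floor, 0.01))
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a, b, size=(S, w))
    else:
        p_sub = np.broadcast_to(p_anc, (S, w)).copy()
    haps = (rng.random((S, _N_FOUNDERS, w)) < p_sub[:, None, :]).astype(float)

    def build(cols):
        block = 2.0 * haps[subpop, assign][:, cols]
        noise = rng.random((n, len(cols))) < _HAP_NOISE
        redraw = 2.0 * (rng.random((n, len(cols))) < p_sub[subpop][:, cols])
        return np.where(noise, redraw, block)

    cols = np.arange(w)
    block = build(cols)
    # enforce the MAF floor by re-drawing failing variants' founder alleles
    for _ in range(20):
        p_hat = block.mean(axis=0) / 2.0
        fail = np.minimum(p_hat, 1 - p_hat) < maf_floor
        if not fail.any():
            break
        idx = np.flatnonzero(fail)
        p_new = rng.uniform(0.2, 0.5, size=idx.size)
        for s in range(S):
            p_sub[s, idx] = p_new
        haps[:, :, idx] = (
            rng.random((S, _N_FOUNDERS, idx.size)) < p_new[None, None, :]
        ).astype(float)
        block[:, idx] = build(idx)
    else:  # force the stragglers by flipping random accessions to the minor allele
        p_hat = block.mean(axis=0) / 2.0
        for j in np.flatnonzero(np.minimum(p_hat, 1 - p_hat) < maf_floor):
            minor = 2.0 if p_hat[j] < 0.5 else 0.0
            need = int(np.ceil(maf_floor * n)) + 1
            have = int((block[:, j] == minor).sum())
            if have < need:
                pool = np.flatnonzero(block[:, j] != minor)
                flip = rng.choice(pool, size=need - have, replace=False)
                block[flip, j] = minor
    dosages[:, b0:b1] = block


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _require_complete(G: GenotypeMatrix):
    if np.isnan(G.dosages).any():
        raise GenotypeError("trait simulation requires a complete genotype matrix")


def _exact_h2_noise(rng, gv, h2):
    """Residual noise orthogonal to the genetic value, scaled so the realized
    sample h2 (var(gv)/var(y)) equals the target exactly."""
    n = gv.size
    vg = gv.var()
    if vg <= 0:
        raise GenotypeError("genetic values have zero variance")
    if h2 >= 1.0:
        return np.zeros(n)
    e = rng.standard_normal(n)
    A = np.column_stack([np.ones(n), gv])
    e_perp = e - A @ np.linalg.lstsq(A, e, rcond=None)[0]
    c = np.sqrt(vg * (1.0 - h2) / (h2 * e_perp.var()))
    return c * e_perp


def _sample_causals(G, n_qtn, rng, max_r2=0.2):
    """Uniform draw of causal variants, constrained to pairwise dosage r2 < max_r2
    so that the per-causal marginal variance shares account for the whole h2."""
    maf = G.maf()
    candidates = np.flatnonzero(maf > 0)
    if n_qtn > candidates.size:
        raise GenotypeError(f"n_qtn={n_qtn} exceeds polymorphic variant count")
    order = rng.permutation(candidates)
    X = G.dosages
    chosen = []
    for j in order:
        x = X[:, j]
        ok = True
        for c in chosen:
            r = np.corrcoef(x, X[:, c])[0, 1]
            if r * r >= max_r2:
                ok = False
                break
        if ok:
            chosen.append(int(j))
            if len(chosen) == n_qtn:
                return np.array(chosen)
    raise GenotypeError("could not draw a low-LD causal set; panel too small")


def simulate_additive_trait(
    G: GenotypeMatrix,
    n_qtn: int,
    h2: float,
    effect_model: str = "geometric",
    seed: int = 0,
):
    """Additive trait from ``n_qtn`` causal panel variants at sample heritability ``h2``.

    ``effect_model`` is "geometric" (k-th effect proportional to 0.9**k, random
    signs — a mixture of major and minor QTNs) or "equal".
    """
    _require_complete(G)
    if n_qtn < 1:
        raise GenotypeError("n_qtn must be >= 1 for a heritable trait")
    if not 0.0 < h2 <= 1.0:
        raise GenotypeError("h2 must lie in (0, 1]")
    if effect_model not in ("geometric", "equal"):
        raise GenotypeError(f"unknown effect_model {effect_model!r}")
    rng = np.random.default_rng(seed)
    causal = _sample_causals(G, n_qtn, rng)
    base = 0.9 ** np.arange(1, n_qtn + 1) if effect_model == "geometric" else np.ones(n_qtn)
    beta = base * rng.choice([-1.0, 1.0], size=n_qtn)
    Xc = G.dosages[:, causal]
    gv = Xc @ beta
    y = gv + _exact_h2_noise(rng, gv, h2)
    var_y = y.var()
    ve = beta**2 * Xc.var(axis=0) / var_y
    truth = SimTruth(
        causal_ids=[G.variants[j].id for j in causal],
        effects=beta,
        variance_explained=ve,
        h2=h2,
        genetic_values=gv,
    )
    return y, truth


def simulate_epistatic_trait(
    G: GenotypeMatrix,
    background: str,
    dependent: str,
    beta_bg: float,
    beta_dep: float,
    h2: float,
    seed: int = 0,
    extra_additive=None,
):
    """Trait with a background-conditional effect.

    The dependent locus contributes ``beta_dep * dosage`` only in accessions
    homozygous for the background allele (dosage 2 at the background locus);
    the background locus acts additively.  ``extra_additive`` optionally adds
    unconditional additive loci as (variant_id, beta) pairs.
    """
    _require_complete(G)
    if background == dependent:
        raise GenotypeError("background and dependent loci must differ")
    if not 0.0 < h2 <= 1.0:
        raise GenotypeError("h2 must lie in (0, 1]")
    g_bg = G.dosage(background)
    g_dep = G.dosage(dependent)
    r = np.corrcoef(g_bg, g_dep)[0, 1]
    if r * r >= 0.2:
        raise GenotypeError(
            f"background/dependent loci in high LD (r2={r * r:.2f}); confounded design"
        )
    rng = np.random.default_rng(seed)
    carrier = (g_bg == 2.0).astype(float)
    gv = beta_bg * g_bg + beta_dep * g_dep * carrier
    causal_ids = [background, dependent]
    effects = [beta_bg, beta_dep]
    if extra_additive:
        for vid, b in extra_additive:
            gv = gv + b * G.dosage(vid)
            causal_ids.append(vid)
            effects.append(b)
    y = gv + _exact_h2_noise(rng, gv, h2)
    var_y = y.var()
    comps = [beta_bg * g_bg, beta_dep * g_dep * carrier]
    if extra_additive:
        comps += [b * G.dosage(vid) for vid, b in extra_additive]
    ve = np.array([c.var() for c in comps]) / var_y
    truth = SimTruth(
        causal_ids=causal_ids,
        effects=np.array(effects),
        variance_explained=ve,
        h2=h2,
        epistatic_pairs=[(background, dependent, beta_dep)],
        genetic_values=gv,
    )
    return y, truth


def simulate_multienv(
    G,
    n_envs: int,
    env_effects=None,
    var_line: float = 1.0,
    var_gxe: float = 0.2,
    var_resid: float = 0.5,
    reps: int = 2,
    seed: int = 0,
    line_values=None,
    mean: float = 0.0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Long-format multi-environment phenotype records.

    value(i, j, k) = mean + env_j + line_i + gxe_ij + e_ijk, with line, GxE and
    residual terms drawn independently at the stated variances.  ``line_values``
    ties line effects to, e.g., a genetic value from an additive-trait
    simulation instead of drawing them.
    """
    if n_envs < 1:
        raise GenotypeError("n_envs must be >= 1")
    for name, v in (("var_line", var_line), ("var_gxe", var_gxe), ("var_resid", var_resid)):
        if v < 0:
            raise GenotypeError(f"{name} must be >= 0")
    accessions = list(G.accessions) if isinstance(G, GenotypeMatrix) else list(G)
    n = len(accessions)
    rng = np.random.default_rng(seed)
    env_effects = np.zeros(n_envs) if env_effects is None else np.asarray(env_effects, float)
    if env_effects.size != n_envs:
        raise GenotypeError("env_effects length must equal n_envs")
    line = (
        np.asarray(line_values, float)
        if line_values is not None
        else rng.normal(0.0, np.sqrt(var_line), n)
    )
    gxe = rng.normal(0.0, np.sqrt(var_gxe), (n, n_envs))
    rows = []
    for j in range(n_envs):
        env = f"env{j + 1}"
        for r in range(reps):
            e = rng.normal(0.0, np.sqrt(var_resid), n)
            vals = mean + env_effects[j] + line + gxe[:, j] + e
            rows.append(
                pd.DataFrame(
                    {
                        "accession": accessions,
                        "environment": env,
                        "replicate": r + 1,
                        "trait": trait,
                        "value": vals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
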