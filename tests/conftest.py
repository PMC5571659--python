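import numpy as np
import pytest

import assocnet as an


@pytest.fixture(scope="session")
def tiny_panel():
    """200 x 1,000 structured panel for fast unit tests."""
    return an.simulate_panel(
        an.PanelConfig(n_accessions=200, n_variants=1000, n_chromosomes=5, seed=1)
    )


@pytest.fixture(scope="session")
def panel809():
    """Study-scale panel (809 accessions) at reduced marker density."""
    return an.simulate_panel(an.PanelConfig(n_accessions=809, n_variants=8000, seed=7))


@pytest.fixture(scope="session")
def engine809(panel809):
    return an.MixedModelGWAS(panel809)


@pytest.fixture(scope="session")
def kinship809(panel809):
    return an.kinship_simple_matching(panel809)


@pytest.fixture(scope="session")
def indep_panel():
    """Independent-variant panel (no LD, no structure), 200 x 1,000."""
    return an.simulate_panel(
        an.PanelConfig(
            n_accessions=200,
            n_variants=1000,
            n_chromosomes=5,
            n_subpops=1,
            fst_like_divergence=0.0,
            ld_block_length=1,
            het_rate=0.0,
            seed=13,
        )
    )


def design_epistatic_fixture(G):
    """Pick background / dependent / additive-control loci on a panel and size
    their effects so that the background locus carries ~40% of full-population
    variance, the conditional locus 10% of carrier-subgroup variance, and the
    additive control ~12% of subgroup variance (noncentrality calculations
    put the full-population marginal of the conditional locus below the
    genome-wide threshold while keeping subgroup detection near-certain)."""
    X = G.dosages
    chroms = np.array([v.chrom for v in G.variants])
    frac2 = (X == 2).mean(axis=0)
    bg = int(np.flatnonzero((frac2 > 0.45) & (frac2 < 0.55))[0])
    carrier = X[:, bg] == 2
    pcs = an.genotype_pca(G, n_components=3)

    def pick(excl, prev):
        for j in range(G.n_variants):
            if chroms[j] in excl:
                continue
            x = X[:, j]
            mc, mn = x[carrier].mean() / 2, x[~carrier].mean() / 2
            if not (0.2 <= min(mc, 1 - mc) and 0.2 <= min(mn, 1 - mn)):
                continue
            # near-orthogonal to the background and to each other, so the
            # conditional locus carries no marginal signal through LD
            if any(np.corrcoef(x, X[:, q])[0, 1] ** 2 >= 0.002 for q in prev + [bg]):
                continue
            # unconfounded with population structure, so the covariates do
            # not absorb the simulated signal
            if all(np.corrcoef(x, pcs[:, k])[0, 1] ** 2 < 0.05 for k in range(3)):
                return j
        raise RuntimeError("no suitable locus")

    dep = pick({chroms[bg]}, [])
    add = pick({chroms[bg], chroms[dep]}, [dep])
    g_bg, g_dep, g_add = X[:, bg], X[:, dep], X[:, add]
    se2 = 0.78
    b_d = np.sqrt(0.10 / g_dep[carrier].var())
    b_a = np.sqrt(0.12 / g_add[carrier].var())
    rest = b_d * g_dep * carrier + b_a * g_add
    b_bg = np.sqrt(0.40 * (rest.var() + se2) / (0.60 * g_bg.var()))
    gv = b_bg * g_bg + rest
    h2 = gv.var() / (gv.var() + se2)
    ids = G.ids
    return dict(bg=ids[bg], dep=ids[dep], add=ids[add], b_bg=b_bg, b_d=b_d,
                b_a=b_a, h2=h2, bg_idx=bg, dep_idx=dep, add_idx=add)


def make_matrix(dosages, chrom="Chr01", start=100):
    """Hand-built GenotypeMatrix from a dense dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = [an.VariantRecord(chrom, start + j * 100) for j in range(m)]
    return an.GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)
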