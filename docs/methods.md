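# Methods

`assocnet` implements the analysis chain used to dissect complex traits in a
selfing-species diversity panel: mixed-linear-model (MLM) association with
permutation-derived genome-wide thresholds, genotype-conditioned subgroup
re-scans that expose epistatic and minor-effect loci, normalized between-locus
LD ("Inter-LD") networks linking traits through shared loci, a
variance-weighted power/FDR simulation, and cross-environment BLUP of line
performance. Every stage is driven and validated by a synthetic-data
generator, so the chain is testable end to end without any sequencing data.

## Genotype substrate

Genotypes are alternate-allele dosages (0/1/2, `NaN` missing) over accessions
x biallelic SNPs, read from VCF (via cyvcf2) or a dosage TSV. Coordinates
are 1-based inclusive; BED exports convert to 0-based half-open. QC keeps
variants with MAF >= 0.05 and missing rate < 0.1 (both configurable); the
filter is idempotent and never touches the accession set. Heterozygotes are
kept as dosage 1 throughout — on a selfing panel (heterozygosity ~0.2%) the
choice is numerically immaterial but must be fixed.

**kNN imputation.** The accession-accession distance is the mean of
|g_i − g_j| / 2 over co-observed variants; each missing call becomes the
rounded mean dosage of the k nearest accessions observed at that variant
(ties broken by accession order; observed cells are never modified). This is
a transparent stand-in for web-service imputation tools whose algorithms are
not published. It exploits *relatedness*: with near-duplicate accessions in
the panel (the norm in germplasm collections) masked-cell concordance is
high, but when local haplotypes are independent of genome-wide similarity —
as in our block-independent simulator — a global-distance kNN degrades to
subpopulation means and cannot beat the major-allele baseline. The test
suite therefore measures concordance on a panel containing relatives.

**Kinship.** Simple matching: K_ij = mean over variants of 1 − |g_i − g_j|/2,
symmetric with unit diagonal, entries in [0, 1]. On inbred dosages this is
(1 + x_i·x_j/M)/2 with x = g − 1, i.e. an affine transform of an uncentered
genomic relationship matrix. A ridge of 1e-6 is added to the diagonal before
eigendecomposition.

**LD.** r² is the squared Pearson correlation of dosage vectors over jointly
observed accessions (genotype-composite r², the standard choice for unphased
inbred data). It is symmetric and invariant to allele relabeling; it is
undefined (an error) for in-context monomorphic variants.

**PCA.** Principal components of the column-centered dosage matrix
(scikit-learn SVD backend); the first three score vectors are the default
fixed-effect structure covariates.

## Mixed-model association scan

The null model is y = Xβ + u + e, u ~ N(0, σ²_g K), e ~ N(0, σ²_e I), with
X = intercept + 3 PCs. The variance ratio δ = σ²_e/σ²_g is profiled out of
the restricted likelihood on the eigenbasis of the covariate-projected
kinship: one eigendecomposition per (X, K) pair, then a 100-point log-grid
search on δ ∈ [1e-5, 1e5] refined by golden section to relative tolerance
1e-6. The implementation was verified to match a direct dense
restricted-likelihood optimizer to six decimals.

Per-marker tests hold (σ²_g, σ²_e) fixed (the population-parameters-
previously-determined approximation) and run generalized least squares in the
basis that whitens V = σ²_g K + σ²_e I, reporting the Wald t with
df = n − rank(X) − 1, two-sided. With K = I the scan reduces *exactly* to
covariate-adjusted OLS (tested to 1e-8). In-context monomorphic variants are
flagged untested, never zero-filled. On permuted phenotypes the scan is
calibrated: P values are KS-uniform and the genomic-inflation factor λ sits
in [0.9, 1.1].

**Permutation thresholds.** The phenotype is shuffled (breaking all
genotype links), δ is re-fitted per shuffle on the cached eigenbasis, the
genome is re-scanned, and the minimum P is recorded; the threshold is the
empirical α-quantile (α = 0.05) of the min-P sample over 1000 permutations
(configurable). On an independent-variant panel the derived threshold lands
within a factor of two of the Šidák value 1 − 0.95^(1/M); stronger LD gives
a larger (less stringent) threshold. A fixed 2e-7 override matches the
empirical cutoff for normally distributed traits. Trait-distribution classes
(binary / normal / skewed / binary-like, the last via a modal-share > 80%
rule and |skewness| > 1 for skewed) let thresholds be shared across traits
of a type; binary-like traits get materially more stringent thresholds.

## SAL calling and the conditional subgroup re-scan

A significantly associated locus (SAL) is called greedily: the unassigned
significant variant with the lowest P seeds a peak; the interval extends over
consecutive panel variants on the same chromosome while r² with the *peak*
stays >= 0.6 (peak-anchored reading of "consecutive region in LD"; a chained
adjacent-r² mode exists behind a flag). Significant variants inside an
interval are absorbed, so significant variants partition cleanly across SALs.
Two SALs overlap if their intervals intersect positionally or their peaks are
in LD (r² >= 0.6).

For each primary SAL the population is split at the peak SNP into the two
homozygous dosage classes (hets/missing excluded; on a selfing panel this
discards ~0.2% of accessions). A class is analyzable only with **more than**
100 accessions (strict). Each analyzable subgroup is re-scanned end to end
with subgroup-recomputed kinship, PCs and MAF filter. A subgroup SAL
overlapping no primary SAL of the trait is *secondary*; a secondary signal
passing the subgroup threshold in exactly one homozygous background is
classified `one_subgroup_only` (the epistatic pattern), in both backgrounds
`both_subgroups` (an ordinary minor-effect locus surfacing once background
variance is removed). One split level only — no recursion.

Validation mirrors the motivating biology: a locus whose effect exists only
in one homozygous background, sized to 10% of carrier-subgroup variance at
n = 809, is invisible to the genome-wide scan at 2e-7 yet recovered by the
carrier-subgroup re-scan in 48/50 replicates, while an unconditional control
locus is significant in both subgroups in 49/50. The fixture deliberately
picks the conditional and control loci near-orthogonal to the background
locus and to the leading PCs; otherwise LD with the large background effect
leaks marginal signal, and structure covariates absorb the control — both
confounds extraneous to the mechanism under test.

## Inter-LD networks, key nodes, allele stacking

For SALs S1, S2:

    LD(S1, S2)   = mean pairwise r² between all member SNPs of S1 and S2
    PmaxLD(S)    = max over member SNPs of that SNP's mean r² to all members
                   (self pairs included; an excluded-self mode is flagged)
    Inter-LD     = ½ · ( LD(S1,S2)/PmaxLD(S1) + LD(S1,S2)/PmaxLD(S2) )

Inter-LD is symmetric, collapses to plain r² for single-SNP loci, and for a
SAL with itself is bounded by 1. The trait-locus network has trait nodes and
SAL nodes; SALs from different traits that overlap are merged into a single
node (how pleiotropy surfaces), trait→SAL membership edges are always drawn,
and SAL–SAL edges are kept when Inter-LD >= 0.4 (a raw cross-LD mode is
flagged). A SAL's score is the lowest P among its merged constituents. Key
nodes are SAL nodes reaching >= 2 traits directly or through their own
SAL–SAL edges, ranked by trait count then score. Exports: GraphML, SIF, edge
TSV.

Allele stacking counts, per accession, the loci homozygous for the favorable
allele (a dosage-0–2 mode is flagged; homozygous counting suits an inbred
panel) and reports the mean-trait curve by count plus a least-squares trend
slope. On additive equal-effect traits the curve rises and the slope is
significantly positive; with shuffled favorable labels it is flat.

## Power and FDR simulation

Per replicate: draw causal SNPs uniformly from the panel (constrained to
pairwise r² < 0.2 so marginal variance shares account for the trait — see
below), simulate the trait, scan, and call intervals around every SNP with
P <= 2e-7 using the LD-0.6 rule. Power is the share of total causal variance
carried by causal loci inside >= 1 interval; FDR is the fraction of intervals
containing no causal locus. Replicates with zero intervals are excluded from
the FDR average by default (an include-as-zero convention is flagged; the
choice is not decidable from the description being followed). Grid defaults:
QTN ∈ {2, 5, 10} × h² ∈ {0.25, 0.5, 0.75}, 200 replicates at desk scale
(1000 on the original design), fully reproducible under one seed, with the
kinship/PC/eigen machinery shared across all replicates. The scorer is
verified exactly against an independent re-implementation.

## Synthetic data

The panel generator emulates a selfing-species diversity collection.
Defaults are the study conditions: 809 accessions, 20,000 variants on 20
chromosomes, 3 subpopulations, Balding–Nichols divergence F = 0.10
(landrace/cultivar-level differentiation), LD blocks of 10 variants at 50-kb
spacing (~500-kb blocks, the long-LD regime of a selfer), MAF floor 0.05,
heterozygosity 0.0017. Within each block every subpopulation carries 6
founder haplotypes; an accession draws one (doubled, selfing) founder per
block with 2% per-cell redraw noise. Variants failing the MAF floor are
re-drawn at the founder level so block LD survives. All generators are pure
functions of (inputs, seed).

Traits: additive (effects geometric with ratio 0.9 and random signs — a
major-plus-minor mixture — or equal), background-conditional (the dependent
locus acts only in accessions homozygous for the background allele; the pair
must have r² < 0.2 or the design is rejected as confounded), and
multi-environment (mean + env + line + G×E + residual at stated variances).
Residual noise is orthogonalized against the genetic value and scaled so the
realized *sample* h² equals its target exactly, removing one layer of
Monte-Carlo noise from power experiments. `SimTruth` records per-causal
marginal variance shares; the low-LD causal constraint keeps their sum equal
to h² up to sampling-level cross terms (exact for orthogonal designs).

**What the generator does not emulate.** Real germplasm panels carry
near-duplicate accessions and pedigree relatedness; here genome-wide
similarity is driven only by subpopulation membership, and block founder
choices are independent across blocks. Consequences measured and accepted:
(i) global-distance kNN imputation has no relatives to lean on (see above);
(ii) with only ~1 independent block per accession-dimension, kinship spectra
are wide, so on pure-noise phenotypes the REML genetic-variance share is
*typically* ~0 (median < 0.02) but its mean is heavy-tailed — calibration
claims are therefore made on medians; (iii) detection power at n = 809 is
higher than on a real panel of the same size, where pervasive relatedness
shrinks the effective sample size — the power grid here reads as an upper
envelope for a panel of this size (at QTN = 2, h² = 0.25 power is ~0.99;
at QTN = 10, h² = 0.75 it is ~0.89 with interval FDR ~0.15).

## Cross-environment BLUP and heritability

The multi-environment model y_ijk = μ + env_j + line_i + (line×env)_ij +
e_ijk (environments fixed, the rest random) is fitted by EM-REML on the
mixed-model equations: tolerance 1e-6, at most 500 iterations, components
floored at zero by construction, a final solve at the converged components,
non-convergence flagged but the last iterate returned. Line solutions
(BLUPs) are the environment-free phenotype passed to GWAS (a raw-means path
exists). EM was chosen over average-information REML for its simplicity and
guaranteed non-negative components at desk scale; it matches lme4's REML
components and BLUPs to ~1e-5 on a balanced fixture. BLUPs are centered and
never more dispersed than centered line means (shrinkage). With a single
environment the G×E component is fixed at zero.

Narrow-sense heritability is σ²_g/(σ²_g + σ²_e) from the kinship null model,
after centering and trace-rescaling the kinship (Gower normalization, the
convention of GCTA/GAPIT-style REML). The rescale matters: raw simple
matching equals (1 + uncentered-GRM/M)/2, whose genetic part carries only
half the projected diagonal, which would inflate the ratio. With 50-QTN
traits at n = 809, targets 0.25/0.5/0.75 are recovered within ±0.04 on
average (±0.1 guaranteed by test); estimates for sparser architectures
(<10 QTNs) are markedly noisier because few causal directions project onto
the kinship spectrum.

Trait correlations are pairwise-complete Pearson on per-accession values
(binary traits pre-encoded 0/1), with entries on fewer than 3 complete pairs
flagged missing.

## Numerical choices and limitations

- Kinship ridge 1e-6; δ grid [1e-5, 1e5]; golden-section tolerance 1e-6;
  P values floored at the smallest positive double.
- SAL peak ties broken by leftmost genomic position; kNN neighbour ties by
  accession order; interval extension stops at undefined (monomorphic) r².
- Problem sizes in the shipped tests — 809 accessions × 8,000 variants,
  50–60 replicates where the full design uses 200–1000 — are the package's
  desk-scale defaults; `scripts/acceptance.py` runs 809 × 20,000 with 200
  replicates.
- Binary traits are analyzed as 0/1 quantitative throughout; no threshold or
  logistic mixed models. No multi-locus models, rare-variant tests, phasing,
  indels, or coalescent realism.
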