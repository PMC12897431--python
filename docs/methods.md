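# Methods

This note documents the models and algorithms breedkit implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that affect
results.

## Data model

Genotypes are diploid biallelic dosages in {0, 1, 2} counting copies of a
designated allele (VCF ALT / PLINK bim A1), stored as int8 with −1 as the
missing sentinel — never conflated with dosage 0. Coordinates are 1-based
inclusive; interval lengths are `end − start + 1` bp. Chromosomes are string
labels; the default autosome set is "1".."18" (*Sus scrofa*), configurable.
Which allele is counted is recorded but immaterial: every statistic in the
package is invariant to flipping the counted allele at any site (folded
frequencies, heterozygosity, r², |dosage differences|), so no orientation
harmonisation step is needed.

## Quality control

Two distinct screens, applied at different points:

* **Panel-design screen** (before ΔMAF scoring): keep sites with missing
  fraction < 0.1 and observed heterozygote fraction < 0.5, both strict. The
  heterozygosity cap removes paralog-collapse artefacts that would otherwise
  look breed-discriminating.
* **Analysis chain**: individuals with call rate < 90% first; then, with
  site statistics recomputed on the reduced cohort: autosomes only → site
  call rate ≥ 90% → MAF ≥ 0.01 → Hardy–Weinberg exact p ≥ 1e-6. Boundary
  semantics are literal (strictly-below removals, retention at equality).
  The chain is idempotent.

The HWE test is the exact conditional test: given the allele totals, all
heterozygote counts of the observed parity are enumerated with weights
∝ 2^h / (n_AA! h! n_aa!), and the p-value sums every configuration no more
probable than the observed one. Log-gamma arithmetic keeps it stable to
n in the thousands; the suite verifies agreement with a rational-arithmetic
enumeration oracle to 1e-12 on all tables with n ≤ 50. When breed labels are
available the test runs within each population and the per-site minimum p is
used, avoiding Wahlund-effect false positives; a chi-square variant exists
for comparison. Under simulated equilibrium genotypes (n=200) the empirical
p<0.05 rate is ≈0.04 — the exact test is conservative, as expected.

## Diversity statistics

For counted-allele frequency p (q = 1 − p) from n non-missing allele copies:
MAF = min(p, q); Ho = heterozygote fraction; He = 2pq with **no**
small-sample correction; Pi = 2pq·n/(n−1), which is exactly the mean
pairwise difference over allele copies (verified against an O(n²) oracle);
PIC = 1 − (p² + q²) − 2p²q². Leaving He uncorrected while Pi carries the
n/(n−1) factor means Ho can exceed He in outbred cohorts — a pattern real
conservation herds show — rather than being forced by construction.
Pn counts the fraction of panel markers segregating (MAF > 0 by default;
threshold configurable) among markers passing call-rate in that population.
Population tables report unweighted means ± sd (ddof=1) across sites; sites
entirely missing in a population are excluded from its means. Two-population
comparisons use the two-sided Mann–Whitney U with normal approximation and
tie correction.

## ΔMAF panel design

For each target breed, ΔMAF = |MAF_target − MAF_other| where MAF_other pools
the genotypes of all non-target individuals (sample-size weighted; an
unweighted mean-of-breed-MAFs option exists, since pooling is a genuine
modelling choice). Both frequencies are folded to ≤ 0.5 before
differencing — the field's printed definition — although folding can mask
differentiation when the minor allele differs between groups; an unfolded
|p_t − p_o| option is provided but not default.

Uniform coverage: each chromosome's span (first to last candidate) is cut
into equal-width bins (default: as many bins as the per-chromosome target);
the top-ΔMAF site per bin is taken, and unfilled slots are backfilled with
the globally next-best remaining sites on that chromosome. Ranking is a
stable sort with ties broken by (chromosome, position, marker id), so the
design is deterministic and seed-free. Per-breed selections are unioned and
deduplicated, keeping the record of every nominating breed.

## Genomic breed composition

Supervised admixture: reference allele frequencies f (K breeds × M markers)
are estimated from labelled reference genotypes by pooled counting and
clamped to [1e-4, 1 − 1e-4] so fixed sites cannot contribute infinite log
terms. For one individual the log-likelihood over the ancestry simplex q is

    ℓ(q) = Σ_j [ g_j log p_j(q) + (2 − g_j) log(1 − p_j(q)) ],  p_j(q) = Σ_k q_k f_kj

which is concave in q (log of affine). EM: counted-allele copies are
attributed to breeds with responsibilities q_k f_kj / p_j, the other allele
with q_k (1 − f_kj)/(1 − p_j); the M-step renormalises the expected counts
by 2M. A flat start (q = 1/K) suffices; convergence is Δℓ < 1e-6 or 500
sweeps. Missing markers are skipped, not imputed. The fitted solutions were
cross-checked against a constrained quasi-Newton optimiser (SLSQP) on
fixtures and coincide to the reported digits — the EM stops at the true MLE,
not short of it.

Purity = max_k q_k; an individual is called *pure* at threshold 0.95
(0.99 for a strict call), *admixed* otherwise. The validation harness runs
the estimator against Random Forest (200 trees) and a one-hidden-layer
multilayer perceptron on mean-imputed dosages, with a stratified 70/30
train/test split.

A known small-sample property worth stating: for a genuine purebred
evaluated on ~1,000 AIMs across K=5 moderately differentiated breeds
(FST 0.15), the MLE purity distribution has mean ≈ 0.98 but a real lower
tail — its 5th percentile sits almost exactly at 0.95, so roughly one
purebred in fifteen is called admixed at the 0.95 threshold at this scale.
This is estimator sampling noise, not a defect (verified against the exact
MLE); with panels of ~19K markers and stronger between-breed differentiation
the distribution concentrates near 1 and purity calls become essentially
deterministic. Purity screening on small panels should therefore use either
more markers or a threshold chosen from the panel's own purebred
calibration.

## Runs of homozygosity

PLINK-style scan per individual and chromosome: windows of 30 consecutive
SNPs are flagged homozygous when they contain ≤1 heterozygous and ≤5 missing
calls; each SNP's hit rate is the homozygous fraction of the windows
covering it; SNPs with rate > 0.05 are candidates. Maximal candidate runs
are partitioned greedily left-to-right into segments respecting the same
het/missing caps at segment level (when adding a SNP would exceed a cap the
current segment closes and a new one starts at the offending SNP, so a
second heterozygote splits rather than discards a run). Segments need ≥30
SNPs and ≥500 kb to be reported. Both window- and segment-level caps are
enforced, and the "≤5 missing / ≤1 het" allowance is configurable at each
level separately because its scope is a genuine ambiguity in common usage.

F_ROH = Σ L_ROH / L_AUTO. L_AUTO defaults to the summed first-to-last marker
spans of the analysed autosomes — the denominator the data can actually
support — with a fixed assembly constant configurable. Length classes are
left-closed: [min, 5), [5, 10), [10, ∞) Mb.

Implant-and-recover behaviour: tracts ≥ 2× the minimum length are recovered
with precision and recall 1.0 at 50 SNPs/Mb in the seeded suite, with
boundary error bounded by one inter-SNP gap plus the expected chance
extension (~1/heterozygosity sites) into the flanking background. Sub-500 kb
implants are never reported as such, but can seed a reportable segment when
chance flanking homozygosity extends them past the minimum — real
autozygosity behaves the same way, so evaluation counts tracts ≥ 1 Mb.

## LD and PCA

r² is the squared Pearson correlation of dosage vectors over jointly
non-missing samples (composite/genotypic LD): phase-free, deterministic, and
the standard choice for decay curves; EM haplotype-frequency r is out of
scope. Pairs with a monomorphic member are signalled and skipped. Decay
curves average r² in half-open distance bins (defaults 10 kb bins to 1,000
kb, both configurable; the axis range is a reporting choice, not a model
choice) with an optional seeded per-chromosome pair cap for dense maps.

PCA standardizes each site by centring at 2p̂ and scaling by √(2p̂(1−p̂)),
sets missing entries to 0 after centring, drops monomorphic sites, and takes
the SVD. Explained fractions are eigenvalue ratios; component signs are
fixed by making each component's largest-|loading| entry positive, so runs
are bit-reproducible. t-SNE is a thin wrapper over scikit-learn for
visualisation only.

## IBS families and mate selection

IBS(i,j) = mean over jointly non-missing sites of (2 − |g_i − g_j|)/2,
computed by indicator-matrix products (exact, no sampling). "Molecular
families" are average-linkage clusters of the distance 1 − IBS cut at a
fixed family count — the count (7 in a typical herd analysis) is a
parameter, since genotype data alone cannot fix it. Animals with
F_ROH > 0.3 (strict) are excluded from breeding candidacy. The mating
planner is a greedy round-robin: every family with an eligible sire
contributes; each sire takes dams from other families, preferring the
least-used dam family, then the lowest sire–dam IBS, then sample order —
deterministic throughout. Offspring comparisons (planned cross-family vs
within-family matings) simulate one generation by independent Mendelian
gamete sampling per marker; no linkage is needed for single-generation
heterozygosity.

## Synthetic data

The generator's default scale mirrors a real multi-breed GBC reference
panel: 25 breeds × 50 individuals (= 1,250; the reference cohort this
emulates had 1,248), 18,900 SNPs on 18 autosomes of 136 Mb (≈ the pig
autosomal genome split evenly), ancestral frequencies Uniform(0.05, 0.95),
FST 0.15 per breed (mid-range for differentiated pig breeds), and a 0.4%
missing rate (a ~99.6% call-rate chip). Validation experiments override
these with the smaller sizes listed below.

Breed frequencies follow Balding–Nichols:
f_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving E[f_k] = p and
Var[f_k] = F·p(1−p) (checked as a moment identity in the suite). Purebred
genotypes are Binomial(2, f_kj); admixed individuals draw each allele copy's
breed of origin from a known q. LD mode builds individuals from a finite
pool of founder haplotypes with Poisson crossovers (switch probability
1 − exp(−c·gap) per inter-marker gap), which produces distance-decaying r²
with a controllable scale. Autozygous tracts are implanted by collapsing
heterozygotes to a random homozygote within an interval; full-sib families
come from founder pairs with per-marker Mendelian sampling.

What the generator does **not** emulate: mutation and realistic site
frequency spectra, admixture LD, linked autozygosity from pedigree
inbreeding (implants have sharp edges), genotyping error beyond missingness,
and sex chromosomes. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated models, not
robustness to artefacts real assays produce.

## Validation experiment sizes

Chosen to exercise each property at the smallest scale where it is
statistically meaningful: ancestry recovery uses K=5, FST=0.15, 1,000-marker
panels designed from 20,000-site pools (a 20:1 enrichment ratio — far below
the ~150:1 of a whole-genome design, so recovery numbers are conservative),
50 replicates; the assignment benchmark uses 40 individuals/breed with a
stratified 70/30 split; ROH recovery uses 10 individuals × 150 Mb at 50
SNPs/Mb with 15.3 Mb of implants each; panel enrichment uses 5,000-site
pools with 10% of sites redrawn at FST 0.5 over an FST 0.05 background,
20 paired seeds. All experiments are bit-reproducible from a single seed.

## Known limitations

* Supervised GBC assumes the reference spans the test individuals' true
  ancestries; an unrepresented breed is absorbed by its nearest relatives.
* ΔMAF on folded frequencies can underscore sites whose minor alleles differ
  between target and pool (the unfolded option addresses this).
* The ROH caller is rule-based; it has no model of genotyping error beyond
  the het/missing allowances, and no HMM alternative is provided.
* Pn's threshold and denominator are reporting conventions; both are
  configurable because published values are rarely auditable.
* The mating planner optimises greedily, not globally (no optimal-contribution
  selection).
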