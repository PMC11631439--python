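# Methods

This note documents the models, defaults, numerical choices, and known
limitations of the pipeline. Everything described here is computed by the
package; no empirical claim is made beyond what the test suite and
`scripts/acceptance.py` themselves measure.

## Cohort filtering and the callable-site ledger

Loci are classified from allele lengths: *snp* (all alleles length 1, ≥ 1
alt), *indel* (some length difference, no SNP-type alt), *complex* (both
SNP- and InDel-type alts), *invariant* (no alt). Complex loci are removed
from every downstream product, including the ledger.

Per-call quality masking (DP ≥ 10, GQ ≥ 20, both inclusive; calls lacking
either tag fail conservatively) runs first. Sample exclusion (missing
fraction ≥ 20% over variant loci) runs **before** site exclusion (missing
fraction ≥ 1% among retained samples); both thresholds are strict, so a
fraction exactly at the boundary is excluded. Sample missingness is
measured over variant (SNP + InDel) loci only, because gVCF invariant
blocks carry no per-sample genotypes.

The heterozygote-excess statistic is the exact one-sided tail
P(het ≥ observed) of the Levene–Haldane conditional distribution of the
heterozygote count given the allele counts, computed with log-gamma
weights; small values signal heterozygote excess. The default filter mode
`remove_below` drops sites whose tail probability is below
1 − 0.99 = 0.01, i.e. sites with genuine heterozygote excess — the
signature of collapsed paralogs and mapping artifacts. The alternative
`remove_above` drops heterozygote-*deficient* sites instead; it is
available but is not the default because inbred, clade-structured
populations are legitimately het-deficient at most sites (Wahlund effect)
and would lose the bulk of their markers. The test is computed on diploid
biallelic calls only.

The callable-site ledger counts non-variant positions plus retained SNP
loci, per chromosome, and optionally stores the callable coordinates so
windowed statistics can use callable positions (not raw window length) as
their denominator.

The genotype matrix is biallelic by construction: multi-allelic SNP loci
are decomposed against their most frequent alt, and calls carrying any
other alt become missing for that locus.

## Zygosity and ploidy

A sample is *heterozygous* iff it carries strictly more than 500
heterozygous SNPs. The 500 count is calibrated to a ~12-Mb genome with
~9.4M callable sites (a rate of ~5×10⁻⁵); for the toy genomes used in
tests the pipeline exposes `het_snp_threshold` and scales it
proportionally. Heterozygosity is n_het / callable_total.

Ploidy is inferred from alternate-allele read fractions at biallelic het
sites with coverage ≥ 10 and fraction inside (0.10, 0.90); at least 100
such sites are required, otherwise the call is *unknown*. Homozygous
samples are always *unknown*: with no heterozygous sites the allelic-ratio
signal does not exist, so sequencing data alone cannot distinguish a
haploid from a homozygous diploid.

Each candidate ploidy p ∈ {2, 3, 4} has a Gaussian mixture with means
fixed at its dosage fractions ({½}, {⅓, ⅔}, {¼, ½, ¾}), free weights, and
one shared standard deviation (floor 10⁻³ against degenerate spikes),
fitted by EM; the log-likelihood is asserted non-decreasing every
iteration. The free model (3 components, free means) is fitted from 10
random restarts **plus** the fitted fixed-model solutions as warm starts,
which guarantees the nesting inequality logL_free ≥ logL_fixed up to
tolerance. The histogram test bins the fractions into 30 equal bins over
the retention interval and compares observed proportions with the fitted
mixture's per-bin mass renormalized to the interval:
SSR = Σ(obs − exp)², R² = 1 − SSR/Σ(obs − mean)².

Decision criteria: `delta_loglik` minimizes logL_free − logL_fixed, `ssr`
minimizes SSR, `r2` maximizes R². Because the tetraploid model's free
weights let it collapse exactly onto the diploid model (all mass on the ½
component), scores on diploid data tie up to EM convergence noise; scores
within a small tolerance (10⁻³ relative for ΔlogL, 10⁻⁵ for SSR, 10⁻³ for
R²) therefore count as tied and the tie resolves to the **lowest** ploidy.
Without this the 2n/4n decision would be decided by floating-point noise.
Ploidies above 4n and denoising of the read-fraction histogram are out of
scope.

## CNV and aneuploidy

Depth is summarized in non-overlapping 1-kb windows (the last window of a
chromosome may be short). Normalized read depth RD = raw / center, where
the center is the genome-wide median (default) or the mode of a smoothed
depth histogram — the mode resists bias when a large fraction of the
genome is aneuploid. Segmentation is deliberately simple: windows with
|RD − 1| > δ (default 0.25) are CNV windows, and maximal runs of at least
2 consecutive CNV windows become regions carrying the mean RD of their
windows. This threshold-merge rule replaces heavier segmentation machinery
because the downstream consumers only need regions and their RD.

Every position outside a region has RD exactly 1. The per-CDS value is the
median RD over all CDS positions (multi-exon CDS pool their exons),
computed as a weighted median over the piecewise-constant RD segments. A
chromosome is aneuploid iff strictly more than half its length lies in CNV
regions, counting gains and losses alike. Coordinates are BED-style
0-based half-open throughout. No GC correction is applied; RD is not
converted to integer copy number.

## Diversity statistics

The pairwise distance between two isolates counts sites where both carry a
call and their alt dosages differ (het vs hom at a site counts once).
Pair sampling is uniform over unordered pairs without replacement. Site π
uses the unbiased estimator n/(n−1)·(1 − Σ p_a²) over observed allele
copies, with mixed-ploidy samples contributing their actual copy numbers
and missing calls reducing n. Windowed π sums site values over 10-kb
windows stepped by 1 kb and divides by the callable positions in the
window (configurable to raw window length). Spearman ρ uses midranks and
the large-sample p approximation.

## Rarefaction and saturation

With c_k variants carried by exactly k of N isolates, the expected count
in a random n-subsample has the closed form

    P(≥1 carrier) = 1 − C(N−k, n)/C(N, n)
    P(≥2 carriers) = P(≥1) − k·C(N−k, n−1)/C(N, n)
    E[y(n)] = Σ_k c_k · P(≥ min_carriers),

evaluated with log-gamma binomials. Singleton status is judged **inside
the subsample** — a population-level doubleton usually looks like a
singleton in a small subsample — and a regression test pins this
semantics. A Monte-Carlo twin exists for cross-checking. The default grid
is 50 geometrically spaced sizes from 2 to N.

The all-variant curve is fitted by y = a·xᵇ − c (a > 0, 0 < b < 1); its
asymptote is infinite, so no coverage fraction is defined from it and the
code refuses to compute one. The non-singleton curve is fitted by
y = Vmax·x/(K + x) with positivity constraints, initialized from a
double-reciprocal linear pass with 5 jittered restarts (fixed seed). The
*coverage fraction* is (observed non-singleton count)/Vmax by default;
the alternative numerator y(N) (the fitted curve at the cohort size) is
exposed because the two differ slightly and either convention is
defensible.

**Limitation.** Vmax extrapolates; its quality depends on how closely the
discovery process resembles a hyperbola. When the pool contains many
variants too rare to be seen at the cohort scale, the fitted plateau
tracks the *visible* pool and the coverage fraction is an upper bound —
adding a divergent population would raise the true pool and lower the
fraction. The simulation used in the acceptance checks (generator-default
Jeffreys Beta(½, ½) ancestral spectrum, six clades, cohort = one third of
the simulated species) recovers the true captured fraction within ~2–3
percentage points; spectra with much heavier rare tails would not.

## Population structure

Structure markers are biallelic loci with minor allele frequency strictly
above 5%, then LD-pruned: a greedy left-to-right scan keeps a locus only
if its pairwise-complete dosage r² with every kept locus among the
previous 49 kept loci is ≤ 0.5 (the later locus of a violating pair is
always the one dropped). The result satisfies the plink indep-pairwise
postcondition — no window of 50 consecutive retained loci contains a pair
with r² > 0.5 — which a brute-force windowed check asserts in the tests.

Distances are 1 − IBS: per comparable locus, allele sharing is
1 − |dose_i − dose_j|/max_dose. Neighbor joining is the standard
Saitou–Nei agglomeration with the Q-criterion, deterministic
lowest-index-pair tie-breaking, and negative branch lengths clamped to 0;
it is exact on additive matrices (asserted against 4- and 8-taxon
oracles).

Ancestry uses the classic admixture likelihood: sample i with m_i allele
copies draws each copy at locus l from component k with probability q_ik
and then the alt allele with probability f_kl, giving the binomial
log-likelihood Σ_il [g_il log(Σ_k q_ik f_kl) + (m_i − g_il) log(Σ_k q_ik
(1 − f_kl))]. EM alternates responsibility updates for alt and ref copies;
Q rows stay on the simplex by construction, F is clipped to [10⁻⁶,
1 − 10⁻⁶], and the log-likelihood is asserted non-decreasing. The first
of 3 restarts is a deterministic spectral warm start (k-means on the top
principal components of mean-imputed dosage fractions), which avoids the
label-symmetric local optima that plague purely random starts on small
cohorts; the remaining restarts are random and the best log-likelihood
wins. Haploid/polyploid samples enter through their declared copy number
m_i. K is a parameter; choosing it is out of scope.

A sample is assigned to its argmax component iff that ancestry strictly
exceeds 0.60, otherwise it stays unassigned (admixed). Superclades are a
declarative mapping from components to names; manual refinement of clades
on the tree is deliberately not automated — the pipeline emits the tree,
Q matrix, and assignments for human curation.

## Synthetic populations

The generator emulates the *shape* of a large yeast survey. Ancestral
allele frequencies are Beta(½, ½) (Jeffreys) clipped to [0.01, 0.99];
clade frequencies follow the Balding–Nichols model f_kl ~
Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F = 0.15 by default, so
E[f|p] = p and Var[f|p] = F·p(1−p). Pure samples have one-hot ancestry;
admixed samples draw Dirichlet(1) rows. Ploidy defaults mirror the
survey's mix (6% 1n, 74% 2n, 12% 3n, 8% 4n); 42% of samples are inbred
(genotypes drawn as identical allele copies → homozygous), matching the
survey's homozygous fraction; outbred samples draw dosage ~
Binomial(m, Σ_k q_k f_kl). The toy genome is four chromosomes (1.5 Mb /
1 Mb / 0.6 Mb / 0.3 Mb by default; tests shrink it further), echoing at
small scale the observation that aneuploidy favors short chromosomes —
the generator picks the aneuploid chromosome with probability
proportional to 1/length (rate 0.30/sample; interstitial CNV segments of
20–80 kb at rate 0.30).

Depth: a window's **read count** is NegBin(mean = coverage × copy-ratio ×
window/read-length, size 500) converted back to mean depth, giving the
~5–10% per-window coefficient of variation of real short-read coverage; a
single NB draw on the depth scale would exaggerate window noise by ~3×.
GQ is emitted as the deterministic convention min(99, 3·DP) — a synthetic
stand-in, since the filter needs a GQ to act on. Allelic read counts at
het sites are Binomial(cov, dosage/m) with Poisson coverage.

What the generator does **not** emulate: linkage disequilibrium along
chromosomes (loci are exchangeable given ancestry), recombination and
coalescent genealogies, sequencing-read-level artifacts, InDel mutational
models (InDels would be presence/absence markers only), or GC-coverage
bias. Passing tests therefore demonstrate the estimators' correctness
under the stated models, not robustness to every real-data pathology.

## Problem sizes and reproducibility

Tests and the acceptance script run on deliberately small instances — a
~100-isolate, 280-kb-genome cohort for the end-to-end pipeline; 150
samples × 2,000 sites for the ploidy benchmark; 150 samples × 5,000 loci
for ancestry recovery; a 360-isolate simulated species for the coverage
check — sizes at which every stage's statistical signal is already
decisive. Every stochastic component takes an explicit seed; identical
seeds give byte-identical generator output and identical pipeline
reports.
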