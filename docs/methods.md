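# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
clonetrack.

## Read-count model and CCF adjustment

Every stage rests on one emission model. A mutation carried by a
fraction *p* of tumour cells (cancer cell fraction, CCF) at multiplicity
*m* on total copy number *c*, in a sample of purity *ρ*, has expected
variant allele fraction

    f(ρ, c, m, p) = ρ·m·p / (ρ·c + 2(1−ρ)),

and the observed variant reads are X ~ Binomial(n, f) at depth n.
A site with n = 0 is *untyped*, which is never treated as absence;
absence is a statistical call (below).

Multiplicity is assigned per mutation and sample by residual
minimisation over m ∈ {1..c} against the clonal expectation, but a
mutation is only escalated above m = 1 when its implied CCF at m = 1
exceeds 1 by more than three binomial standard errors (and at least
0.2). Without this noise allowance, a few percent of genuinely clonal
single-copy mutations at depth ~80 would have their high-VAF
fluctuations reinterpreted as m = 2, which clips the upper tail of the
clonal VAF distribution and biases clonal CCF estimates low.

## QC before clustering

Mutations are excluded, with reason codes, when (a) they fall in a
segment with total copy number zero in any related sample (`lost-region`
— absence there could reflect the deletion, not subclonal structure),
(b) they fall outside every copy-number segment in some sample
(`undefined-CN`), or (c) they have zero depth in every sample
(`untyped`). The retained fraction is reported; on the default synthetic
configurations it is ≈ 1 because segments cover the whole synthetic
genome.

## Dirichlet-process clustering across samples

Retained substitutions are clustered with a Dirichlet-process mixture
whose components are per-sample CCF vectors p_k and whose emission is
the binomial model above, independent across samples. Sampling choices:

* Cluster CCFs live on a grid over [0, 1.2] (step 0.01). Values above 1
  absorb residual multiplicity misestimates; reported CCFs are truncated
  to [0, 1]. The grid makes the parameter update an exact categorical
  draw and lets the whole likelihood be precomputed as one
  (mutations × samples × grid) table.
* Assignments use auxiliary-component Gibbs updates (three auxiliary
  draws from the uniform grid prior) for the non-conjugate emission.
* The concentration parameter has a Gamma(1, 1) hyperprior resampled
  every sweep by the usual beta-augmentation.
* Defaults: 1,000 sweeps, 500 burn-in, thinning 5. The summary
  partition maximises the posterior-expected adjusted Rand index among
  the sampled partitions.
* Cluster CCF point estimates and 95% credible intervals are *marginal*:
  per sweep, each summary cluster takes the parameter draw of the
  sampled cluster holding its members (median across members), and the
  interval is the 2.5–97.5% range of those pooled draws, widened by half
  a grid cell (a grid point represents a cell, not a point). This folds
  assignment uncertainty into the interval; a conditional interval for
  one fixed partition is materially too narrow. Note that per-sample
  95% intervals cover jointly across S samples only at ≈ 0.95^S.
* Clusters smaller than max(5, 1% of mutations) are merged into the
  nearest cluster (Euclidean CCF distance) and flagged. The threshold is
  exposed in configuration.
* The sampler internally sorts mutations by their data content, so
  results are invariant to input row order at a fixed seed; all draws
  come from a single seeded generator.

## Clone trees by the pigeonhole principle

A cluster A may be ancestral to B only if CCF_A ≥ CCF_B − τ in every
sample (τ = 0.05 by default), and the children of any node may not sum
above the parent's CCF + τ in any sample. Clusters whose CCFs agree
within τ everywhere are merged (mutually dominating clusters carry no
ordering information). Exactly one cluster must qualify as trunk
(CCF ≥ 1 − τ in all samples). All parent assignments satisfying both
constraints are enumerated; the deepest-nesting tree is primary and the
rest are returned ranked, which operationalises "resolve ambiguity by
deduction" as an explicit enumeration.

Presence of a point mutation in a sample is decided by the exact
binomial upper tail at an expected error rate of 1/200: present iff
P(Binomial(n, 1/200) ≥ X) ≤ 0.05. Structural variants are present where
reconstructed or supported by ≥ 4 split reads.

Branch statistics use substitution counts as molecular time. The
divergence fraction of a recurrence is the substitution count on the
shared lineage from the root to the deepest recurrence-lineage node
still present in the primary, divided by the primary's longest
root-to-tip lineage. When the primary hosts several subclones the
longest primary lineage is used as denominator; the modal lineage is a
defensible alternative and would give smaller denominators. The
recurrence-specific excess is 100 × (private-to-recurrence −
private-to-primary) / all-substitutions-in-primary and may be negative.
Indel spectrum shifts (deletion vs insertion, deletions ≥ 5 bp) are
tested with two-sided Fisher exact tests; odds ratios use a Haldane 0.5
correction when a table cell is empty, and that correction is flagged.

## WGD timing

On tetraploid regions (total copy number 4 — other ploidies are
rejected, as the early/late multiplicity dichotomy is specific to one
duplication), clonal trunk mutations follow a finite binomial mixture:
early-clonal (m = 2, p = 1), late-clonal (m = 1, p = 1) and one
subclonal state per known subclone (m = 1, p from the clustering stage,
rather than free parameters). EM estimates the weights π; since the
component VAFs are fixed, the log-likelihood is concave in π and EM
converges globally — the 10 random restarts kept by best likelihood are
a cheap safeguard. Convergence: max |Δπ| < 1e-8 or 1,000 iterations;
the log-likelihood trace is checked to be non-decreasing on every run.
States with numerically identical expected VAFs are collapsed with a
warning. The relative duplication time is t = 2πₑ/(2πₑ+πₗ): before
duplication each mutation is doubled, so early counts are halved when
converting to time. Confidence intervals are percentile bootstrap over
mutations, 100 resamples by default, clamped to contain the point
estimate.

## Signature refitting

Exposures for a candidate subset are the NNLS reconstruction of the
observed 96-channel spectrum from the catalogue columns (columns sum to
one, so coefficients are mutation counts; their sum matches the
spectrum total within ~2%). The selection score is the Pearson
correlation between observed and reconstructed spectra. The search
evaluates subsets of size 1..7 exhaustively per size. Admissibility:
every selected signature other than the designated clock-like exempt
pair (Signatures 1 and 5 under COSMIC v2 naming) must contribute ≥ 2%
of mutations and ≥ 50 mutations. A size-k best is preferred over the
selected size-(k−1) solution only when r improves by ≥ 0.02, applied as
a best-of-size ladder ascending from k = 1; which smaller model anchors
the comparison is genuinely open, and the nested ladder is the
interpretation implemented. Because a size that fails the improvement
rule ends the ladder, enumeration stops there by default;
`search="full"` forces all sizes. The per-size search is exact: batched
normal-equation solves identify subsets whose unconstrained optimum is
already non-negative (then it equals the NNLS optimum), and the rest
fall back to active-set NNLS on the Cholesky-reduced k×k system. A
branch-and-bound over r was considered and rejected: no sound upper
bound on the Pearson score of a subset's NNLS fit was available that
preserves exact best-of-size results. If no admissible solution exists
at any size the best single-signature fit is returned with a warning
flag. Branches need > 20 substitutions to be analysed.

## Driver annotation

The four oncogenic categories are applied in fixed precedence (canonical
hotspot; oncogene locus with ≥ 3 prior somatic reports; truncating or
hotspot (≥ 2) events in tumour suppressors; silent changes at splice
hotspots), so every mutation receives at most one category. The
hotspot/cancer-gene table is an input, not bundled. Copy-number calls:
amplification strictly above twice genome ploidy, homozygous deletion at
total copy number zero, targeted-panel amplification at mean logR > 1
called on the point estimate with the CI reported; heterogeneity of
targeted amplifications across related samples is flagged for review
rather than auto-called. "Late" driver timing requires the primary site
to be typed (n > 0) and negative by the presence test, so coverage
dropouts cannot masquerade as late drivers. Enrichment between cohorts:
per-gene two-sided Fisher tests, Benjamini-Hochberg q, significance at
q < 0.1.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:
a clone tree with per-sample CCFs (trunk fixed at 1 everywhere, children
never above parents — violations raise configuration errors naming the
branch), purity in [0.1, 1], depth ~ Poisson(mean) with floor 1,
X ~ Binomial(n, f) from the emission model, branch spectra drawn
multinomially from signature mixtures, and optional WGD: with true time
t, trunk mutations are pre-duplication (m = 2) with probability
t/(2−t), the inverse of the timing estimator, and subclonal mutations
are always m = 1. Sequencing error can be exercised through null sites
whose reads are Binomial(n, 0.005). Defaults mirror the study
conditions the pipeline targets: 2–4 samples per patient, mean depths
of tens of reads (whole-genome scale), hundreds to thousands of
mutations per branch, and subclone CCFs chosen per test; where no value
was prescribed (e.g. the distribution of subclone CCFs), uniform draws
respecting lineage monotonicity are used and flagged as arbitrary.

What it does **not** emulate: real trinucleotide genome composition
(positions are uniform on one synthetic chromosome), mapping artefacts,
strand bias, subclonal copy number, overdispersed read counts, FFPE
artefact spectra, or structural-variant breakpoint sequences (SVs are
records with split-read counts only). Passing recovery tests therefore
demonstrates correctness of the inference under the model's own
assumptions, not robustness to real-data artefacts.

The bundled signature catalogue generator produces *synthetic* sparse
96-channel signatures in the COSMIC layout for tests and simulations;
real analyses should load a published catalogue TSV.

## Problem sizes used in the test and acceptance runs

Recovery suites use 20 clustering replicates of ~500 mutations at depth
80 (300 sweeps, 150 burn-in), WGD coverage studies of 50–100 replicates
at 1,000 mutations with 100 bootstrap resamples, and signature recovery
at 3,000 mutations against the 27-signature synthetic catalogue. These
sizes give stable recovery statistics while keeping a full run in the
minutes range on one CPU.

## Known limitations

* The binomial emission ignores overdispersion; real data may need a
  beta-binomial.
* Cluster credible intervals are MCMC-marginal but still conditional on
  the chosen summary partition's cluster membership for the point
  estimate; strongly overlapping clones can bias CCFs toward each other.
* Tree enumeration is exponential in clusters with many mutually
  dominating candidates; practical cases (≤ ~8 clusters) are fine, and
  a hard cap raises an error rather than silently truncating.
* WGD timing assumes uniform mutation rate in molecular time and clean
  tetraploidy; segments at other copy numbers are not used.
* The exhaustive signature search is exact but, at 27 signatures and
  size 7, evaluates ~1.3M subsets (≈ half a minute vectorised); larger
  catalogues need the ladder's early stop to stay fast.
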