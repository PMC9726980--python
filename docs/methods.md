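# Methods

## Scope and data model

cloneweave analyses multi-region tumour sequencing cohorts at the level of
per-variant read counts. Inputs per patient are: somatic mutations with
per-region alt/total read counts and a functional class (nonsynonymous,
stop gain/loss, frameshift/non-frameshift indel, synonymous, noncoding),
region metadata (tumour site, pathology carcinoma content, computational
purity), and copy-number segments with per-segment mean log2 ratios.
Coordinates are 1-based inclusive throughout. Carcinoma content and purity
are deliberately distinct: the pathology estimate gates which regions enter
the analysis (default ≥ 30%, boundary inclusive), while the computational
purity estimate enters the CCF formula.

Non-silent mutations are the five classes nonsynonymous, stopgain,
stoploss, frameshift_indel and nonframeshift_indel; heterogeneity counts
include indels, but indels carry no trinucleotide channel and are excluded
from signature spectra, which are substitution-only by construction.

## Detection rule

Per-variant per-region presence requires alt reads ≥ 3 and VAF ≥ 0.05
(both inclusive). The underlying study-type protocols rarely publish their
exact presence rule, so these defaults are declared, configurable, and
logged; every presence-dependent output is interpreted relative to them.
Mutations detected in no retained region are dropped and counted.

## Cancer cell fraction and clonal status

For VAF `v`, purity `rho`, tumour/normal local total copy number
`CNt`/`CNn` and multiplicity `m`:

    CCF = v * (rho * CNt + (1 - rho) * CNn) / (rho * m)

the standard purity/copy-number correction. Multiplicity is estimated as
`round(v * (rho*CNt + (1-rho)*CNn) / rho)` clipped to [1, max(CNt, 1)].
CCF is clipped to [0, 1.5] to tolerate copy-number misestimates; clip
events are logged. A mutation is *clonal* in a region when CCF ≥ 0.9. The
threshold is a declared default (configurable): at depth 200 a truly clonal
pure diploid het (VAF 0.5) has a CCF sampling s.d. of ~0.07, so 0.9 keeps
> 90% of truly clonal mutations while separating distinctly subclonal ones.
Copy number at a locus is taken from the covering segment of that region
(`CNt = round(2 * 2^log2)`), defaulting to diploid.

CNV gain/loss calls use the strict thresholds log2 > 1 (gain) and
log2 < −1 (loss); a ratio exactly at a threshold is neutral.

## Clone inference

Mutations are clustered across regions with an EM fit of a K-component
binomial mixture on raw read counts. Cluster k has a per-region CCF
`phi_kr`; the alt count of mutation i in region r under cluster k is
Binomial(d_ir, phi_kr * c_ir) with `c_ir = rho_r * m_ir / (rho_r * CNt_ir +
(1 - rho_r) * CNn)`. The binomial likelihood (rather than a Gaussian on CCF
point estimates) gives the correct variance at low depth and lets
undetected regions (0 alt reads) contribute evidence of absence.

The M-step maximises each concave one-dimensional `phi_kr` problem exactly:
closed form when the CCF-to-VAF factor is constant within a region,
bisection on the score otherwise; the observed-data log-likelihood is
therefore non-decreasing across iterations (recorded per fit, asserted in
tests). Initialisation is k-means++-style seeding on naive CCF point
estimates with 10 restarts; everything is deterministic given the seed.
K = 1..8 candidates are compared by BIC with K·R + (K − 1) free parameters
on N·R observations. Clones are reported in decreasing order of total
clonality, so C1 is the trunk-like cluster.

"Clonality" of a clone in a region is its cluster-mean CCF — the fraction
of cancer cells carrying the clone's mutations. Because clones are nested
along the phylogeny, clonalities may legitimately sum above 1 per region
and more than one clone can be *dominant* (clonality > 0.5, strict) at
once; both behaviours match how dominant subclones are counted in
multi-region studies.

## Dual-tumour clonal relationship

Clones from the two tumours of one patient are matched by mutation
identity: a pair of clones matches when it shares at least 5 identical
variants or the Jaccard index of the mutation sets reaches 0.5, with
greedy one-to-one matching by shared count. Labels: 0 matched clones =
"not clonal", 1 = "one subclone in common", ≥ 2 = "clonally related".
Identity-based matching (rather than CCF-profile similarity) reflects that
a physically shared clone carries the same variants in both tumours,
whereas independent tumours of one patient share essentially none.

## Trunk/branch classification and heterogeneity

A mutation present in all retained regions is trunk; in exactly one,
private branch; otherwise shared branch. The heterogeneity frequency
H = (shared + private branch) / (trunk + branch) over a patient's
detected non-silent mutations; the denominator is all patient-specific
mutations, the reading that reproduces the canonical worked example
(1273 branch of 1982 total = 64.2%). Single-region patients are all-trunk
with a logged caveat — one region cannot reveal branching.

Driver subclonality is aggregated per gene: a driver gene counts as
subclonal in a patient when any of its mutations is subclonal in any
region. The high-ITH flag defaults to subclonal-driver fraction ≥ 0.5
(configurable, threshold always reported). Percentages are displayed with
half-up rounding.

## Region phylogeny

Presence patterns (region subsets) are binary characters. When the
patterns are pairwise compatible (any two nested or disjoint — laminar,
given that trunk mutations span all regions) the unique perfect phylogeny
is built, with each pattern's mutation count on its edge and trunk
mutations on the root edge. Otherwise patterns are accepted greedily in
order of mutation support; the rejected patterns' mutations are counted as
homoplasies and attached to the smallest accepted superset. Trees are
exported as Newick with per-edge mutation counts in comments.

## Signature spectra and exposures

Spectra use the conventional 96-channel COSMIC ordering (six
pyrimidine-strand substitution types × 16 alphabetical flanking contexts);
purine-reference substitutions are reverse-complemented. Contexts come
from a precomputed channel or a reference FASTA.

Exposures are fitted by non-negative least squares on counts (not
proportions), with the reconstruction quality reported as the cosine
between observed and reconstructed spectra. No sparsity penalty is applied
— the fit emulates a plain catalogue refit. Per-patient presence of a
signature requires relative exposure ≥ 0.05 (declared default) in at least
one third of the patient's regions, boundary inclusive.

The bundled catalogue is synthetic: seven deterministic sparse-Dirichlet
columns named after the processes most often reported in oesophageal
squamous tumours (Signature_1, _2, _6, _7, _10, _13, _16). It is generated
in code, so no COSMIC download is needed; tests additionally use exactly
orthogonal synthetic catalogues for hand-checkable fits. Users can supply
a real COSMIC v2 file as TSV.

## Association statistics

The two-sided Fisher exact p-value follows the probability-mass ordering:
the sum over all tables with the observed margins whose hypergeometric
probability is at most that of the observed table, with a 1e-7 relative
tie tolerance — the convention used by mainstream statistics packages. The
phi coefficient is `(ad − bc)/sqrt((a+b)(c+d)(a+c)(b+d))`, identical to
the Pearson correlation of the binary indicators. Missing covariates are
excluded pairwise with logged counts. Benjamini–Hochberg q-values come
from the standard step-up rule.

The differential copy-number screen compares per-region mean log2 ratios
between two tumours per genomic bin with an exact two-sided Wilcoxon
rank-sum test, BH correction across bins, and default reporting thresholds
p < 0.01 and q < 0.15. With 3 vs 3 regions the smallest achievable exact
p is 0.1, so small designs need relaxed thresholds or more regions; when a
tumour has a single region the test is infeasible and a
|Δlog2| ≥ 2 fallback rule is applied with a warning.

Two-proportion power supports a pooled normal approximation, an arcsine
variance-stabilised approximation, and a seeded Monte-Carlo estimate in
which each replicate's 2×2 table is tested with the exact Fisher test.
The three can differ noticeably for extreme proportions (e.g. one group at
100%); the Monte-Carlo method is the reference.

## Synthetic cohort generator

The simulator provides ground truth for every downstream stage. Defaults
describe the emulated study design: 18 patients, 4–6 regions per tumour,
1–6 clones, purity 0.3–0.9, Poisson depth around 80× (close to the ~90×
mean tumour coverage of such studies; recovery experiments use 150–200×),
10–30 mutations per clone, and a signature-16 prevalence of 13/18 driving
six binary covariates (drinking, smoking, male, dual primary, relapse,
death) with conditional probabilities taken from the printed cohort
margins.

Clone trees use uniform random recursive attachment. The root occupies all
regions and is fully clonal everywhere (per-region clone proportions are
Dirichlet over occupying clones, summing to 1), so root mutations are
trunk by construction. Each non-root clone occupies a non-empty subset of
its parent's regions drawn preferentially from regions not yet claimed by
its siblings: subclones segregate spatially, which keeps truth presence
patterns tree-compatible, as multi-region sampling of solid tumours
typically shows; overlap arises only when a parent's regions are
exhausted. Alt reads are Binomial(Poisson depth, purity-, copy-number- and
multiplicity-corrected expected VAF). Copy-number events are
whole-chromosome, clonal, at 5% gain / 5% loss rates per chromosome, with
gains at CNt 5–8 (so they exceed the strict |log2| > 1 call thresholds),
losses at CNt 0–1, and mutation multiplicity uniform on {1..CNt} on gained
chromosomes; mutations are placed only on chromosomes retaining at least
one copy. Trinucleotide channels are i.i.d. draws from the patient's
signature mixture through the bundled catalogue. Dual-primary patients get
two independently simulated tumours sharing either zero clones or exactly
one inserted clone whose identical mutation set appears in both tumours.
All randomness flows from one seeded generator with fixed per-patient
substreams; identical seeds give byte-identical fixtures.

What the generator does *not* emulate: subclonal or allele-specific copy
number, sequencing artefacts and strand bias, mutation hotspots and
realistic gene annotation, selection dynamics, and sampling of normal
contamination structure beyond a single purity scalar per region. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the stated generative model, not calling performance on
real reads.

Truth labels for trunk/branch recovery experiments are the clone occupancy
composed with the detection rule (expected VAF at mean depth): a subclone
whose expected VAF sits below the detection threshold in a region is
unobservable there at any depth, so raw occupancy is not a meaningful
target for a presence-based classifier at low purity.

## Problem sizes used in validation

Recovery experiments run at the scales a single-workstation analysis of a
~20-patient cohort would use: clone-count recovery on 25 simulated
patients (5 regions, 150×), dual-tumour relationship recovery on 20
simulated dual patients (150×), exposure recovery on 100 spectra of 1000
mutations, trunk/branch accuracy on 20 patients at 200×, and exhaustive
Fisher verification over all 2×2 tables with N ≤ 30 against an exact
rational enumeration oracle.

## Known limitations

- Clone inference assumes cluster CCFs are free per region; it does not
  enforce tree constraints (pigeonhole/crossing rules), so closely nested
  clones can merge and heavily overdispersed data can split clusters.
- Multiplicity is a point estimate; subclonal copy number is not modelled.
- The differential CNV screen treats regions as exchangeable replicates
  within a tumour, ignoring their spatial correlation.
- The exact Fisher enumeration is for 2×2 tables only.
- Signature fitting is a refit against a fixed catalogue; no de novo
  extraction, bootstrap stability, or COSMIC v3 composite sets.
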