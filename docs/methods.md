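# Methods

This note records the models, conventions, numerical choices, and open
design decisions behind `esccmut`, and what the synthetic-data studies do
and do not demonstrate.

## Record harmonization and QC

Mutation records are MAF-like: 1-based inclusive coordinates, one row per
variant per sample, sample ids prefixed with their source dataset.  BED
capture files are 0-based half-open; all conversions happen at the module
boundaries (`capture` converts once, internally).

**Reference verification.** A record is authentic iff the genome bases at
`[pos, pos + |ref| - 1]` equal its ref allele (case-insensitive).  Pure
insertions (ref `-`) carry no reference claim beyond their anchor, so only
the anchor position is checked.  Mismatches are excluded from every
downstream statistic and reported, never silently dropped.

**Duplicate samples.** Cohorts assembled from published studies can
contain the same tumor twice.  Each sample's profile is its set of
`chrom:pos:ref:alt` keys; all pairs sharing at least one site are scored
by Jaccard index.  Independent ESCC tumors share well under 5% of sites at
typical mutation loads, so the default flagging threshold of 0.5 separates
true duplicates cleanly; it is configurable.  Of a flagged pair we keep
the member from the larger dataset (ties: lexicographically smaller id) —
larger sources tend to carry richer accompanying data.

**Nonsilent classification.** Protein-altering classes (missense,
nonsense, nonstop, start-loss, splice-site, frameshift and in-frame
indels) gate the gene × patient matrix; silent/noncoding classes do not.
Unknown labels warn and count as silent by default (strict mode raises):
inflating denominators is the safer failure.

## Pooled frequencies

Per-dataset gene frequencies get Clopper–Pearson 95% intervals.  Pooling
uses DerSimonian–Laird random effects on the logit scale with
inverse-variance weights; studies at the boundary (0 or all patients
mutated) get a 0.5 continuity correction.  The logit scale keeps the
pooled value inside (0,1) and is the standard default for meta-analysis
of proportions.  The implementation is closed-form; a test cross-checks
it against `metafor::rma(measure="PLO", method="DL")` in R to 1e-8.

## Capture-platform bias

For each variant the signed distance to the nearest capture boundary is
positive inside an interval (minimum 1 at an edge base) and negative
outside (bp to the nearest interval; −∞ if the contig has no intervals).
Indels use their start coordinate.  The bias estimate for a platform is

    % of WGS-derived test SNVs with distance < −200 bp
  − % of platform-sequenced reference SNVs with distance < −200 bp.

The subtraction removes background that appears even in platform-native
data (annotation drift, liftover loss), so the difference isolates what
the platform genuinely cannot see.  The estimate may be negative and is
reported as-is.  Genes whose merged CDS is not fully inside capture are
listed and passed to the prognostic-panel builder as exclusions.

## Driver-gene selection

Mutational density is `(mutation count / patients) / (CDS Mb)` — a
coding-length-adjusted mutation rate.  The numerator uses nonsilent counts
by default: the selection threshold (density ≥ 50) is only consistent
with nonsilent counting, but a `density_numerator="synonymous"` switch
exists for sensitivity analysis.  dN/dS here is the raw
nonsilent/synonymous count ratio: `x/0 = +∞` (passes any finite
threshold), `0/0` undefined (fails selection).  It is a positive-selection
heuristic, **not** the site-opportunity-normalized evolutionary rate
ratio, and is labelled accordingly.

Selection requires all five criteria — frequency ≥ 2%, external
Q ≤ 0.01, external cluster score ≥ 0.2, density ≥ 50, dN/dS ≥ 5 — with an
audit table of per-criterion booleans.  External scores come from
user-supplied per-gene tables (background-mutation and hotspot-clustering
tools are consumed, not reimplemented); a missing score fails its
criterion unless `allow_missing_external` relaxes it to "not evaluable".
Datasets depositing only nonsilent records are removed before these
statistics (explicitly, plus auto-detection: >500 records and zero
synonymous), since they bias density and dN/dS upward for every gene.
The most common transcript per gene (ties → longest CDS) defines CDS
length.

## Mutational signatures

SBS96 channels follow the pyrimidine-strand convention: 6 substitution
classes × 16 flanking contexts, class-major order (`A[C>A]A` … `T[T>G]T`).
Purine-reference SNVs are reverse-complemented with their context.

Extraction is NMF, `V ≈ W·H` with V the sample × 96 counts, by
multiplicative updates on the Frobenius objective (`max_iter` 2000, `tol`
1e-6 relative objective change).  The updates make the objective
non-increasing; the trajectory is retained and asserted in tests.
Signature rows of H are scaled to probability vectors with the
compensating scale folded into W, so exposures stay on the mutation-count
scale; signatures are named sig1… by total contribution descending.

**Rank survey.** Per candidate rank: 30 restarts (seeds `base + 1009·k +
i`), best-of-restarts RSS, and a consensus matrix in which two samples
co-cluster in a restart when they share the argmax-exposure component.
The cophenetic correlation between the consensus dissimilarity and its
average-linkage dendrogram measures stability.  The selected rank is the
`k` before the largest drop in cophenetic correlation (ties → smaller k);
the RSS elbow is reported alongside for manual override.  Survey restarts
run at `max_iter` 500 / `tol` 1e-5: deep enough that memberships at and
below the true rank are stable, while over-fitted ranks remain restart-
dependent — under-converged restarts blur the cliff the selection rule
needs.

Refitting fixed signatures onto any cohort is per-sample non-negative
least squares; zero-count samples get zero exposures and are excluded
from fraction normalization.  Catalog matching is cosine similarity,
with both `A[C>A]A`-labelled and COSMIC Type/SubType catalog dialects
parsed.  Dominant-signature clusters assign each patient to their argmax
relative exposure (ties → lower signature index).  Fitting on a
WGS-discovery subset and refitting on everyone is a pipeline
configuration, not hard-coded.

## Survival and the mutational score

Per-gene effects come from multivariable Cox regression of overall
survival on the nonsilent-mutation indicator, adjusted for age, sex, and
stage (4-level categorical, dummies against stage I).  Complete-case
analysis throughout; Efron approximation for tied event times; Wald
p-values.  Fits are not evaluable (NA with a reason code) when there are
no events, fewer than 10 events, or a constant indicator.

The partial likelihood is maximized by an in-package vectorized
Newton–Raphson solver with step-halving.  Panel construction performs one
fit per candidate gene per stratum (hundreds to thousands of fits), which
is what the solver is built for; tests pin it against `lifelines` (to
1e-5 in coefficients and standard errors, with and without heavy ties)
and against direct Nelder–Mead maximization of the Efron partial
likelihood.

**Panel construction** (training set = patients with survival data):
(1) adjusted Cox per gene overall; (2) the same within early (I/II) and
late (III/IV) subgroups, with stage dropped from the covariates — within
a subgroup the residual stage variation is small and dropping it keeps
small-stratum fits identifiable (configurable); (3) candidates have
overall HR > 1 with p < 0.05 and subgroup HRs both > 1, minus
capture-incomplete exclusions; (4) rank by mutational frequency
descending (ties alphabetical), keep the top n = 8.  The default of eight
balances positive rate against model complexity; a positive-rate-vs-n
report supports choosing differently.  Fewer than n candidates are
returned with a warning, never padded.

The mutational score is the count of mutated panel genes — a gene hit
three times still contributes 1 — banded 0 / 1 / ≥2.  Validation runs
banded KM/log-rank within stage strata, Cox of band dummies against band
0, and per-dataset Cox of score-positive vs 0 adjusted for early/late
stage, keeping datasets with ≥30 survival-informative patients.

## Synthetic-data generator

The toy genome has one contig per gene: padding + contiguous CDS +
padding (no introns) — context extraction behaves exactly as on a real
genome while coordinates stay trivial.  Per gene and patient, nonsilent
and synonymous mutations are Bernoulli draws at the configured
probabilities (a second hit with probability 0.1, producing Multi-Hit
multiplicity); ref alleles always match the emitted genome.  Exome
platform masks hide the 3' tail fraction of every gene's CDS: records at
masked sites are dropped from WES-labelled datasets and kept in
WGS-labelled ones, and the truth matrices reflect what was emitted.

Signature-driven substitutions are drawn per sample as multinomial counts
over the 96 channels from the sample's exposure-weighted mixture.  When
emitted as records, a dedicated `sbs_source` contig is built containing
exactly the trinucleotide each drawn substitution needs, so the SBS96
matrix rebuilt from records equals the drawn counts exactly.  These
records are classified intergenic — they feed signature analysis (which
uses all SNVs) without touching gene-level statistics, mirroring the real
pipeline's split.

Survival times are exponential with hazard
`baseline · exp(Σ log-HR over mutated panel genes)`; censoring is an
independent exponential tuned so a baseline patient is censored at the
target rate (rate 1 censors everything).  Clinical covariates loosely
match the cohort's shape: age ~ round(N(62, 8)), 80% male, stage
multinomial centered on II/III, smoking/drinking Bernoulli; the exact
values do not drive any test.  Default mutation load (81 substitutions
per genome) matches the cohort's median nonsilent count.

**Study-scale defaults** (chosen once; also the scales
`scripts/acceptance.py` runs at):

- *Signature recovery*: 10 replicates × 200 genomes × 5000 mutations from
  4 planted signatures (each concentrated on ~14 of 96 channels), survey
  k = 2…8, 30 restarts.  Exposures are Dirichlet draws with geometrically
  decaying concentration (0.8, 0.44, 0.24, 0.15): a few processes
  dominate most genomes, as in real cohorts, which also makes low-rank
  merges deterministic and rank selection well posed.  Reported: fraction
  of replicates selecting k = 4, mean Hungarian-matched cosine to the
  planted profiles, mean absolute error of refit exposure fractions.
- *Panel recovery*: 20 replicates; training n = 1500 with 8 planted
  prognostic genes (HR 1.6–2.2, frequency 3–8%) among 200 null genes
  (frequency 0.5–4%, matching the observation that non-panel candidates
  sit at ≤3%), ~60% events; held-out test cohorts n = 800 with the same
  truth.  Reported: median planted-gene recall; median held-out band HRs.
- *Cox calibration*: 200 null replicates (n = 500, 10% frequency, no
  effect) for the type-I rate at α = 0.05; 10 replicates of a planted
  HR = 2 gene at n = 3000 for effect recovery.
- *Capture bias*: 50,000 test and reference sites on a 40-block capture
  map; the mask places 2% of test sites >200 bp outside capture, the
  reference carries a 0.3% far-outside background; plus 10,000 random
  boundary-distance cases against an exhaustive interval scan.

**What passing does and does not show.**  The generator draws gene
indicators independently (no mutual exclusivity or load correlation
unless planted), uses exponential baselines (real baselines are not),
plants well-separated signatures (real signatures overlap more, e.g. the
flat-profile ones), and has no annotation error, purity variation, or
variant-calling noise.  Recovery here demonstrates the statistical
machinery is correct and calibrated at realistic scales — not that real
ESCC cohorts will yield these effect sizes, nor that the specific
published gene panels will reappear; reproducing a specific cohort's
headline gene lists requires that cohort's records and survival data.

## Known limitations

- dN/dS without site-opportunity normalization over-calls long genes with
  poor synonymous coverage; it is one of five joint criteria precisely to
  compensate.
- The duplicate screen keys on exact site-allele identity and can miss
  duplicates re-called on different genome builds; records are assumed to
  share one build (liftover is upstream, out of scope).
- Monte-Carlo p-values for >2-level group comparisons use a fixed-seed
  permutation of the chi-squared statistic rather than the network
  algorithm for exact RxC Fisher tests.
- NMF rank selection inherits the fragility of consecutive-difference
  rules when the cophenetic curve is flat; the survey table is always
  reported so the rank can be overridden.
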