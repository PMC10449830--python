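# Methods

This note records the statistical models the package implements, the
conventions chosen where a definition was genuinely open, what the
synthetic generators do and do not emulate, and the numerical edge-case
handling. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Repertoire model and diversity

A clonotype is identified by (CDR3 amino-acid sequence, V gene, J gene)
within a chain; nucleotide sequences are carried but not part of identity,
because all statistics aggregate at the CDR3/VJ level. Input rows sharing
a key are summed. Frequencies are taken verbatim when a table provides
them (immunoSEQ-style percent columns are rescaled), otherwise computed
from counts.

Filtering removes non-productive rearrangements and clones at frequency
≤ 2×10⁻⁵ — at typical bulk sequencing depths of ~10⁵ reads this is the
one-to-two-read floor where PCR/sequencing artifacts concentrate. Whether
frequencies are renormalized after filtering is exposed as a flag
(default on, because every downstream entropy needs a probability
vector). `top_n_subset` breaks frequency ties deterministically by
(count desc, CDR3, V, J) so repeated runs select identical clone sets.

Shannon entropy is in **bits** and clonality is its complement normalized
by log₂ n. A single-clone repertoire has an undefined normalizer; it is
returned as clonality 1.0 (the monoclonal limit) with a warning.
`expanded_clone_frequency` uses a strict inequality ("above 1%").

## Divergence and its decomposition

Jensen–Shannon divergence is computed in **nats** from the KLD definition
with the midpoint distribution; the two log bases (bits for entropy, nats
for JSD) are deliberately not unified because each statistic is defined
on its own scale. Zero-probability categories contribute nothing;
distributions are aligned on the union of categories before comparison.

The VJ flavor weights each (V, J) pair by summed clone frequency — usage
moves with clonal expansion, which is the phenomenon of interest. The
rank flavor is built by truncating both repertoires to the same top-N
(default 700, small enough that deep samples need minimal down-sampling),
renormalizing, and comparing rank-to-rank; a repertoire with fewer than N
clones contributes zero-probability ranks. This rank alignment is one
reasonable construction of a "rank-based divergence" and is this
package's own convention — the construction is not uniquely determined by
the name, and alternatives (e.g. comparing sorted vectors after binning)
would differ in detail.

The decomposition regresses JSD_VJ of the top-700 subsets on JSD_RANK of
the same subsets across a cohort of paired samples (OLS; R², slope,
two-sided p). High R² means divergence is explained by clone-size
re-weighting; VJ-usage turnover that rank statistics cannot see drives
R² down.

## Antigen-signature partitioning

Matching is exact CDR3β string equality against the signature set.
Inferring antigen specificity from the β chain alone is an approximation
(distinct TCRs can share a CDR3β); fuzzy or motif matching is out of
scope. Signature mass is reported on the pre-renormalization scale;
the matched and unmatched sub-repertoires are renormalized before any
clonality computation. Jaccard overlap of signature-matched sets uses
the CDR3β-only key by default (the level at which the signature is
defined), with a (CDR3β, V, J) key available; an empty union returns 0
with a warning.

## Gene-signature scoring

Cluster signatures intersect two filters: single-cell markers
(log₂FC > 0.5, adjusted p < 0.01, optionally > 60% of cluster cells
expressing) and bulk up-regulation in treated tumors (FC > 1.3, adjusted
p < 0.01). Two printed-source quirks are resolved as follows and exposed
as parameters: a "> 0.01" significance threshold is read as "< 0.01"
(consistent with every other threshold in the source analyses), and
"odds ratio < −1.5" — impossible for an odds ratio — is read as
reciprocal depletion, OR < 1/1.5.

The enrichment score is the log₂FC-weighted mean of log-scale expression
over signature genes present in the matrix; missing genes are dropped
and n reduced (logged), with raw log-scale expression as the default
input (a z-scored variant is a caller-side transform). Scores entering
Cox models are standardized to mean 0, sd 1 (sample sd). Combined
signatures take the union of genes, keeping the largest |log₂FC| for
duplicates. The fixed 21-gene activated-cDC1 list ships as packaged data
and is scored as an unweighted arithmetic mean with a two-sided Welch
t-test between groups.

Composition enrichment runs a two-sided Fisher exact test per 2×2 table
with BH-FDR across the supplied family; the reported OR is the sample
cross-product ratio with a Haldane–Anscombe 0.5 correction applied only
when a zero cell occurs (the p-value is never corrected). Group balancing
retains min(group sizes) cells per group (seeded, without replacement)
before pooled analyses, so no treatment group dominates clustering by
abundance.

## Survival association

The log-rank statistic is implemented directly from the risk table
(observed minus expected events at each distinct event time, with the
hypergeometric variance), because it is simple enough to oracle-test
exhaustively. Cox models are delegated to lifelines (Efron tie handling,
Wald CIs); median splits assign ties to "low". AJCC stages map to 1–4
with letter substages collapsing to their numeral. Records with missing
covariates are dropped (complete-case), with counts logged.

## Tumor response

Volumes use the ellipsoid approximation length × width² × π/6 (mm³); RTV
normalizes to the randomization-day volume. The five response rules
overlap as printed (a complete-response trajectory also satisfies the
partial-response condition), so the classifier applies the precedence
MCR > CR > PR > SD/PD, the clinically natural ordering by response
depth; "end of study" is the last recorded timepoint, so early exits are
classified on available data. The classifier is total on nonnegative RTV
vectors (fuzz-tested against an independent rule-by-rule oracle).
Abscopal experiments sum primary and secondary volumes day-by-day before
RTV.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed).

*Repertoires*: clone weights are i.i.d. shifted-Pareto (tail index 1.5 by
default), giving the heavy-tailed clone-size distributions typical of TCR
repertoires; a symmetric-Dirichlet alternative provides evenness control.
VJ pairs are drawn independently of clone size from geometric-decay usage
pools (20 V × 12 J by default). CDR3s are random 9–17-mers with collision
checking — no V(D)J recombination model, no sequence similarity
structure. Sequencing is multinomial read sampling, which is what makes
the 2×10⁻⁵ filter meaningful. Signature clones are planted with an exact
total mass, so recovery is checkable to sampling error.

*Treatment effects*: two identity-preserving (clonality-only) mechanisms —
a power tilt f → f^β, and multiplicative expansion of a random clone
subset — plus recruitment of novel clones. The paired-cohort generator
uses the tilt (β ~ U(1.02, 1.35) per mouse) as its re-weighting
mechanism: random-subset expansion leaves a substantial idiosyncratic VJ
component (which clones expand is random), which blurs the
re-weighting/recruitment contrast the decomposition is designed to
measure, whereas the tilt couples rank and VJ divergence tightly.
Recruitment draws each mouse's recruits from a concentrated VJ pool (a
few random V and J genes) with recruited mass log-uniform over 0.3–3×
the mean clone mass — an antigen-focused recruitment wave. These are
phenomenological knobs, not a model of T-cell priming.

*Expression studies*: log-scale baselines U(4, 10) per gene, treated-group
shifts of effect_scale × weight on planted genes, i.i.d. Gaussian noise.
The emitted bulk DE table is computed from the simulated matrix itself
(per-gene difference of means, Welch p, BH adjustment); the single-cell
style table carries the planted weights as strong markers against null
background genes. Real expression data have correlated genes,
mean-variance structure and batch effects; none are modeled, so passing
round-trip tests shows the filters and scoring are self-consistent, not
that they are robust to those artifacts.

*Survival cohorts*: exponential event times with rate
baseline × exp(β·score) (exact proportional hazards), independent
exponential censoring, and decoy covariates with no hazard effect. The
calibration scenario used by the acceptance checks is log-HR = ln 2 on a
standard-normal score at n = 500 with censoring at the baseline event
rate (roughly half the cohort censored, as in typical clinical cohorts);
Wald-interval coverage is nominal there. With essentially no censoring
and the same strong effect, coverage dips to ~0.93 — a finite-sample
property of Wald intervals under heavy effect skew, worth knowing when
interpreting tight CIs on strong scores.

*Growth series*: each response category has a canonical RTV archetype over
eight post-randomization timepoints; jitter perturbs nonzero points
multiplicatively and then clamps them so the intended category is
preserved by construction (jitter 0 returns the archetype exactly).

## Problem sizes

The simulation-based checks run at: 24 mice × 2000 clones × 10⁵ reads for
the decomposition; 50 repertoires of 1000 clones at depth 10⁵ for planted
mass; 200 cohorts of 500 for CI coverage and 1000 cohorts of 100 for
log-rank calibration; 10⁴ fuzzed trajectories for the classifier; 1000
random instances per formula oracle. These sizes give Monte Carlo error
comfortably inside every asserted tolerance while keeping the full suite
in the tens of seconds.

## Known limitations

- CDR3β-only antigen matching (see above); no paired-chain support.
- The rank-divergence construction is a convention (documented above),
  not a uniquely determined definition.
- No rarefaction or richness estimation; diversity statistics assume the
  filtered frequency vector is the repertoire.
- Cox diagnostics are limited to convergence checks; no proportional-
  hazards testing or competing risks.
- The growth classifier takes measurements at face value; it does not
  model measurement error beyond what the caller provides.
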