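# clonoshift

Quantitative analytics for preclinical radio-immunotherapy studies that
read out treatment effects through the T-cell compartment: longitudinal
TCR-repertoire statistics, antigen-signature partitioning, gene-signature
enrichment scoring with survival association, cell-composition enrichment,
and tumor-response classification. It is aimed at immunogenomics analysts
who have clonotype tables, differential-expression tables, clinical
expression cohorts and caliper measurements in hand, and want the
statistics between them to be reusable, tested and reproducible — with a
synthetic-data layer so every stage can be exercised without any deposited
data.

## What it computes

**Repertoire diversity.** For a sample with clone frequencies *fᵢ* over
*n* unique clones (clones keyed by CDR3 amino-acid sequence + V/J genes),

```
Clonality = 1 − H / log₂(n),    H = −Σᵢ fᵢ log₂ fᵢ
```

so 0 is a perfectly even repertoire and 1 a monoclonal one; plus the
cumulative frequency of the top-k clones and of all clones above 1%.
Vendor dialects (iRepertoire-, immunoSEQ- and AIRR-style TSV) are read
into one canonical clone table; clones at frequency ≤ 2×10⁻⁵ and
non-productive rearrangements are filtered before analysis.

**Paired divergence.** Between a mouse's pre- and post-treatment
repertoires, the Jensen–Shannon divergence (natural log, bounded by ln 2)

```
JSD(P‖Q) = ½ KLD(P‖M) + ½ KLD(Q‖M),   M = (P+Q)/2
```

is computed in two flavors: over VJ-gene-pair usage (`jsd_vj`) and over
the rank-frequency vector of the top-700 clones with identity discarded
(`jsd_rank`). Regressing the VJ divergence of the top-700 subsets on the
rank divergence attributes repertoire turnover to clonal re-weighting
(R² near 1) versus recruitment of new VJ usage (R² collapses).

**Antigen signatures.** A set of CDR3β sequences defining reactivity to
one epitope (e.g. the AH1 epitope of 4T1 tumors) partitions a repertoire
into matched/unmatched sub-repertoires, with signature mass, per-partition
clonality, and the Jaccard overlap of the matched clone sets between
paired compartments (tumor vs draining lymph node).

**Signature scoring and survival.** Cluster gene signatures are built by
intersecting single-cell and bulk differential-expression filters
(single-cell log₂FC > 0.5 and bulk FC > 1.3, both at adjusted p < 0.01);
a sample's enrichment score is the weighted mean
`ES = Σᵢ GEᵢ·log₂FCᵢ / n` over the n signature genes present. Scores are
related to outcome by median-split log-rank tests and multivariable Cox
proportional-hazards models (age, menopausal state, NPI, scaled CD3E for
breast-cancer cohorts; age, numeric AJCC stage, scaled CD3E for
melanoma). Cell-subset composition shifts between treatment groups are
tested per subset with two-sided Fisher exact tests under BH-FDR, calling
enrichment at q < 0.05 and OR > 1.5 (or < 1/1.5 for depletion).

**Tumor response.** Caliper volumes (`length × width² × π/6`) become
relative tumor volumes (RTV = Vₜ/V_ref, reference = randomization day)
and a 5-category call: PD, SD, PR (RTV ≤ 0.5 at least once), CR (RTV = 0
at least once), MCR (RTV = 0 at the end of study).

**Synthetic data.** `clonoshift.simulate` generates all of the above with
known ground truth: power-law repertoires with VJ usage and planted
signature clones, clonality-only and recruitment treatment effects with
multinomial resequencing, planted expression signatures, proportional-
hazards survival cohorts, and growth trajectories per response class.

## Worked example

```
$ clonoshift simulate repertoire --n-clones 400 --depth 50000 --seed 3 --out pre.tsv
$ clonoshift ingest pre.tsv --dialect canonical --out pre_f.tsv
$ clonoshift diversity pre_f.tsv
sample_id  n_clones  shannon_entropy_bits  clonality  top_k_cumfreq  expanded_cumfreq
sim        400       8.06558591250062      0.06689957173954053  0.1593  0.21224
```

A 400-clone power-law repertoire sequenced to depth 50 000 carries about
8.07 bits of entropy against a maximum of log₂ 400 ≈ 8.64, i.e. clonality
0.067 — a fairly even repertoire; its ten largest clones hold 15.9% of the
reads and clones above 1% hold 21.2%. Comparing it with an independently
drawn repertoire (a maximally dissimilar "pair"):

```
$ clonoshift divergence --pairs pairs.tsv --n-top 300
mouse_id  chain  jsd_vj   jsd_rank  jsd_vj_top  n_top
sim       TRB    0.2351   0.0091    0.2755      300
```

The two samples have near-identical clone-size *shapes* (rank divergence
0.009 nats) but unrelated VJ usage (0.24–0.28 nats), the signature of
turnover rather than re-weighting. Finally, growth-series classification:

```
$ clonoshift simulate growth --category PR --seed 2 --out g.tsv
$ clonoshift response g.tsv --ref-day 11
animal_id  category
PR-2       PR
```

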