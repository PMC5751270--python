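# Methods

## Design model

An experiment is 24 single-replicate libraries: {cold, drought} ×
{FL, FEL, RT} × {control, t1, t2, t3}, with treatment times 6/24/48 h
(cold) and 4/6/10 d (drought). Each (stress, tissue) pair forms a
*condition series*; by default the series' time-index-0 sample is the
control for all three treatment comparisons. Time-matched parallel
controls can be represented instead by supplying a sample sheet in
which each (stress, tissue) keeps one control — the pairing is a
property of the sheet, not of the code path.

## Normalization

TMM scale factors follow the standard formulation. For sample *j*
vs reference *r* (library sizes N), genes with a zero count in either
sample are excluded; the rest contribute

- M_g = log2((x_gj/N_j) / (x_gr/N_r)),
- A_g = ½·(log2(x_gj/N_j) + log2(x_gr/N_r)),
- weight 1/v_g with v_g = (N_j−x_gj)/(N_j·x_gj) + (N_r−x_gr)/(N_r·x_gr),

the asymptotic binomial variance of M_g. Genes are kept when their
M-rank lies inside the central 40% (30% trimmed per tail) *and* their
A-rank inside the central 90% (5% per tail); ties share average
ranks. The factor is 2^(Σw·M / Σw), snapped to 1 when
|log2 factor| < 1e-10, and all factors are rescaled to geometric
mean 1. The reference sample is the one whose 75th-percentile count
fraction is closest to the mean across samples (lexicographically
smallest sample id on ties). Trim fractions and the reference are
arguments. The implementation agrees with a brute-force enumeration
oracle to 1e-9 on random instances and with edgeR's
`calcNormFactors(method="TMM")` to 1e-6.

CPM uses the TMM-adjusted library size:
`cpm = count / (library_size × factor) × 1e6`, with library size
defaulting to the column sum. CPM — and therefore every downstream
call — is invariant under scaling a library's counts and size by a
common constant.

**Expressed genes.** A gene is expressed in a sample when CPM
strictly exceeds 10; in a tissue (under one stress) when it is
expressed at ≥ 1 of the four time points. The CPM > 10 cut is applied
to TMM-scaled CPM throughout, one consistent choice where either
scaled or unscaled CPM would be defensible.

## Differential-expression rule

All comparisons are strict, mirroring the ">" / "<" form of the
thresholds:

- *ratio rule*: both CPMs > 10 and treatment/control > 3 (up) or
  control/treatment > 3 (down);
- *on/off rule*: one CPM < 10 and the other > 30, direction toward
  the expressed side.

A series call requires ≥ 2 of the 3 time-point candidates to share a
direction; that direction is the call. Mixed candidates where neither
direction reaches 2 are not DE — directional consistency is required
because the downstream group taxonomy is defined in terms of per-series
up/down status, and a gene significantly up at one time point and
down at another has no coherent series direction. A 3-candidate
series can never support both directions at the 2-of-3 level, so the
rule is unambiguous. `min_support` and all thresholds are
configurable (`Thresholds`).

The fold change for the ratio rule divides raw TMM-CPM values without
a pseudocount: both operands exceed 10, so the division is safe.

## Set partitions and percentages

Venn partitions are exact set algebra. Two-set percentages are taken
over the union of the two sets and rounded half-away-from-zero at one
decimal — the convention that reproduces printed specificity tables
of this kind (e.g. 1951/3180 → 61.4). `proportion` exposes the same
rounding for general bookkeeping.

## Pattern taxonomy, fold-change profiles, clustering

A DE gene's pattern is its up/down/none status across the six series,
in the fixed order c.FL, c.FEL, c.RT, d.FL, d.FEL, d.RT. Non-empty
patterns partition the DE universe (each gene in exactly one group;
at most 3^6 − 1 = 728 patterns). Group labels G1, G2, … are
regenerated deterministically — sorted by number of responding series
ascending, then slot-wise with down before up — and are stable under
permutation of the input; they are a labelling scheme, not a fixed
vocabulary.

The fold-change profile holds log2((treat+c)/(ctrl+c)) per DE
(gene, series) at each of the 18 treatment columns, pseudocount
c = 1 CPM so on/off genes stay finite; cells of non-DE series are
forced to log2(1) = 0. The pseudocount affects display/clustering
values only, never rule evaluation. Columns are per time point
(`c.FL.6h` … `d.RT.10d`) rather than per-series summaries, matching
how such heatmaps label their axes. Clustering is agglomerative
complete linkage on Euclidean distances (scipy), verified against an
O(n³) naive implementation; merge heights are non-decreasing.

## Enrichment

For a DE set of size n in a background of size N, a bin with K
background members and k DE members gets the one-sided p-value
P(X ≥ k), X ~ Hypergeometric(N, K, n) — Fisher's exact test for
over-representation. Bins are tested at every hierarchy level with
descendant memberships rolled up into parents, skipping bins with
K < 2. The background is the set of genes expressed under the
relevant stress rather than the whole genome, so detectability alone
cannot drive enrichment; it is an argument. Multiplicity is handled
by Benjamini–Hochberg step-up FDR at 0.05 within each tested family —
a standard default where no specific procedure is dictated. Genes in
several bins count once per bin.

## Co-expression

"Co-expressed" is operationalised as Pearson r of log2-FC profiles
over the 18 treatment columns, threshold r ≥ 0.9, positive
correlations only, computed for seed–seed and seed–other pairs
(seeds = genes of interest, e.g. TFs). All three choices are
arguments; FC profiles are used rather than raw CPM trajectories so
that edges reflect concordant *responses*, not shared baseline
abundance. Zero-variance profiles form no edges. Under independence,
length-18 normal profiles clear |r| ≥ 0.9 with probability well below
5e-3, so chance edges are rare at this design size.

## Synthetic data

The generator draws NB counts (gamma–Poisson; variance μ + αμ²) with
mean `baseline_cpm × library/1e6 × effect`, where effect is the
planted fold change in planted (gene, series, time point) cells and 1
elsewhere. Defaults — chosen once as the study conditions:

| parameter | default | why |
|---|---|---|
| `n_genes` | 20,000 | with 10% silent gives ≈ 17.5k expressed per stress, the design's scale |
| `fraction_silent` | 0.10 | near-zero baseline tail (exponential, mean 0.5 CPM) |
| `library_size_mean` | 3.5e6 | ≈ 84M mapped reads over 24 libraries |
| `library_size_sigma` | 0.15 | modest lognormal spread between libraries |
| `baseline_log_sigma` | 0.8 | lognormal abundance spread; after rescaling baselines to sum to 1e6 CPM this alone sets the expressed fraction (~96% of active genes) |
| `dispersion` α | 0.05 | typical bulk RNA-seq overdispersion; the rule-based caller must tolerate it |
| planted FC | 8 | a strong, clearly callable response |

Baselines of unplanted active genes are rescaled so all baselines sum
to 1e6 — baseline values are then true control CPMs, which makes the
planted windows exact: on/off "up" cohorts draw control baselines in
(max(2, 36/FC), 8) CPM so control < 10 and treatment > 30; planted
"down" (ratio) cohorts draw baselines in (12·FC, 40·FC) CPM so the
repressed value stays above the expressed threshold. The default
planted mix (≈1,550 genes) contains per-series up/down cohorts,
per-series on/off cohorts, within-stress shared cohorts and
cross-stress shared cohorts. A ramp option restricts a cohort's fold
change to chosen time points; a single-time-point ramp must *not* be
called, exercising the replication rule.

`generate_category_map` assigns every gene one two-level bin and
loads one designated bin with planted DE genes at a configurable odds
ratio (odds 1 = null, giving uniform Fisher p over replicates; large
odds = positive control).

What the generator does **not** emulate: time-trend shapes other than
constant or ramp, correlated co-regulation beyond the planted shared
cohorts, genewise dispersion variation, GC/length biases, or
time-matched parallel controls drifting from the t0 control. Passing
recovery tests therefore demonstrates correctness of the calling
logic under the stated noise model, not robustness to every artefact
of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale simulations
(500–2,000 genes) for recovery and null-rate checks and one full
20,000-gene run for the end-to-end summary. Brute-force oracles run
at 50 genes × 3 samples (TMM), N ≤ 200 (Fisher) and 20 rows
(linkage). Determinism: a fixed generator seed reproduces matrices
byte-for-byte; pipeline artifacts are sorted, floats written at 6
significant digits; group labels and the TMM reference have explicit
tie-breaks.

## Known limitations

- The rule-based caller has no error-rate guarantee; its false-positive
  behaviour is characterised empirically (< 1% of genes under the
  null at default thresholds, dispersion 0.02).
- With a single shared control per series, an outlier control library
  biases all three time-point comparisons in the same direction; the
  2-of-3 rule does not protect against this.
- Fisher's test treats genes as exchangeable; co-expressed gene
  blocks violate its independence assumption, as in any
  over-representation analysis.
- Venn percentages use the 2-set union denominator; other published
  conventions (per-set denominators) would need the exposed
  `proportion` directly.
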