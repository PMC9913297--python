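# Methods

## Ct model

Array cards report one cycle-threshold (Ct) per gene per sample per
platform; lower Ct means more template RNA.  Reactions that never cross
threshold ("Undetermined") are stored at the maximum cycle count, Ct = 40,
and flagged undetected, which keeps all downstream arithmetic total while
preserving the information that the gene was absent.  Detection uses the
conventional Ct ≤ 35 limit; expression tiers partition the axis as
HIGH (< 25), EXPRESSED ([25, 35]) and NOT_DETECTED (> 35).  The published
cut-offs ("< 25", "25–35", "> 35") leave the two boundary points formally
unassigned; both are assigned EXPRESSED here so the partition is exhaustive.

**Global-mean normalisation.** ΔCt(g) = Ct(g) − mean(Ct over the analysis
panel).  Two scopes are provided: *joint* (default) pools all of a sample's
cards into one global mean, which is what makes targets on the three array
platforms directly comparable; *per-card* normalises each platform
separately.  The mean includes undetected genes at their stored Ct of 40 by
default — the global-mean convention has no published exclusion rule — with
a `detected_only` flag for the alternative.  Endogenous controls
(PPIA, 18S, GAPDH, GUSB, HPRT1 by default; configurable) are excluded from
the analysis panel.  ΔCt sums to zero over the panel by construction, and
is invariant to adding a constant to every Ct; both properties are tested.

**Self-renewal metrics.** Spheroid-forming efficiency = wells containing a
spheroid / wells seeded with a single cell × 100; colony-forming efficiency
= colonies / cells seeded × 100.  The companion Poisson helper gives the
single-cell seeding occupancy P(X ≤ 1) = e^−λ(1 + λ) and solves for the λ
achieving a target probability (λ ≈ 0.532 for 0.9).  The conditional
variant P(X = 1 | X ≥ 1) is provided as well, since "probability of a
single cell" is ambiguous between the two readings; neither is asserted as
the only one.

## Moderated differential expression

With two biological replicates per group the per-gene residual degrees of
freedom are 2, so per-gene variances are extremely noisy and an ordinary
t-test is unusable — the reason moderated linear models are standard for
array data.  The implementation follows the classical empirical-Bayes
recipe: per gene, a two-group fit gives the mean difference and pooled
residual variance s²; the prior (d₀, s₀²) is estimated by method of moments
on log s² (digamma/trigamma moment equations, trigamma inverted by Newton
iteration); the posterior variance s̃² = (d₀s₀² + df·s²)/(d₀ + df) feeds a
t-statistic on df + d₀ degrees of freedom.  When the observed
log-variances are no more dispersed than χ² sampling alone explains, d₀ is
infinite and all genes share s₀² (normal tails, implemented as df = 10⁶).
Genes constant in both groups yield diff = 0, t = 0, p = 1; zero sample
variance elsewhere is absorbed by the prior.  `prior_df=0` disables
shrinkage and exactly reproduces the ordinary pooled t-test, which the test
suite uses as an independent cross-check.

Q-values are Benjamini–Hochberg, delegated to
`statsmodels.stats.multitest` and verified against a brute-force step-up
oracle on permutations.  The significance rule is Q < 0.1 AND
|ΔCt difference| > 2 cycles AND the gene passes the detection filter.  Two
documented ambiguities are resolved as config switches:

* *Ct exclusion*: the published legends state both "Ct > 35 in both
  populations" and "Ct > 35 in 2D cells"; the stricter both-populations
  rule is the default (`ct_exclusion_mode="both"`), the 2D-only variant is
  selectable.
* *"Mean Ct difference"*: computed on global-mean ΔCt (matching the
  plotted "difference in ΔCt"), not raw Ct.
* *BH scope*: Q-values are computed jointly across the platforms by
  default; per-platform adjustment is available by running the stage per
  card.

The detection-set (Venn) analysis counts genes not detected in both
populations, uniquely undetected in each, detected in both and highly
expressed in both, with percentages of panel size rounded half away from
zero (integer percentages are what the comparison reports).

## Targets and network structure

The target set is the case-folded union of the DE-increased genes
(source 2) and the patient-derived CSC list (source 1); genes in both carry
both source codes.  Network statistics on the association edge list use
networkx: degree within the target universe (duplicate/reversed edges
collapse; all four evidence channels — experimental, curated,
co-expression, text-mining — count by default, with a channel filter,
since the published degree claim does not restrict evidence type), and
"mutually interacting" cores as maximal cliques of size ≥ k.  Because
"interact" could also mean merely connected, connected components are
emitted alongside cliques; the pipeline summary reports both and asserts
neither as the intended reading.  The clique finder is verified against an
exhaustive subset-enumeration oracle on graphs of ≤ 12 nodes.

The packaged 21-gene panel (`data/es_csc_targets_synthetic.txt`) is a
synthetic stand-in: members recoverable from the published panel appear by
symbol, the rest are TGTX-prefixed placeholders; the pipeline never
hard-codes the list into logic.

## Repurposing

Interaction scores are computed over whatever table is supplied — the full
database snapshot by default, since restricting the partner-count averages
to the disease slice is a choice the source description leaves open (a
pre-filtered table can simply be passed in).  Drug names are case-folded
and stripped with an optional synonym map; no fuzzy matching.  Trial
phases are the ordered enum Other < Phase 1 < Phase 1/2 < Phase 2 <
Phase 2/3 < Phase 3 < Phase 4, so "Other" never wins the maximum when a
numbered phase exists.  A trial is an oncology trial when its cancer-type
field is non-empty; the support score is the unweighted count of the five
ReDO-style evidence categories (weights are a config hook, never the
default).  The candidate table includes single-target drugs by default;
`min_targets=2` reproduces the stricter ">1 target" filter used for the
licence lookup.  Per-drug target lists are restricted to the prioritised
set, and each target's `has_drug` flag is set as a side effect.

## Synthetic data

The generators emulate the study design: a 140-gene panel split over three
card platforms, two biological replicates per culture condition, baseline
Cts uniform on [22, 34], planted condition effects of −3 cycles on ABCG1
and POU5F1 (a 3-cycle Ct drop ≈ 8-fold RNA increase in 3D) and 0.5-cycle
Gaussian technical noise — the effect/noise regime in which the moderated
test must operate at n = 2.  Cts above 40 are clipped and flagged
undetected, mirroring ingestion.  Interaction tables are sparse bipartite
(each pair kept with probability `edge_density`; geometric publication
counts, uniform 1–5 source counts; every drug keeps ≥ 1 edge); trial
registries draw per-drug counts from Poisson(`trial_rate`) with phase /
status / cancer-type vocabulary matching public registers, and a
configurable fraction (default 0.35) of records are oncology trials.

Randomness is split from one root seed via `numpy.random.SeedSequence`
with a fixed `spawn_key` per generator, so adding a generator never
perturbs existing streams and equal seeds give byte-identical bundles.

What the simulation does *not* model: primer-efficiency differences,
inter-platform batch effects, correlated technical replicates, heavy-tailed
Ct noise, and the literature biases of real interaction databases
(publication counts on real edges are far more skewed than geometric).
Passing tests therefore demonstrate correctness of the arithmetic and the
claimed operating characteristics under clean Gaussian conditions, not
performance on real cards.

The *engineered* bundle is a deterministic fixture for end-to-end checks:
the 21-gene panel with a hand-built drug roster covering exactly 13 targets
(62%), a licence list marking 4 of the 19 drugs as cancer drugs, and an
association network in which one hub gene touches 10 partners and
{POU5F1, KIT, CAV1, ITGB1, CD44} form a complete 5-clique.

## Problem sizes and numerics

The validation suite uses: 200 replicate null simulations of 1000 genes at
n = 2 per group for the false-discovery share; 200 replicate 140-gene
simulations with ten ±3-cycle planted effects for recovery; 100 random
interaction tables of ≤ 20 drugs × 20 genes against the brute-force scorer
(tolerance 1e-12 relative); all 120 permutations of five 5-element
p-vectors for BH; 1000 random cards for ΔCt conservation (|Σ ΔCt| < 1e-9);
and exhaustive clique enumeration on graphs of ≤ 12 nodes.  These sizes
give stable Monte-Carlo estimates while keeping the whole suite in seconds.
Floating-point ties in BH resolve by stable input order; clique output
order is size-descending then lexicographic; association-score ties in
polypharmacology expansion break alphabetically.

## Known limitations

* The DE model is strictly two-group, single-factor; no array weights or
  duplicate-spot correlation.
* Database snapshots enter as TSVs with documented schemas; no live
  queries, no patent-status inference.
* The headline counts of a real screen (hundreds of drugs against the
  panel) depend on versioned external databases and are out of desk-scale
  reach; the engineered fixture reproduces the coverage *ratio*, not the
  absolute drug counts.
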