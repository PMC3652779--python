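# Methods

This note documents the statistical model behind `ionoscreen`, the choices
made where the design was genuinely open, and what the simulator-backed
tests do and do not demonstrate about real screen data.

## Measurement model and normalization

ICP-MS well concentrations are positive and technical effects (plate
position in the run, instrument day, culture density) act multiplicatively,
so the pipeline works on the log scale for correction and returns to the
linear concentration scale for phenotypes. The assumed structure of an
OD-normalized well value for gene *g*, element *e*, on plate *p* of day *d*
is

    log c = mu_e + beta_ge + delta_d + gamma_p + eps

with gene effect `beta_ge`, day effect `delta_d`, plate-within-day effect
`gamma_p` and replicate noise `eps`.

The published screens were normalized with a linear mixed-effects model
whose full specification lives outside this codebase; `ionoscreen`
implements a control-anchored surrogate with the same intent (remove
technical day/plate variation using the four control strains present on
every plate):

- per element, day effects are estimated as fixed effects — the mean of the
  day's control log-values minus the grand control mean;
- plate-within-day effects are shrunken random effects: the residual plate
  control mean times `lambda = B/(B + W/n)`, the empirical-Bayes weight
  built from the method-of-moments between-plate variance `B` (floored at
  zero) and the pooled within-plate control variance `W` with `n` controls
  per plate. With noise-free controls `lambda -> 1` and plate offsets are
  recovered exactly; with no real plate effects `lambda -> 0` and the
  correction degenerates to the day mean.

Corrections are subtracted on the log scale (division by `exp(c_p)`), so
phenotypes stay in linear concentration units: `D_ge` is the mean and
`sigma~_ge` the sample sd (n−1) of the corrected replicate values. Whether
the original analysis summarized on the log or linear scale is not
recoverable; linear-after-log-correction is this package's documented
choice, and only the correction step assumes log-normality. Genes with a
single replicate have no scale estimate; they are flagged and excluded
from testing. A test asserts that correction never increases the
between-plate variance of control values.

## Significance testing

The moderated Z is `(D - median)/(1.4826 * MAD)` per element across genes.
The MAD-based denominator makes the statistic insensitive to the very
outliers the screen is looking for; 1.4826 rescales the MAD to a
consistent sd estimate under normality. Two identities are enforced to
1e-9 in tests: per element, `median(Z) = 0` and `median|Z| = 1/1.4826`. An
element with zero MAD across genes (possible only in degenerate synthetic
data) has no scale and its Z column is left undefined with a warning.

Z maps to p through the two-sided standard normal — the conventional
companion of a robust Z; the mapping is a parameter (`scipy.stats.norm` is
the default) because the original choice is not documented.
Benjamini–Hochberg runs jointly over all gene×element cells of a dataset,
not per element, because the screens quote a single cutoff pair per
dataset. The reported cutoffs are the observed extremes (largest
significant negative Z, smallest significant positive Z), which reproduces
their slight asymmetry without any asymmetric test; ±inf sentinels mark an
empty side.

The annealing filter re-examines replicate-level values: pooled across all
genes per element, take median `m_e` and raw MAD; a candidate call passes
iff ≥75% (inclusive, so 3 of 4 passes) of the gene's replicates deviate
from `m_e` in the call's direction by ≥2×MAD. The pooled reading of "all
samples across genes" is deliberate: the filter's reference scale should
describe the population of replicates, not the candidate gene.

`perCh` is implemented exactly as defined — `sigma~*D` recentred by its
across-gene mean, in units of that mean. In the original analysis `D` is a
standardized mixed-model phenotype and `sigma~*D` restores abundance
units; with this package's linear-scale `D` the product mixes location and
replicate spread, which makes `perCh` a noisier effect-size estimate. It
is retained as specified for comparability; its per-element mean is
identically zero, which tests enforce. Group boundaries are inclusive
toward the more extreme group (exactly +100%/−50% is C, exactly ±20% is
B), matching the quoted "≥/≤" band definitions.

## Exhaustive significance clustering

Genes are partitioned by exact equality of the full sign vector over the
panel — all elements, not only significant ones, define the pattern, which
is what makes the 3^E pattern-space count meaningful. Patterns below
`min_size` (default 3) members are reported unclustered. Clusters are
named `CLUSTER_k` by descending size with lexicographic pattern-key
tie-break (the original numbering scheme is not documented). Median
profiles use all elements so sub-threshold trends remain visible; heatmap
ordering is scipy complete-linkage on Euclidean distances, deterministic
given input order. Heatmap bands use strict inequalities at the cutoffs
(a median exactly at the cutoff stays in the non-significant band),
matching the quoted "less than / greater than" colour rules.

## Enrichment

The overlap statistic is the exact upper tail P(X ≥ k) of the
hypergeometric — "at least as extreme as observed" under random draws. It
is summed in log space (log-gamma binomials + log-sum-exp) so p-values
near 1e-10 retain full relative precision; tests verify it against exact
rational enumeration (all universes N ≤ 12, plus the genome-scale case)
and against `scipy.stats.hypergeom.sf`. The universe is always an explicit
caller argument — overlap p-values are meaningless without one, and
published universes are often ambiguous.

Conditional GO enrichment visits terms children-before-parents
(topological order). When a parent is tested, genes annotated to any
already-significant descendant (p ≤ `alpha_cond`, default 0.05,
configurable; the original threshold is undocumented) are removed from the
term's annotation set *and* from the universe for that test. With no
significant children the test reduces exactly to the plain hypergeometric,
which tests assert. Annotations propagate over `is_a` and `part_of` only,
the standard choice; terms annotating fewer than `min_genes` (default 2)
universe genes are skipped. No multiple-testing correction is applied
across terms — raw conditional p-values are reported, as in the source
analyses.

## Networks

Subnetworks are the induced typed subgraph of a BioGRID interaction list
on the tested gene set. A physical and a genetic interaction between the
same pair are kept as two edges (figure legends count them separately) but
the pair contributes nodes once. Isolated tested genes are excluded from
the node set but retained in the denominator of the inclusion rate
(nodes/tested × 100); the published legend wording inverts this ratio, but
the printed 36–54% values force the interacting/tested orientation.
Connectivity is edges/nodes. Edge correlations are Pearson (Spearman
optional) over the two endpoint moderated-Z vectors across the full panel,
with absent cells imputed as 0 — the null of the moderated Z, matching
supplementary tables that blank sub-threshold cells.

## Simulator

`simulate_screen` realizes exactly the structure the normalization stage
assumes, on 96-well plates with the screen geometry (4 fixed control
strains per plate, ≤20 mutants, 3 plates per day, one plate appearance per
replicate batch). Reported concentrations are multiplied by a per-well
OD600 draw so OD normalization is a real step. Defaults, chosen a priori
as plausible for a well-run plate screen and not revisited:

| parameter | default | meaning |
|---|---|---|
| `replicate_noise_sd` | 0.15 | per-well log-scale measurement + biology noise (~15% CV) |
| `plate_effect_sd` / `day_effect_sd` | 0.10 | log-scale technical effects (~10%) |
| `baseline_log_sd` | 0.05 | strain-to-strain baseline spread, fixed per gene |
| `od_mean`, `od_sd` | 1.8, 0.25 | stationary-phase culture density |
| `spike_effect_range` | (2.0, 4.0) | fold-change of true perturbations, sign random |
| `baseline_log_mean` | per element | plausible ppm baselines (P/K/S/Mg high, traces low) |

`baseline_log_sd` is interpreted as *gene-level* variation (a fixed offset
per gene×element reused across replicates): it is the spread the moderated
Z standardizes across. "Zero noise" in degenerate tests therefore zeroes
it along with the other sds (`synthetic_data.noise_free`). Spiked
fold-changes must stay away from 1 so truth signs are well defined. One
master seed spawns six named child streams (spikes, offsets, day, plate,
noise, OD) in fixed order, so changing one draw cannot perturb another.

What the simulator does **not** emulate: instrument drift within a run,
element–element covariance beyond spiked patterns, growth defects coupling
OD to genotype, plate-position (edge) effects, and non-lognormal error
tails. Passing recovery tests therefore show the pipeline is correct and
well calibrated *under its own assumptions*, not that real screens meet
them.

## Operating characteristics and problem sizes

The recovery property asserted in tests and recomputed by
`scripts/acceptance.py`: with 60 genes, 4 replicates, 3% spike rate and
2–4× fold-changes, aggregated over 20 simulated screens, sign-correct
recall is ≥80% (observed ≈100%) and empirical FDR ≤0.10 (observed ≈0.07).
Twenty repeats at 60 genes keep the full suite fast while giving ~500 true
effects to aggregate over; operating characteristics at this size were
indistinguishable from larger runs during development. Null screens (no
spikes) are separately checked to call at most an `alpha + 3·SE` fraction
of cells.

## Known limitations

- The plate correction is a surrogate, not a reimplementation, of the
  original mixed model; absolute agreement with the published per-gene Z
  values is not expected (published cutoff pairs such as (−3.328, 3.473)
  are data-dependent outputs, not constants of the method).
- `perCh` inherits noise from `sigma~` under this package's linear `D`
  (see above); group A/B/C boundaries are sharp, so genes near ±20% are
  sensitive to it.
- The conditional enrichment removes descendant genes from the universe
  per test, one of several "conditional hypergeometric" variants in
  circulation; results for deep, heavily overlapping DAGs can differ
  between implementations.
- BioGRID-snapshot-dependent edge counts are not reproducible and are not
  asserted anywhere; only snapshot-independent metrics are.
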