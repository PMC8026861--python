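# Methods

## Signed literature networks

A relation is a directed assertion `subject → object` with polarity
(`positive`/`negative`), an entity kind per endpoint (gene, small
molecule, disease), and a count of supporting references. Quality
control keeps relations with defined polarity and at least `min_refs`
references (default 3, the conventional evidence floor for
literature-mined edges). When several rows assert the same ordered pair
with conflicting signs, reference counts are summed per polarity and the
majority wins; an exact tie yields polarity `unknown`, which QC removes.
This evidence-weighted majority is the least surprising aggregation rule
when the upstream source does not resolve conflicts itself.

Gene identity is case-insensitive symbol matching (stored upper-case),
with no alias resolution: the analysis operates at the symbol level, and
set accounting counts only entities of kind `gene`. "Regulators" of a
disease are all genes with an edge into it regardless of relation class.

The protective motif extraction scans the shared genes of two diseases
for the two discordant sign patterns: `A ⊣ g → B` (A inhibits a promoter
of B) and `A → g ⊣ B` (A activates an inhibitor of B). Membership is
computed on the aggregated network, so it is invariant to row order and
duplicated rows.

## Mega-analysis model

Per gene and study the effect is the log2 fold-change
`LFC = mean(case) − mean(control)` with unpooled two-sample (Welch)
variance `s²_case/n_case + s²_control/n_control`; Welch is chosen because
the emulated study designs are strongly unbalanced (down to 34 cases vs
4 controls). Both groups need ≥ 2 samples, otherwise the study
contributes no effect for that gene.

Pooling across the k studies containing a gene (minimum k = 2; genes
below that are reported as unanalyzable):

- Cochran's `Q = Σ wᵢ(θᵢ − θ̂)²` with fixed-effect weights `wᵢ = 1/varᵢ`
  and `θ̂` the fixed-effect pooled estimate; `df = k − 1`.
- `I² = 100·(Q − df)/Q`, truncated to 0 whenever `Q ≤ df`.
- Model selection: `Q ≤ df` ⇒ fixed-effect model; `Q > df` ⇒
  random-effects model with DerSimonian–Laird
  `τ² = max(0, (Q − df)/(Σw − Σw²/Σw))` and weights `1/(varᵢ + τ²)`.
  DerSimonian–Laird is the standard closed-form moment estimator and is
  the natural companion of a Q-vs-df selection rule. By construction
  `model = fixed ⇔ Q ≤ df ⇔ I² = 0`.
- `pooled = Σwθ/Σw`, `se = (Σw)^(−1/2)`, and a two-sided Wald z-test
  `p = 2·Φ̄(|pooled/se|)`. The test is asymptotic; with k = 7 small-study
  corrections (Knapp–Hartung) would widen intervals, but the plain
  z-test is what the selection rule above pairs with and is what the
  package calibrates and reports.

Significance calls use raw thresholds, strictly: `|LFC| > 1` and
`p < 0.05`. No multiplicity correction gates the call; BH q-values are
reported as an extra column. The LFC gate can only remove calls relative
to `p < 0.05` alone.

### Preprocessing helpers

Inputs are assumed expression-summarized (no background correction or
RMA). A matrix whose maximum exceeds 30 is treated as linear-scale and
transformed by `log2(x + 1)` (overridable); negative values on that
branch are an error. Probe-to-gene collapsing takes the per-sample
median over a gene's probes — robust, deterministic, and standard when
no probe-quality information is available.

### Diagnostics

- Forest table: per-study LFC with 95 % CI (`lfc ± 1.96·√var`) and the
  selected model's weights normalized to percent (they sum to 100),
  plus a pooled summary row.
- Volcano table: pooled LFC vs −log10 p.
- QQ check: per-gene `z = lfc/√var`, standardized robustly (median
  location, MAD scale calibrated to the normal) and compared to N(0, 1)
  quantiles; the deviation is the Kolmogorov–Smirnov distance, with a
  `systematic_bias` flag above a configurable threshold (default 0.1).
  Robust standardization is deliberate: the check must flag
  distribution-wide distortion while tolerating a handful of genuinely
  extreme genes, and scaling by the plain standard deviation would let a
  single huge outlier shrink every other point and trip the flag.

## Enrichment

One-sided Fisher exact over-representation per gene set: the 2×2 table
is formed over a background universe (default: the union of all
collection members, used when the caller states none), and the p-value
is the exact hypergeometric upper tail. BH-FDR runs across all tested
sets. A set is reported when `q ≤ 0.005`, its background-restricted size
is ≤ 1000, and the overlap is ≥ 2 % of that size; the size cap motivates
using the set size (not the query) as the percentage denominator. Sets
with no member in the background are skipped with a warning.

## Shortest paths

Paths are simple and hop-count is the metric (literature edges carry no
weights). All minimum-hop directed paths are enumerated (bounded by
`max_paths`, default 100, to keep dense graphs tractable), in
lexicographic node order for determinism. A path's net sign is the
product of its edge polarities. Intermediates are classified by their
direct edge into the target disease — promoter (+), inhibitor (−),
indirect (none) — and the overall verdict is "mixed" when both promoter
and inhibitor intermediates occur.

## Synthetic data

The generator draws data under exactly the model the meta-analysis
assumes, so planted truth is recoverable in expectation: per gene g and
study i a realized effect `θ_gi ~ N(LFC_g, τ²)`, control samples
`~ N(baseline, σ²)` and case samples `~ N(baseline + θ_gi, σ²)`, all on
the log2 scale. Defaults: the seven study designs mirror the emulated
array studies (case/control 34/4, 17/7, 49/50, 10/7, 49/48, 31/21,
84/14), `baseline = 8.0` (mid-intensity on a log2 array scale),
`σ = 1.0` (a typical per-gene array spread), `τ² = 0`. Heterogeneity is
planted at the study level (one θ_gi shift shared by all cases of a
study), matching what the random-effects model estimates. Output is
rounded to 6 decimals and serialized as text, so a fixed seed gives
byte-identical files across runs.

What the generator does **not** emulate: probe-level artifacts, batch
and platform effects, correlated genes, non-Gaussian heavy tails, and
array saturation. Passing tests therefore demonstrate correctness of
the statistics under the model's own assumptions, not robustness to
real-array pathologies.

The relation generator plants each gene into one of the four
(A → g, g → B) sign patterns with QC-clean reference counts, and two
fixed fixtures ship with the package: the 11-gene core network (the
inhibited-promoter motif, as a packaged TSV), and an SM1-scale synthetic
table planting the full set accounting (573 targets, 231 regulators,
101 shared, 472 target-only) with synthetic `SYN*` symbols beyond the 11
core genes. The PTH neighbourhood fixture plants two promoter- and two
inhibitor-class intermediates (MMP9 and CTNNB1 being the two named in
the literature; `SYNP*` nodes are synthetic), yielding the "mixed"
verdict.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (NumPy `default_rng`);
the CLI and the acceptance script derive all randomness from a single
`--seed`. The shipped checks use 1000 random pooling instances for
formula-level agreement (tolerance 1e−10 relative), 2000 null genes at
the seven-study design for type-I calibration (expected rate 0.05), and
200 planted genes across ten (LFC, τ²) cells for recovery (mean cell
bias below 0.1, i.e. within two standard errors of the cell mean).
These sizes make the whole suite run in seconds while keeping Monte
Carlo error well inside each tolerance.

## Known limitations

- The Wald z-test and DL τ² are both first-order; with very few studies
  the type-I rate of the *random-effects* branch can drift above
  nominal. The shipped calibration check runs under τ² = 0.
- The linear-scale detection threshold (max > 30) is a heuristic and is
  configurable; mixed-scale inputs should be normalized upstream.
- Set accounting trusts the entity-kind column; misannotated kinds
  propagate.
- The enrichment background defaults to the GMT union, which is
  anti-conservative if the expression platform covers fewer genes;
  supply the platform universe for real analyses.
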