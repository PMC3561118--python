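# Methods

## Model and scope

The package analyses a factorial design: genotype ∈ {control, hif_mutant,
err_mutant, double_mutant} × oxygen ∈ {normoxia, hypoxia}, with ≥ 2 (by
default 3) biological replicates per cell and log2-scale expression values
per probe, as produced by standard array normalisation upstream. All
classification is at the probe level; collapsing probes to genes is left to
the caller. The pipeline's stages are: two-group permutation differential
expression, gating into directed gene sets, dual-evidence factor
classification, overlap/enrichment statistics, and the metabolomics and
qPCR companion analyses.

## Differential expression

For a comparison "a vs b" the per-probe statistic is
d = (x̄_b − x̄_a)/(s + s₀), with s the pooled standard error
sqrt[(1/n_a + 1/n_b)(SS_a + SS_b)/(n_a + n_b − 2)]. The statistic is
antisymmetric under group swap. Degenerate probes are defined by
0/0 → d = 0 and x/0 → ±∞, so zero-variance designs (e.g. noise-free
simulations) remain well-behaved.

**s₀ (fudge factor).** Three modes: `fixed`; `median_s` (median per-probe
s); and the default `cv_minimization`, which evaluates the 0th–100th
percentiles of s in steps of 5 as candidates and picks the one minimising
the coefficient of variation of the MAD of d across windows of probes
grouped by s (window count = min(100, n/10), MAD scaled by 1/0.64). This
makes |d| approximately independent of the variance level, so
low-variance probes cannot dominate the tails. If every window is
degenerate (all-zero variance), the median of s is used as a fallback.

**Permutation q-values.** For each probe's threshold t = |d_i|, the
observed call count is #{j : |d_j| ≥ t} (the probe counts itself, so the
denominator is ≥ 1). For each label assignment the exceedance count
#{j : |d*_j| ≥ t} is recorded (tie rule ≥ by default; configurable to >).
q_i = median over assignments of the exceedance count, divided by the
observed count, clipped to [0, 1]. When the number of distinct label
assignments C(n, n_a) is at most `exhaustive_limit` (default 10,000) all
assignments are enumerated — the original labelling included — and the
result is fully deterministic; otherwise `n_permutations` assignments are
sampled without within-assignment replacement using the config seed.
Monotonicity is enforced by a running minimum from the weakest |d| upward,
so a larger |d| never receives a larger q (the same cumulative-minimum
device Benjamini–Hochberg uses). This estimator sets the null proportion
π₀ = 1, which is conservative.

**Gating.** A probe enters a set iff |signed fold| ≥ `min_abs_fold`
(default 1.5) and q < `max_q` (strict inequality). Signed fold is computed
from log2 group means — a geometric mean on the linear scale — with
r = 2^(x̄_b − x̄_a) reported as +r when r ≥ 1 and −1/r otherwise. The seven
default per-comparison q gates are 0.733% (control N vs H), 0.414%
(hif_mutant N vs H), 0.721% (control-H vs hif_mutant-H), 7.84%
(err_mutant N vs H — this comparison carries a deliberately relaxed gate),
0.619% (control-H vs err_mutant-H), 0.662% (double_mutant N vs H) and
0.703% (control-H vs double_mutant-H). All are configurable per run.

## Dual-evidence classification

Per factor: independent_H = Total ∩ factor-independent;
set2 = Total − independent_H; dependent_H = cross ∩ set2. The invariants
|independent_H| + |set2| = |Total|, dependent_H ⊆ set2 ⊆ Total and
independent_H ∩ dependent_H = ∅ hold for any inputs and are property-tested.
`direction_mode="ignore"` (default) intersects on membership alone, because
the original scheme is stated purely in set terms; `"concordant"`
additionally requires the mutant N-vs-H direction to match the control
direction for the independent intersection, and the cross-comparison
direction (oriented mutant-relative-to-control) to oppose it for the
dependent intersection. Both modes are exposed since direction handling in
such schemes is a genuine design choice; membership-only is the default as
the weaker assumption.

## Overlap and enrichment

Overlap significance is the inclusive upper tail P(X ≥ k) of the
hypergeometric distribution (population = universe, successes = |A|,
draws = |B|, observed k = |A ∩ B|); inclusive is the standard
over-representation convention and the more conservative choice. The
default universe is the number of probes in the analysed matrix —
configurable, and recorded in output metadata, since the choice between
"all probes on the platform" and "expressed probes" materially changes p.
Venn partitioning enumerates all exclusive regions for 2–3 sets.
Enrichment applies the same tail probability per annotation term with
Benjamini–Hochberg q-values across the tested terms.

## Metabolomics

Stage order is enforced and recorded: impute → protein-normalise → log2 →
ANOVA; the later stages refuse tables that still contain censored values.
The imputation rule is generalised from the six-replicate reference design
to any group size: a group whose replicates are all below detection gets
the global minimum detected value across all compounds (a post-hoc
detection floor — instrument limits are rarely published); a group with at
least one detected replicate gets the compound's minimum detected value.
Detected entries are never modified, and no imputed value can fall below
the global detected minimum. Heat-map values are log2 of the arithmetic
group mean (linear scale) over the control-normoxia mean. Significance is
a per-compound one-way ANOVA across all genotype × oxygen groups with
pairwise contrasts tested against the pooled within-group mean square
(error df N − k, two-sided); fitting one model with contrasts rather than
separate pairwise tests is the default because it uses the common error
variance the design affords. q-values are Benjamini–Hochberg within each
contrast across compounds.

## qPCR

Relative expression is 2^−(CT_gene − CT_ref), assuming doubling efficiency
(no efficiency correction, matching standard ΔCT practice); H/N
fold-change is the ratio of group means of relative expression, with 1.0
meaning no net response. Tests run on ΔCT values: two-tailed unpaired
t-tests, pooled-variance by default ("Student's"), Welch available.
The Bonferroni family size `m_tests` must be supplied by the caller —
the family depends on how many gene × stage comparisons a study makes —
and is recorded in the output.

## Synthetic data generator

The generator defines the reference study conditions. Expression: baseline
log2 intensities ~ Normal(7, 1.5); additive Gaussian noise with
`noise_sd = 0.25` log2 units per observation (within-group array variance
is rarely published; 0.25 makes gate-clearing effects recoverable without
saturating the tests, and is flagged in the config); hypoxic effects drawn
as ±Uniform(0.8, 3.0) log2 so most planted responders clear the 1.5-fold
gate (log2 ≈ 0.585). Dependency classes map to the genotypes in which the
effect is realised: HI everywhere; HD where HIF is functional (control,
err_mutant); ED where ERR is functional (control, hif_mutant); HD_ED only
in control; DM_only everywhere except the double mutant; a
negative-regulation class applies its effect everywhere but amplified
(default 2×) in genotypes lacking a designated repressing factor; null
probes have zero effect everywhere. One seeded RNG stream drives the
expression dataset; the metabolite and CT generators use deterministic
sub-seeds (seed+1, seed+2). Identical configs give bit-identical outputs.

Metabolites: lognormal abundances (CV 0.25) around per-group means spanning
the detection floor so censoring actually occurs; 20% of compounds get a
±1.5 log2 hypoxic shift; six replicates per group; per-sample protein mass
~ Normal(100, 10) µg. CT values: baseline 22 cycles minus log2 relative
expression plus Normal(0, 0.15) cycle noise, with the reference gene
constant across conditions.

Because classification is by *realised* response, the scheme-level
expectation derived from the planted effects (`expected_dependency_sets`)
is the correct recovery target: a planted ED probe also belongs in the
HIF-independent set, and planted HD and ED probes both belong in DM. The
generator emulates the variance structure and effect architecture the
analysis assumes; it does not emulate probe-level artifacts, correlated
noise between samples, batch effects, or developmental time courses, so
passing recovery tests demonstrate the logic and calibration of the
pipeline, not robustness to those real-data pathologies.

## Numerical and determinism choices

Problem sizes in the test suite and acceptance script (10,000 null probes
for calibration, 20,000 probes for recovery, 3-vs-3 exhaustive
enumeration) were chosen so the whole suite runs in seconds while keeping
binomial error on measured rates small. All sampling is seeded; pipeline
outputs are byte-stable (sorted GMT members, fixed column orders) and the
run manifest records seeds, gates, universe size and per-file SHA-256, so
re-execution from the same config reproduces every output exactly.

## Known limitations

- The permutation estimator with π₀ = 1 over-estimates q slightly on
  mostly-null data (conservative).
- With only 20 distinct assignments in a 3-vs-3 design, attainable q
  values are coarse; very small gates (< 1/20) are effectively "no
  permuted exceedance anywhere".
- The below-detection rule's "global minimum" branch anchors on the data
  at hand, not on instrument detection limits.
- No paired or multi-class differential variants; no GO graph propagation;
  enrichment runs on whatever flat annotation is supplied.
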