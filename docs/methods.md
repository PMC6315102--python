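# Methods

## The diel time axis

Samples are labelled `[2]?[LD]<hour>`: phase (light/dark), hours since
entry into that phase (1-based), and an optional `2` marking the second
light/dark cycle.  `dieltx` places labels on a continuous axis whose
origin is the first light onset (first dark onset for dark-first
regimes), with a 12 h/12 h photoperiod by default.

Published label conventions are not fully self-consistent: a full-length
terminal-phase code (`D12`, `2D12` under 12/12 light-first) is used for
the day boundary itself (hours 0 and 24), and some series leave the cycle
prefix implicit for samples in the second night.  The context-free parser
(`parse_time_label`) therefore adopts the day-boundary reading for
full-length terminal labels, and the sequence-aware parser
(`parse_series`) resolves each label of an ordered series to the smallest
admissible hour strictly after its predecessor.  Ordering is the contract:
all five sampling grids shipped as constants (8-, 9-, 6-, 8- and 19-point
series) come out strictly increasing, which is what every downstream
computation needs.  Absolute origin is a convention; only relative hours
enter the statistics.

## Synthetic data: what it emulates and what it does not

Gene courses follow a single-harmonic cosinor in log2 units,
`x(t) = mesor + A·cos(2π(t − φ)/24) + ε`, `ε ~ N(0, σ²)`.  Defaults mirror
the emulated study design: 8 time points spanning 36 h with duplicate
chips at four of them, 6 probes per gene, 30% of genes periodic
(amplitude 0.8–2 log2 units, uniform random phase), 65% flat background
near log2 intensity 2.5, the remainder flat but expressed (mesor uniform
in 6–10, matching a log2 intensity range of roughly 2–13.5 with median
near 6), and per-sample noise σ = 0.25.  Probe-level data add a per-probe
affinity offset (σ = 0.7), probe noise (σ = 0.1), and a per-chip affine
distortion in log2 space (gain ~ N(1, 0.05), shift ~ N(0, 0.3)) before
exponentiation — enough structure to make quantile normalization and
median polish non-trivial without modelling scanner physics.

Planted fractions are realized exactly by construction, and a fixed seed
gives bit-identical output.  The generator does *not* simulate
hybridization chemistry, cross-hybridizing probes, spatial artifacts,
missing values, or non-sinusoidal wave shapes; passing tests therefore
demonstrate correctness of the statistical machinery under the cosinor
model, not robustness to every failure mode of real arrays.

## Preprocessing

Linear intensities are floored at 1e-6 (count logged) and log2
transformed.  Quantile normalization forces each chip's sorted values to
the across-chip mean of order statistics, with stable rank ties, which
makes the operation idempotent.  Median polish is Tukey's alternating
row/column median sweep (R `medpolish` sweep order); the per-sample gene
value is overall + column effect.  Iteration stops when the sum of
absolute residuals decreases by a relative tolerance (default 1e-8,
max 20 sweeps).  Median polish can cycle without converging, so exact
comparisons between implementations must fix the sweep count; the
decomposition reconstructs its input exactly at every iteration
regardless.  Normalization runs before summarization (the robust
multichip convention, applied uniformly to both emulated platforms);
`preprocess_probes(normalize_first=False)` swaps the order for
sensitivity analysis.  Replicate chips are averaged arithmetically on the
log2 scale after summarization.

## Detection

Per chip, BG is the mean of the lowest ⌈5%·n⌉ signals (requiring
n ≥ 1/fraction), and SNR = (S − BG)/BG on the linear scale, making SNR
invariant to per-chip rescaling.  A gene is detected when SNR ≥ 5 on at
least one chip (rule `ANY`); `ALL` and `K_OF_N` are available because the
across-chip combination rule is a genuine free choice — `ANY` maximizes
sensitivity for "transcribed at detectable levels".  Calls are made on
un-averaged chips.  The abundance/IQR filter keeps genes above an
explicit `min_value` in ≥ 25% of samples with a log2 IQR ≥ 0.5;
`min_value` has no default because the conventional "64" threshold is a
linear-scale value (2⁶) and must be stated on the scale in use.

## Periodicity

The Fourier score is the single-frequency periodogram of the
standardized series (sample sd), evaluated at the true absolute hours —
irregular grids are handled directly, with no resampling.  Constant
series score 0 by convention.  Significance comes from permuting the
assignment of values to time points: p = (1 + #{permuted ≥ observed}) /
(n_perm + 1), with an independent child generator per gene spawned from
one seed so results are reproducible and order-independent.  The
permutation null was chosen over parametric (Gaussian or AR(1))
backgrounds because it is assumption-free and directly testable; n_perm
defaults to 1999 (p resolution 5·10⁻⁴).  Benjamini–Hochberg q-values
control FDR; the diel call threshold defaults to q < 0.25.

Peak hour is the phase of the least-squares cosinor fit
`x ≈ a + b·cos ωt + c·sin ωt`, i.e. `atan2(c, b)/ω mod 24`.  On a uniform
full-period grid this equals the first Fourier component's phase; the
regression form remains unbiased on irregular grids.  Light-vs-dark
contrasts use Welch's t-test on log2 values (≥ 2 samples per phase) with
BH adjustment; fold change is 2^|Δmean|.  Welch was chosen over moderated
(empirical-Bayes) statistics to keep the contrast self-contained; with
few chips it is conservative.

## Phase clades

Diel genes are standardized per gene across time points (mean 0, sample
sd 1; constant genes excluded with a logged count), pairwise distances
are d = 1 − Pearson r ∈ [0, 2], and complete-linkage agglomeration is cut
into k = 4 groups by default (matching the four observed peak-phase
clades; k is a parameter).  Cluster labels are renumbered by first
appearance, so output is deterministic for a given input order;
partitions are invariant to input order up to relabelling on tie-free
data.  A clade's peak hour is the argmax of its mean standardized course
on the observed grid (mod 24), so its resolution is the grid spacing.

## Cross-species comparison

Standardized courses are evaluated on a common grid (default hourly) that
spans from the latest series start to the earliest series end, capped at
36 h.  No cyclic extension is performed: extrapolation outside an
organism's observed span is refused, a deliberately conservative reading
of mixed-grid designs.  Genes observed at fewer than 4 points are
excluded.

Interpolation is Stineman's rational scheme: it passes through every
knot, reproduces exactly linear data exactly, and never overshoots.
Slopes start from the circle tangent through each point and its
neighbours, with sign-preserving endpoint extrapolation; they are then
limited to at most 3× the smaller adjacent secant (zero where the secants
change sign), the standard monotonicity-consistent restriction.  The raw
circle tangents alone can exceed a small secant many-fold and force an
interior extremum; numerically, the rational form stays monotone whenever
both end slopes share the secant's sign and stay below about 4× its
magnitude, so the 3× cap guarantees a monotone interpolant for monotone
knots.

Orthologs are reciprocal best hits over any pairwise similarity table;
ties yield no pair.  The built-in scorer counts shared 11-mers normalized
by the shorter sequence's k-mer count — a desk-scale stand-in for a full
alignment search, swappable for user-supplied score tables.  Networks
connect genes with r > threshold on the common grid (edges from positive
co-expression only; `include_anticorrelated` switches to |r| for
exploration).  The thresholds 0.5 and 0.2 correspond to the conservative
and exploratory views of cross-species co-expression; "distance 0.5"
and "correlation > 0.5" coincide under d = 1 − r.

## Probe filter cascade

Candidate 60-mers are tiled at evenly spaced offsets (6 per gene by
default).  Cross-hybridization and strain-specificity filtering use an
exhaustive gapless sliding-window identity scan over both strands:
identity = matches/length over 100% of the probe, deletion at ≥ 95% —
the full-length identity criterion implied by a 5% hybridization mismatch
tolerance.  No gapped alignment is performed, a documented deviation that
makes the 57/60-vs-56/60 boundary exact and testable.  Redundancy removal
is greedy clustering in input order at 95% identity (first member founds
the cluster and stays).  Whitelisted conserved genes (the nitrogenase
scenario) survive the strain filter with the cross-strain evidence
recorded.  The cascade order is fixed (cross-hyb → redundancy → strain)
and per-stage removals sum to total attrition.

## Pipeline, configuration, determinism

`run_all` chains simulate → preprocess → detect → rhythm → cluster →
network.  The YAML config is validated with unknown keys rejected
(pydantic, `extra="forbid"`); the run summary is checked against a
published JSON schema (`dieltx/data/summary.schema.json`) by a small
internal validator covering the schema subset used.  Every threshold is
echoed into `metadata.json`, wall-time logging goes to stderr only, and
all randomness derives from the single config seed, so a bundle is
byte-identical across runs (verified file-by-file in the tests).

## Problem sizes and defaults in the shipped checks

The acceptance checks use 1,000 genes for permutation calibration
(n_perm = 1999), 300 genes for rhythm recovery, 100 ortholog pairs for
the cross-species checks, 60 genes for clade recovery, and a 150–300 gene
preset for end-to-end runs — sizes at which every Monte-Carlo margin in
the assertions is comfortably wide while the whole suite runs in seconds.

## Known limitations

- Single-harmonic rhythms only; square-wave or multi-peak profiles are
  out of scope, as is differential rhythmicity between conditions.
- The permutation test treats samples as exchangeable under the null;
  autocorrelated noise would inflate significance.
- The k-mer similarity scorer is not a substitute for alignment-based
  ortholog calling on real genomes; supply precomputed score tables for
  serious use.
- SNR background uses all gene signals on a chip; arrays with dedicated
  control probes could estimate BG from controls instead.
- Peak-hour estimates for clades are grid-resolution limited; per-gene
  cosinor peaks are continuous.
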