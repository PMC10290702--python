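# Methods

This note documents the models, parameter choices and numerical decisions
behind `orgscope`, and what the synthetic-data tests do and do not show
about real recordings.

## Calcium-imaging quantification

### Model of a recording

A field of view holds R disk ROIs sampled for T seconds over F frames
(default 300 s / 109 frames, i.e. 2.75 s per frame — the analysis grid of
the experiments this package serves; recordings themselves are typically
acquired at 250 ms and analysed on a coarser grid). Raw fluorescence is

F_r(t) = B · (1 + d·t + Σ_e a_e k(t − t_e)) + ε_t,  ε ~ N(0, σ²)

with baseline B, linear drift d, and a peak-normalised
difference-of-exponentials indicator kernel
k(t) = (1 − e^(−t/τ_r)) e^(−t/τ_d) (defaults τ_r = 0.05 s, τ_d = 0.6 s,
fast-GCaMP-like). The simulator renders this signal on a fine internal
grid (≤25 ms) and **averages within each output frame**: frames integrate
the signal as a camera exposure does. Point-sampling instead would miss
roughly half of all sub-frame transients at a 2.75-s interval and make
every recovery property meaningless; integration also fixes the
amplitude semantics (at fine sampling the frame value approaches the
kernel peak, so an injected transient of amplitude *a* reads ≈ *a*).

Events are Poisson: each ROI has its own spontaneous train
(rate ρ/min), and a network-wide train (rate s/min) adds shared events.
Each network event recruits a uniformly random subset of exactly
⌈p·R⌉ ROIs (participation p). A fixed-size subset rather than
independent Bernoulli recruitment keeps "a network event is seen by at
least ⌈p·R⌉ ROIs" true by construction, which the ground-truth contract
relies on. Recruited events are included in each ROI's event list, so the
true per-ROI transient rate is ρ + s·p.

Default amplitudes, noise and drift are the package's own choices (the
source experiments publish none): a = 0.75 dF/F₀ (order-unity somatic
GCaMP bursts), σ = 1% of baseline (ROI-averaged confocal noise), drift
0.2%/min (slow bleaching under stable illumination). Two constraints make
this the coherent operating point for the default detector settings:
a frame-integrated transient must clear the 0.05 dF/F₀ detection floor
even when split across a frame boundary (needs a ≳ 0.6 at 2.75-s frames),
while a single ROI's transient diluted onto the R=5 ROI-averaged trace
must stay below the floor so it is not mistaken for a network event
(needs a·0.27/5 < 0.05, i.e. a ≲ 0.9).

### Detection

F₀ is the 10th percentile of each ROI's raw trace — robust to sparse
transients, and the reason the simulator's noise matters: a percentile
baseline sits ~1.3σ below the true baseline, so large frame noise would
shift the whole dF/F₀ trace toward the detection floor. Peaks are local
maxima with height **and prominence** ≥ max(0.05, 3·MAD of the trace),
separated by ≥2 frames; the prominence requirement rejects noise
excursions riding on residual drift without altering the amplitude
contract. Synchrony applies the identical detector to the unweighted mean
dF/F₀ trace across ROIs. Frequency is by default the summed peak count
over ROIs per minute (one number per FOV); a per-ROI-mean variant is
available via `per_roi_mean=True`. Recordings of different lengths are
only ever compared through per-minute rates.

### What recovery tests show — and the coarse-grid limit

At the native 250-ms resolution the detector recovers configured event
rates within a few percent across 1–4 events/min. On the default 2.75-s
analysis grid, recovery is *information-limited*: two events landing in
the same or adjacent frames merge into one detected peak. Occupancy
arithmetic (events per frame λ = rate·Δt) predicts detected/true ≈ 0.94,
0.88, 0.78 at 1, 2, 4 events/min/ROI, matching simulation (≈0.93, 0.85,
0.73). This saturation is a property of any peak counter at that frame
interval, not of this implementation; the tests therefore assert accurate
recovery at native resolution and the quantified, monotone merge-loss
band on the coarse grid. Synchronous-rate recovery is validated at sparse
spontaneous background (0.5/min/ROI): at busy backgrounds (≈3/min/ROI)
chance co-activation of 3-of-5 ROIs crosses the averaged-trace threshold
and inflates the synchronous count by ~10–17%. Genotype *contrasts* are
unaffected in direction by either effect, which is why the power analysis
(control 3 & 2/min vs deletion 1.5 & 1/min, 25 FOVs/arm) detects both
deficits in every replicate while a zero-effect null almost never does.

ROI selection scores each candidate centre by the temporal standard
deviation of the disk-mean trace, places disks greedily without overlap,
and breaks ties in raster order (the published workflow chose "most
active regions" by hand; an explicit score makes the choice testable).

## Group statistics

ROUT outlier removal, for one-sample scatter data, fits the robust
constant (median), scales residuals by the RSDR (68.27th percentile of
|residuals| × √(n/(n−1))) and tests them outermost-inward against a
t reference (df = n−1) with step-down FDR thresholds α_i = Q(n−i+1)/n,
stopping at the first non-significant residual. The commercial
implementation's internal constants are unpublished, so this variant is
validated by calibration: a 100-SD contaminant among 29 unit normals is
flagged in 100% of runs; clean unit-normal samples average <1% flags at
Q = 1%. Two-group comparisons use the pooled-variance (Student, not
Welch) two-tailed t test; multi-condition designs use one-way ANOVA with
Tukey HSD (studentized range). Degenerate inputs (zero pooled variance)
return t = 0/p = 1 for equal means and a flagged p → 0 otherwise.

## Single-cell QC and normalisation

Per-cell metrics: total UMI, detected genes (count > 0), mitochondrial
fraction (genes by "MT-" prefix or explicit list). Filters are strict
inequalities — a cell at exactly 1200 UMI, 6000 genes or 10.0% mito is
kept — reading "less than / more than" literally; cluster-level removal
of low-depth clusters is out of scope because it presupposes an external
clustering. Normalisation is counts-per-million per cell followed by
log₂(CPM+1); back-transforming must return 1e6 per cell, which the tests
assert to 1e-6 relative.

## Differential expression and gene-set statistics

DE is the two-sided Wilcoxon rank-sum test per gene (tie-corrected;
exact for small untied samples), BH-adjusted within the (class,
time point) family, significant at FDR < 0.05. Log₂ fold change is
computed on exponentiated group means of the log-normalised values with a
1e-9 pseudocount (clipped at zero before the ratio). Constant genes
report p = 1. GO filtering is flat set algebra on GMT collections:
union(include) minus union(exclude), no DAG propagation.

Overlap significance between DEG lists is the upper-tail hypergeometric
p for the observed intersection, with the universe defaulting to the
number of genes tested (configurable), BH-corrected across all
off-diagonal pairs of one panel, reported as −log₁₀(FDR p). Disease
enrichment uses the same machinery against curated disease sets with the
score clipped to [0, 10]; preranked GSEA is provided as the second route
(the source analyses used both over-representation and GSEA without
stating which produced which panel). Its ES is the weighted (exponent 1)
KS running sum; the null permutes set membership among ranked genes;
NES = ES / mean |null ES| of matching sign. A set covering the entire
ranking has an empty complement and is defined to score ES = 0
(uninformative). The default ranking metric is signed
−log₁₀(p)·sign(log2FC). Per-class gene modules are the top-N (default
200) one-vs-rest genes ranked upregulated-first, then by p, then by
fold change — a module is a positive signature.

## Label transfer

One-vs-rest L2 logistic regression (inverse penalty C = 1, lbfgs) per
reference cell type on the 2000 most variable reference genes,
standardized with reference means/SDs; the query reuses the reference
transform (no refitting, no leakage) and missing features impute to the
standardized zero. Types under 10 reference cells are dropped with a
warning. Cluster scores are arithmetic means of per-cell probabilities;
a cluster's identity is the argmax type. Monotone degradation under
reference label noise (0 → 10% → 30%) is asserted with 1-s.e. slack.

## Pseudotime densities and divergence

Pseudotime values are inputs; trajectory-graph inference is explicitly
out of scope. Ridge curves are Gaussian KDEs sharing one grid (pooled
range padded by 4 bandwidths) and one pooled-sample Silverman bandwidth
(0.9·min(sd, IQR/1.34)·n^(−1/5)), so genotype curves are pointwise
comparable and each integrates to 1 (trapezoid, tolerance 1e-3). The
divergence statistic — a deliberate, labelled extension beyond visual
ridge comparison — is the two-sample KS statistic with a label-permutation
p. Because the KS statistic is discrete, permuted values tie with the
observed one; ties count half (mid-p), which keeps the null p
approximately uniform where the conventional add-one rule is visibly
conservative.

## Synthetic count matrices

Counts are negative binomial with mean μ and dispersion θ
(var = μ + μ²/θ, default θ = 2). Each of the five default classes (NEC,
oRG, IPC, CN, IN) shares a log-normal baseline expression profile with 20
disjoint markers boosted 8-fold. Library sizes are log-normal with mean
6000 UMI; per-cell mitochondrial fractions are Beta with mean 5%
(13 "MT-" genes scaled per cell to hit the fraction in expectation), so a
realistic tail of cells fails the 10% QC cut. Deletion samples multiply
50 genes per class by 2^(±1) (half up, half down); injected DEGs are
restricted to genes expected at ≥1 UMI/cell because a fold change on a
never-observed gene is unidentifiable at any sample size. Pseudotime is
Beta per class on [0,1] with a +0.08 location shift (clipped) for the
deletion genotype. With zero injected effect the generator is an exact
null: the rank-sum false-positive rate calibrates to 5%.

What this generator does *not* emulate: batch effects and ambient RNA,
doublets, gene–gene correlation beyond the compositional constraint,
UMI saturation, spatial structure of image data beyond disk sources, and
indicator nonlinearity/saturation in the calcium signal. Tests passing
here show the statistics are implemented correctly and calibrated under
their stated assumptions — not that those assumptions hold in any given
real dataset.

## Problem sizes and determinism

Test and acceptance runs use deliberately desk-scale problems (25 FOVs
per arm × 20 replicates; 2000 genes × 1000–4000 cells; 100–500
permutations), chosen so the full suite and the acceptance script each
complete in about a minute while leaving Monte-Carlo margins well clear
of the asserted thresholds. All randomness flows through
`numpy.random.default_rng` seeds; identical config + seed reproduces
every artifact bit-for-bit (the pipeline manifest records SHA-256
checksums to make this checkable).
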