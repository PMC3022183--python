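# Methods

This note documents the models and procedures implemented in `eegtopo`,
the choices made where the underlying methodology leaves room, and what
the synthetic-data tests do and do not establish.

## Global topographic measures

A *map* is the vector `u ∈ ℝᴺ` of potentials at all N electrodes at one
instant. All topographic math begins by average-referencing (subtracting
ū): any change of recording reference adds a constant per map, so every
quantity defined on centered maps is reference-independent. This is
enforced structurally — `gfp`, `gmd`, `spatial_correlation`, the
clustering and TANOVA all center their inputs internally; callers never
need to rereference first.

- `GFP(u) = sqrt(Σ(uᵢ − ū)²/N)` uses the population normalization
  (divide by N, not N−1).
- `GMD(u, v)` is the RMS difference of the GFP-normalized centered
  maps; the identity `GMD² = 2(1 − r)` with the spatial Pearson
  correlation `r` is exact and is used as a cross-check in the tests,
  never as the implementation of both sides.
- Flat (zero-GFP) maps make GFP-normalization undefined. Pairwise calls
  raise; curve functions return NaN for the affected entries. Silent
  NaN propagation is deliberately avoided.

## Microstate clustering

Both algorithms operate on centered maps and produce unit-L2-norm,
zero-mean templates; goodness of fit is the global explained variance

    GEV = Σₜ (GFPₜ · rₜ)² / Σₜ GFPₜ²,

with `rₜ` the spatial correlation between frame t and its template
(|r| in polarity-ignore mode). With unit-norm templates this reduces to
`Σ (cₜ·τ)² / Σ ‖cₜ‖²` over centered frames, which is how it is computed.

**Modified k-means.** Initial templates are q distinct frames drawn
without replacement (one RNG per call; fully deterministic given the
seed). Assignment maximizes squared correlation (polarity-ignore) or
signed correlation (polarity-respect); ties resolve to the lowest
template index via `argmax`. The update step is the dominant
eigenvector of the members' outer-product scatter (ignore) or the
normalized member mean (respect). Empty clusters are re-seeded from the
currently worst-fit frame. Iteration stops when GEV changes by less
than `tol` (default 1e-7) or after `max_iter`; the best of `n_restarts`
by GEV is returned. Template sign is fixed by making the
largest-|value| electrode positive.

**AAHC.** Starts from singletons; the cluster with the smallest GEV
contribution is atomized and each freed frame reassigned to the
surviving cluster with the highest (squared) correlation. The
implementation caches one N×N scatter matrix per cluster: in
polarity-ignore mode a cluster's GEV-numerator share is exactly the
largest eigenvalue of its scatter, and its template the corresponding
eigenvector, so each agglomeration step costs one rank-k update plus
one 19×19 eigendecomposition. This makes the exact algorithm practical
at several thousand frames (about one second at T=5000, N=19). The
per-cluster "contribution to GEV" is defined as that cluster's share of
the GEV numerator — each frame's term goes entirely to its own cluster.
AAHC involves no randomness and repeated runs are bit-identical.

GEV is non-decreasing in q for the recorded AAHC solutions in practice,
but not by mathematical necessity: reassignment maximizes each freed
frame's own fit, not the pooled rank-1 fit of the receiving cluster, so
hair-sized decreases (~1e-4) can occur; the invariant test allows 5e-3.

**Model selection.** The cross-validation criterion is
`cv = σ̂² · ((N−1)/(N−1−q))²` with
`σ̂² = Σₜ(‖cₜ‖² − (cₜ·τ)²) / (T(N−1))`; it requires `N > q + 1` and is
minimized over q. The Krzanowski–Lai criterion uses the within-cluster
dispersion `W(q) = Σₜ (2 − 2|rₜ|)` of unit-normalized maps about their
templates, `DIFF(q) = (q−1)^{2/N} W(q−1) − q^{2/N} W(q)` and
`KL(q) = |DIFF(q)|/|DIFF(q+1)|`, maximized over interior q (smallest q
on ties). The dimension exponent uses the electrode count N. A KL
profile with no value at least twice its median — what featureless
noise produces — triggers a "weakly supported" warning rather than a
failure.

**Temporal post-processing.** Smoothing iteratively relabels each frame
to minimize `residualₜₖ/(2e(N−1)) − λ·(count of label k within ±b)`,
where `e` is the current mean residual variance; defaults b=3 frames,
λ=5. λ=0 returns the input unchanged by contract. Small-segment
rejection absorbs runs shorter than `min_tf` frame-by-frame into the
better-correlated neighboring run (nearer neighbor when maps are not
supplied; a run with no labeled neighbor becomes UNASSIGNED). Merging
pools clusters whose templates correlate above a threshold,
most-correlated pair first; sequentialization gives each temporally
disjoint occurrence of a template its own id without moving any
segment boundary.

## Back-fitting and statistics

Back-fitting labels each frame with the template of maximal correlation
— provably the same labeling as minimal GMD. Optional `min_r` floors
and an analysis window produce UNASSIGNED frames, which keep their full
variance in the residual and contribute nothing to GEV. Onset/offset
are the first/last labeled frame (inclusive); mean duration is mean run
length × 1000/rate in ms.

The TANOVA p-value at each frame is the fraction of permutation GMDs
(between GFP-normalized permuted group means) at least as large as the
observed one, *including* the identity permutation, so p ≥ 1/n_used and
the test is exact under exchangeability. Within-subject designs
enumerate all 2ⁿ condition assignments when 2ⁿ does not exceed
`exhaustive_threshold` (default 2¹⁶); otherwise n_perm−1 random
assignments plus the identity. Between designs shuffle group
membership, exhaustively over all C(n₁+n₂, n₁) splits when small
enough. By default only the group means are GFP-normalized;
`normalize_subjects=True` additionally scales every subject map to unit
GFP, removing individual strength differences from the statistic. A
permutation-GMD comparison uses a 1e-12 slack so ties (notably the
identity under the null) count as exceedances regardless of rounding.

A pure amplitude effect leaves the TANOVA median p far above α but can
mildly inflate its tail (the observed pure-condition means have a
different noise-to-signal mix than permuted mixtures); the dissociation
tests therefore compare median p-values in the effect window.

Degenerate zero-variance cells in t-tests (identical conditions) are
reported as t=0, p=1 rather than NaN.

## Frequency domain

Spectra are one-sided FFTs of tapered (Hann by default; rectangular for
exact-bin tests) windows of an average-referenced recording, advancing
by `window·(1−overlap)` frames. Power maps — mean |coefficient|² per
electrode over a band — are reference-dependent, unlike every
time-domain topographic quantity; this is documented behavior, not a
bug. The FFT-approximation stacks each window's real and imaginary
coefficient vectors as columns of an N×2W matrix and takes its dominant
left singular vector: stacking windows is equivalent to averaging
cross-spectra and avoids the phase cancellation that averaging complex
coefficients would cause. The map is scaled so its squared norm equals
the explained power, its sign makes the largest-|value| electrode
positive, and the reported phase is that of the first window's
component. Near-equal leading singular values (e.g. perfect quadrature,
explained fraction 0.5 at N=2) are flagged `degenerate`: no single
phase is preferred.

## Preprocessing

Filtering is Butterworth (SOS), zero-phase by default (forward-backward,
so segment boundaries are not phase-shifted; `zero_phase=False` gives
the causal single pass whose order-2 magnitude response rolls off at
−12 dB/octave). The notch is an IIR band-stop with Q=30 (the bandwidth
is a free implementation parameter). Downsampling applies a zero-phase
order-8 Butterworth anti-alias low-pass at 80% of the new Nyquist
before decimation — the contract is alias suppression (≥20 dB above the
new Nyquist), not a particular filter family. Epoch windows are
inclusive on both ends; out-of-bounds windows are dropped and counted,
not errors. All temporal operations act strictly per channel.

## Synthetic data

`make_montage` places electrodes on a golden-angle spiral over the
upper unit hemisphere with a small seeded jitter. `make_templates`
builds dipolar-looking maps (position·axis plus a quadratic curvature
term), average-referenced at unit GFP, rejection-sampled to pairwise
|r| ≤ 0.7. Microstate EEG concatenates template runs with geometric run
lengths (floor 1, mean `mean_duration_tf` — matching abrupt-switch
phenomenology), scales them by a rectified ~10 Hz sinusoid floored at
0.1 (so no frame is flat), and adds spatially white Gaussian sensor
noise scaled so mean signal GFP over mean noise GFP equals `snr`. ERP
group data use a deterministic block sequence and raised-cosine
envelope; condition B's effect is either a topography rotation to
spatial correlation `1 − effect_size` at exactly equal GFP, or a GFP
scaling by `1 + effect_size`, inside an effect window defaulting to the
middle third. All randomness flows through `numpy.random.default_rng`
(PCG64), so every artifact is reproducible per seed across platforms.

The generator emulates the structure the methods assume — piecewise
stable topographies, abrupt switches, additive white sensor noise,
exchangeable subjects. It does not emulate volume-conducted correlated
noise (beyond an optional smoothing hook), 1/f spectra, artifacts, or
latency jitter between subjects. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
model, not performance on recorded EEG.

## Default problem sizes

The heavier validation suites use 19 electrodes, 4 templates, mean
duration 20 frames, SNR 5 and 5,000 frames across 20 seeds for template
recovery, and 12 subjects × 500 frames × 1,000 permutations for TANOVA
calibration — regimes representative of a clinical montage and a
typical group study, chosen once as the package's standard validation
conditions.

## Known limitations

- AAHC memory grows as T·N² for the cached scatter matrices (~15 MB at
  T=5000, N=19); very long recordings should be restricted to GFP
  peaks or downsampled first.
- The smoothing penalty λ trades off against a residual term whose
  scale is estimated from the data; λ values are comparable across
  datasets only approximately.
- `fitstats_test` compares exactly two conditions with univariate
  t-tests; multivariate designs must be analyzed elsewhere from the
  exported spreadsheet.
- Between-design TANOVA treats subjects as exchangeable across groups;
  covariate imbalance is not modeled.
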