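# Methods

## The JIP test

The package derives, per sample, the standard JIP-test parameter vector
from a single OJIP fluorescence induction curve. The curve is assumed to
be recorded after full dark adaptation under a single saturating pulse,
with log-spaced acquisition covering at least 50 µs – 2 ms. Landmarks:

| quantity | convention | default |
| --- | --- | --- |
| F₀ | fluorescence at the JIP-test origin time t₀ | 50 µs |
| F₃₀₀ | fluorescence at the slope time | 300 µs |
| F_J | fluorescence at the J-step | 2 ms |
| F_M | maximum observed fluorescence (first occurrence) | — |

F₀, F₃₀₀ and F_J are obtained by linear interpolation of fluorescence in
log₁₀(time): on log-spaced grids this is the least biased simple
interpolant, and it reduces to ordinary linear interpolation on the short
segments between adjacent points. No smoothing is applied before the
maximum is read off; `ExtractionSettings` exposes the three landmark times
and an optional linear-in-time interpolation mode.

Derived quantities follow the standard formulary: φ_Po = 1 − F₀/F_M,
V_J = (F_J − F₀)/(F_M − F₀), ψ₀ = 1 − V_J, the cross-section energy fluxes
ABS/CS = F₀, TR₀/CS = φ_Po·ABS/CS, ET₀/CS = φ_Po·ψ₀·ABS/CS,
DI₀/CS = ABS/CS − TR₀/CS, RC₀/CS = φ_Po·(V_J/M₀)·ABS/CS, and
PI_ABS = (RC₀/ABS)·[φ_Po/(1−φ_Po)]·[ψ₀/(1−ψ₀)].

Two conventions are worth making explicit because the verbal definitions
in the literature do not fix them:

* **M₀** is computed as 4·(F₃₀₀ − F₀)/(F_M − F₀), i.e. the slope of the
  relative variable fluorescence over the first 0.25 ms expressed per
  millisecond — the common realization of "initial slope of the
  fluorescence rise". The per-ms unit choice cancels inside PI_ABS only
  through V_J/M₀, so it is recorded here and in the output metadata.
* **Area** is the trapezoidal integral of (F_M − F(t)) from the first
  acquired timepoint to t(F_M). It therefore depends on the acquisition
  window; the synthetic oracle (below) uses the same convention.

Degenerate transients (F_M ≤ F₀, or a maximum at the first sample) are
flagged and reported in a rejects list rather than raised, so a batch of
field samples survives the occasional dead leaf. For a fully quenched
sample the fluxes degrade gracefully (TR₀/CS = ET₀/CS = 0,
DI₀/CS = ABS/CS, PI_ABS = 0); ratios that are genuinely undefined
(φ_Po = 1 or ψ₀ = 1) are carried as NaN.

## Group statistics

Each parameter is compared between factor cells
(population × season × period) with two-sided Wilcoxon–Mann–Whitney tests:
exact null distribution when the pooled sample size is ≤ 12 and tie-free,
otherwise the normal approximation with tie and continuity corrections
(scipy's implementation; an independent enumeration oracle covers it in
the tests). Benjamini–Hochberg adjustment is applied within each
parameter's family of contrasts by default — matching how per-panel
significance brackets are usually displayed — with a global-family option.
The default contrast family for a factorial design is the bracket set:
day vs night within population × season, summer vs winter within
population × period, and population vs population at matched
season × period (12 contrasts per parameter for a 2×2×2 design).
Stars: `*` p < 0.05, `**` < 0.01, `***` < 0.001, `****` < 0.0001 on the
adjusted p.

## CAP ordination

CAP (canonical analysis of principal coordinates) is a PCoA of the
distance matrix followed by a canonical discriminant analysis of the first
m orthonormal PCoA axes against the group-indicator space. Defaults:
z-scored parameter matrix (population SD), Euclidean distances, Gower
double-centering G = −½ J D∘D J, symmetric eigendecomposition with axes
kept when the eigenvalue exceeds 10⁻⁹ of the spectral range. With
Euclidean distances this reproduces PCA of the centered matrix exactly
(a test asserts |columnwise correlation| = 1), but the implementation
goes through the distance matrix so that other dissimilarities can be
plugged in.

* **Axis count.** m = "auto" scans 1..min(rank, n−2) and keeps the m with
  the highest leave-one-out allocation success, breaking ties toward the
  smallest m to avoid overfitting.
* **Leave-one-out protocol.** Each holdout's PCoA is re-estimated from the
  remaining n−1 samples and the held-out point is added by Gower's
  projection formula, so no information leaks from the holdout into the
  axes. (Column standardization is performed once on the full matrix,
  as the normalization is treated as part of data preparation.)
  Classification is by the nearest group centroid in the canonical space;
  the implementation exploits the fact that this equals nearest-centroid
  allocation in the first m orthonormal PCoA coordinates — the canonical
  rotation spans the group-centroid subspace, and the components it
  discards contribute equally to every centroid distance — which makes
  the LOO scan for all m a single vectorized pass.
* **Permutation test.** The statistic is the trace of Q_m′HQ_m (the sum of
  squared canonical correlations). Because "auto" chooses m using the
  labels, each of the n_permutations (default 999) relabelings re-runs the
  entire procedure — LOO scan, m selection, trace — on the permuted
  labels. The label-independent LOO geometry is computed once and reused,
  so this exactness costs little; permuting only the final trace at the
  observed m is measurably anti-conservative (~2× the nominal level in
  our null simulations), while the full re-selection scheme is exact by
  exchangeability and calibrates to the nominal level in the test suite.
  p = (1 + #{permuted trace ≥ observed})/(n_permutations + 1).

## The synthetic generator

A transient is F(t) = F₀ + (F_M − F₀)·Σᵢ wᵢ(1 − e^(−kᵢt)) with three
ordered rates — the simplest strictly increasing family whose J- and
I-like inflections, V_J and M₀ are controllable, with every JIP quantity
available in closed form. Defaults: rates (1500, 80, 4) s⁻¹, weights
(0.45, 0.30, 0.25), F₀ = 5000 a.u., F_M/F₀ = 5, sampled at 160 log-spaced
points over 10 µs – 1 s, multiplicative Gaussian noise with relative SD
0.02 (detector-like behavior at high signal, clipped to stay positive).

The default experiment mirrors a two-site field campaign: 2 populations ×
2 seasons × day/night × 10 replicates = 80 samples, with factorial effects
on the kinetics (population → F₀ level and F_M/F₀ ratio; season → phase
weights and the terminal rate, i.e. V_J and Area; day/night → F₀ scaling
and the J-phase rate) and between-sample biological jitter (relative SD
0.03 on F₀ and F_M, 0.015 on the J-phase weight). Under these conditions
the eight cell means sit well apart (≥ 4 pooled within-group SDs in the
standardized parameter space) and the CAP step typically re-allocates
~92–96% of samples correctly.

Closed forms: landmark values are direct evaluations of F(t);
the complementary area to the asymptote over [t_start, T] is
(F_M − F₀)·Σᵢ wᵢ/kᵢ·(e^(−kᵢ t_start) − e^(−kᵢ T)). Because a finite
acquisition window ends below the asymptote (the default grid stops at
1 s while the slowest phase saturates around 2.5 s), the oracle used for
recovery scoring adopts the extractor's own convention — complement to
the attainable plateau F(t_max) — obtained from the same closed form by
subtracting (F_M_true − F(t_max))·(t_max − t_start). With the asymptotic
convention instead, the two Area definitions differ by several percent at
the default window, which is a property of the window, not an extraction
error.

What the generator does **not** emulate: photoinhibited K-bands,
baseline drift, detector saturation, additive dark noise (an additive
floor is configurable but off by default), non-exponential kinetics of
real PSII electron transport, and any dependence of kinetics on
temperature or light history. Passing recovery tests therefore shows the
extraction pipeline is correct for well-behaved polyphasic rises, not
that it is robust to every field artifact.

## Problem sizes and runtime choices

Simulation-based tests use the sizes at which the statistical properties
are already informative: 500 replicates for type-I-error and permutation
calibration checks, 200 for power and bias checks, 50 random kinetic
specs for oracle recovery, 40 end-to-end null runs at 5 replicates per
cell. The full suite runs in a few minutes on one CPU.

## Known limitations

* The exact contrast family and the CAP axis-retention rule of any given
  published study are rarely reported; both are configurable here and the
  defaults are labeled in the outputs.
* The rank-sum test's asymptotic branch is slightly conservative at small
  group sizes with heavy ties.
* CAP's LOO success estimates are optimistic when m is selected on the
  same data (the selection is honest within each holdout, but the choice
  of m itself sees all samples); the permutation p is exact regardless.
* lux→PAR conversion uses a single spectral factor (0.019 for ~6000 K
  sunlight) and is only as good as that approximation.
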