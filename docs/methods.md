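# Methods

## The system being modelled

In a mother-machine microfluidic device, the cell at the closed end of
each growth well — the *mother* — inherits the same old pole at every
division, while its sibling — the *daughter* — inherits the pole formed at
the previous fission and is washed out after a cycle or two. Misfolded
proteins, reported here by a DnaK-msfGFP fusion, cluster into a single
polar aggregate that the mother retains across generations. The analysis
quantifies four linked phenomena on tracked per-cycle data:

1. **Elongation.** Single cells elongate exponentially,
   L(t) = L₀·exp(r·t); the per-cycle rate r (min⁻¹) is the slope of an
   ordinary least-squares fit of ln L on t. This is deterministic and
   closed form, exact on noiseless exponential input, and unbiased under
   multiplicative observation noise.
2. **Aggregates.** On each cycle's first fluorescence frame, a 1D
   transect from old pole to new pole is scanned for a bright focus. The
   focus diameter d, its distance to the old pole, its mean and peak
   intensity, and the relative aggregate length ρ = d/L are recorded, and
   the transect is partitioned exactly into aggregated and dispersed
   pixel means.
3. **Asymmetry.** Cells born at the same fission are paired; the
   morphological asymmetry A = L₀(mother)/L₀(daughter) exceeds 1 when the
   aggregate displaces the septum toward the new pole.
4. **Statistics.** Aggregate diameters are regressed linearly on time
   (they widen at a constant rate until they approach the cell width);
   competing additive models of elongation rate (role, aggregate
   presence, time smooths, tensor interactions) are ranked by AIC with a
   ΔAIC > 2 support rule; distributions are compared with two-sided
   two-sample Kolmogorov–Smirnov tests and Welch t tests; binned
   summaries drop bins with fewer than 10 points.

## Synthetic lineage generator

The generator (`SimConfig`, `simulate_lineages`) emulates the
data-generating process so that every downstream stage can be tested
against known ground truth. Per well it follows one mother lineage for
the full duration and each retained daughter for one cycle. Defaults are
the study conditions; every stochastic draw flows from one seeded
generator, so a fixed seed reproduces a run byte for byte.

| parameter | default | meaning |
|---|---|---|
| `r_free`, `r_sd_free` | 0.0162, 0.0049 min⁻¹ | elongation rate of aggregate-free cells |
| `r_sd_bearing` | 0.0039 min⁻¹ | rate SD of aggregate-bearing cells |
| `beta` | 0.2 | rate penalty per unit relative aggregate length |
| `agg_onset_prob` | 0.052 | per-generation nucleation probability |
| `d0`, `k` | 0.4 µm, 0.01 µm/h | diameter at nucleation; linear growth rate |
| `k_jitter_sd` | 0.05 µm | per-generation diameter fluctuation |
| `delta`, `delta_sd` | 0.22, 0.05 µm | pole-to-focus-edge gap, mean and cell-to-cell SD |
| `baseline_mean`, `baseline_sd_cell` | 776.5, 250.5 a.u. | dispersed fluorescence level, between-cell SD |
| `agg_mean`, `agg_peak` | 1799.4, 2305.3 a.u. | focus span mean and peak intensity |
| `daughter_agg_prob` | 0.036 | probability a daughter carries a focus |
| `mother_birth_length_mean` | 2.82 µm | mother birth length before fission displacement |
| `asym_gain` | 0.5 | extra mother birth length per µm of aggregate diameter |
| `mean_width` | 0.8 µm | cell width; hard ceiling on aggregate diameter |
| `pixel_size` | 0.065 µm/px | transect sampling (typical 100× widefield) |
| `phase_cadence`, `fluor_cadence` | 2, 10 min | length and fluorescence frame intervals |

Within a cycle, r = max(ε, N(r_free, r_sd)·(1 − β·ρ)) with ρ evaluated at
birth; division fires when length doubles (equivalent to a timer under
exponential growth — adder-style size control is deliberately out of
scope). Aggregates nucleate once per lineage (first success of a
per-generation Bernoulli trial; a calibration mode `nucleate_at_start`
places the focus at t = 0 in every lineage so that pooled diameters
follow d₀ + k·t directly). The diameter at generation g is
d₀ + k·(t_g − t_nuc) + N(0, k_jitter_sd), clamped to [0, width]. At each
fission the mother's birth length is
`mother_birth_length_mean + asym_gain·d` plus N(0, 0.1 µm); the daughter
receives the remainder of the doubled length, which yields A > 1 exactly
when a focus is present and a positive correlation between A and d.
Observed lengths carry 1% multiplicative noise.

Calibrated values: `agg_onset_prob = 0.052` was solved by sweeping the
generator's ground-truth event log so that 66.9% of completed mother
divisions carry a focus over a 40 h run (8 seeds × 100 wells: 67.3 ±
0.9%); `beta = 0.2` follows from requiring the mean bearing-cell rate
0.0156 ≈ 0.0162·(1 − β·E[ρ]) with E[ρ] ≈ 0.18 at the default geometry.

**Transect rendering.** A cell of length L maps to round(L/0.065) pixels.
Each transect draws a per-cell baseline from N(776.5, 250.5) plus i.i.d.
per-pixel noise N(0, 60), floored at zero. A focus spans
[gap, gap + d] and is rendered as a raised cosine on a pedestal; the
pedestal and amplitude are solved **on the pixel grid** so that the
rendered span's mean and maximum equal `agg_mean` and `agg_peak` exactly.
Two choices here are deliberate. First, a pure raised cosine cannot
satisfy both printed focus statistics (it forces mean = peak/2 above
baseline; the configured values imply a ratio of 0.669), hence the
pedestal. Second, the pedestal gives the focus a sharp support edge
(≈520 a.u. above baseline at the boundary), which makes the rendered
diameter a well-posed quantity: a threshold-crossing span rule recovers
it without the systematic shrinkage a smoothly tapering bump would
suffer. The pole gap is drawn per cell, N(0.22, 0.05) truncated at 0 —
the 0.22 µm figure is a cohort average, and a literally fixed gap would
also pin the focus edge at a fixed sub-pixel phase and bias every
pixel-quantized diameter by a constant (up to half a pixel).

**What the generator does not emulate.** No 2D imagery, photobleaching,
phototoxicity, cell death, tracking errors, segmentation noise beyond the
length/intensity noise above, aggregate dissolution or splitting,
multiple simultaneous foci per cell, or adder-based size control. Tests
passing on this generator therefore validate the estimators under the
stated generative assumptions — unbiasedness, conservation, calibration —
not robustness to every artefact of real segmentation output.

## Aggregate detection

Baseline = transect median; noise scale = Rousseeuw–Croux Qn (robust to
the focus itself, like the MAD, but efficient enough at ~45 pixels that
the false-positive rate stays at the known-σ floor of ~0.6% instead of
the ~2.5% the MAD's sampling noise produces; `scale_estimator="mad"` is
available). Candidate peaks are local maxima with height above
baseline + 3·scale and prominence above 3·scale; the span is the maximal
contiguous run above baseline + 1.5·scale around the peak, minimum 2 px,
with spans separated by <2 px merged. One call per cell: the span
nearest the old pole is reported (others are kept as diagnostics),
because the biology of nucleoid occlusion makes the polar focus the
object of interest. Reported quantities: d = span·pixel_size,
distance to the old pole (pole-to-span-edge by default — a polar focus of
diameter d cannot have its center nearer than d/2, so the edge distance
is the size-invariant quantity; center mode is available), span mean and
peak intensity, and ρ = d/L. An alternative absolute mode accepts a span
only when its mean exceeds 1,000 a.u.

The fluorescence partition is exact pixel arithmetic:
n_agg·F_agg + n_disp·F_disp = n_total·F̄ holds on every cell by
construction, and is asserted on every simulated cell in the tests.

## Statistical layer

- `fit_diameter_growth`: OLS of d on time restricted to t ≤ 40 h (the
  linear regime; diameters saturate at the cell width beyond it).
- `compare_models`: additive models via statsmodels GLM/GLMGam with
  penalized B-spline smooths (fixed penalty weight, default α = 1, basis
  dimension per term in the spec), factor terms as treatment-coded
  dummies, and tensor-product interactions built as centered products of
  marginal B-spline bases appended to the parametric design. Families:
  Gaussian, or negative binomial with identity link for fluorescence
  responses; an identity-link fit that fails to converge falls back to
  Gaussian with a note in the result. Ranking by AIC; a model is flagged
  substantially better only when ΔAIC > 2 over the runner-up. With these
  choices the role-effect selection has ≈100% power at a 2-SD effect
  (n = 2000) and a ~5% false-selection rate without an effect
  (ΔAIC > 2 ⇔ a χ²₁ deviance improvement > 4).
- `binned_summary` anchors fixed-width bins at the data minimum and
  suppresses bins with n < 10 (their counts are retained so totals
  conserve). Defaults elsewhere in the pipeline: 2 h bins for time axes,
  0.05 for ratio axes.
- Welch's unequal-variance t is used for all two-sample t tests (the
  printed cohort SDs differ), `scipy.stats.ks_2samp` for KS tests.

## Numerical choices and degenerate inputs

- Elongation fits require ≥3 points and positive lengths; a constant
  series returns r = 0 with R² defined as 1 (zero total variation).
- Observed length series are validated for strictly increasing *times*
  only; with 1% multiplicative noise an occasional single-frame length
  decrease is expected, as in real segmentation output.
- Detection requires ≥8 px; an exactly flat background (zero robust
  scale) falls back to a vanishing noise floor so that any excursion
  above the median is treated as signal.
- Diameter-rate estimation skips, but flags, generation gaps; both
  per-hour and per-generation denominators are emitted.
- Spans are half-open pixel intervals [start, end); reversing a transect
  maps a span [s, e) to [N−e, N−s) exactly.
- Two-point linear fits report R² = 1 and are flagged `low_n`.
- All CSV output is UTF-8 with '.' decimals; numeric parsing uses
  correctly rounded conversion so that write→read→write is
  byte-identical.

## Problem sizes

Tests and the acceptance script run the pipeline at 200 wells × 40 h
(~10⁴ mother cycles, ~2×10⁴ transects) for cohort-level recoveries, 10³
rendered transects for detector fidelity, 10³ cycles for estimator bias,
and 100 replicates × n = 2000 for model-selection operating
characteristics. These sizes put Monte-Carlo standard errors well below
the effect sizes being checked while keeping a full run in tens of
seconds.

## Known limitations

- The diameter trend reaches the width ceiling (0.8 µm) exactly at the
  40 h window end in calibration mode, so the clamp clips the upper
  jitter tail over the last hours and the realized pooled slope sits ~2%
  below k. The pipeline recovers the generator's realized truth without
  bias; recovery of the nominal k is correspondingly ~2% conservative.
- The irreducible ~0.6% detector false-positive rate adds to the 3.6%
  planted daughter focus rate, so the detected daughter incidence reads
  ~4.2–4.4% end to end.
- The additive-model layer implements the comparison *framework*; it
  does not attempt to reproduce study-specific deviance-explained
  percentages, which depend on the original tracked dataset.
- Smoothing penalties are fixed rather than selected by ML/REML;
  comparisons are therefore between models of fixed effective
  complexity.
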