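# Methods

## Problem and scope

Given an arclength-sampled lumen diameter profile `d(s)` (mm) of one
epicardial coronary artery and the invasively measured proximal/distal
pressure pair (P_a, P_d, mmHg), the package predicts absolute flow at the
inlet, outlet and side branches, the along-vessel flow and pressure
profiles, and microvascular resistance. The inlet is anchored at the P_a
measurement site (`s = 0`), the outlet at the P_d site. Angiographic
reconstruction itself (centerline extraction, border detection) is out of
scope: the profile CSV is the input contract.

## Side-branch flow: magnitude and distribution

**Magnitude.** Murray's law at a bifurcation, `D_PV^x = D_DB1^x + D_DB2^x`,
implies that over a healthy taper from calibre `h(0)` to `h(L)` the main
lumen retains the fraction `(h(L)/h(0))^x` of inlet flow. The exponent `x`
is biologically between 2 (area-preserving) and 3 (Murray's optimum);
`MurrayConfig` validates this range by default and defaults to **x = 3.0**,
the classical value. No patient-specific optimum is assumed; the value is a
configuration parameter, and `synthetic.recover_exponent` shows it is
identifiable from flow data when ground truth exists.

**Healthy envelope.** Atherosclerotic narrowing must not be read as
branch-related taper. The envelope `h(s)` is defined as the running maximum
of `d` taken from the outlet backwards — the minimal non-increasing curve
that dominates the profile. It is flat across any region whose diameter
recovers downstream (the signature of a stenosis rather than of taper), is
idempotent, and equals the profile exactly when the profile is already
monotone. No closed formula for this filter exists in the literature we
follow; the running maximum is the natural operationalization, and its
properties (dominance, monotonicity, idempotence, refinement invariance)
are property-tested. Because total side-branch flow is computed from
*envelope* endpoints, a locally diseased inlet or outlet sample cannot
corrupt the flow split — the method degrades gracefully rather than
requiring the user to guarantee healthy end sections.

**Distribution.** Two leak profiles share the same endpoints (hence the
same total side-branch flow, to 1e-9):

* *regional*: `g(s) = (h(s)/h(0))^x` — leak concentrated exactly where the
  healthy calibre drops; zero across envelope-flat (stenotic) stretches;
* *homogeneous*: `g(s)` linear in `s` from 1 to `(h(L)/h(0))^x` — constant
  leak per unit **arclength**. (Uniform-per-unit-wall-area was considered
  and rejected: it would weight leak by local diameter, which is neither
  simpler nor better motivated.)

The discrete `leak_density` is stored per segment as the exact difference
quotient of `g`, so its arclength integral equals the total shed fraction
identically, not just approximately.

## Flow solve

Steady, laminar, Newtonian flow with standard blood parameters
(ρ = 1056 kg/m³, μ = 0.0035 Pa·s). Units are mmHg / mL/min / mm at every
interface and SI internally (1 mmHg = 133.322 Pa).

* **Viscous term.** Per segment, Poiseuille resistance
  `128 μ Δs ḡ /(π D̄⁴)` with segment-mean flow fraction and diameter;
  summed into a linear coefficient α. On a uniform tube this is exact, and
  on piecewise-linear profiles halving the grid changes the result by
  < 0.1 % (measured ~1e-3 %).
* **Expansion term.** Irreversible Borda–Carnot loss `½ρ(v_up − v_down)²`
  where `v = g·q_in / A`. The loss is charged **per maximal monotone
  velocity-decrease run** (local peak to the following trough), not per
  grid segment: per-segment charging would make the loss vanish as a
  smooth deceleration is sampled more finely, whereas the run-based form
  is grid-stable and reduces exactly to the classical sudden-expansion
  loss when the decrease occupies one segment (e.g. a branch step or a
  stenosis recovery). For the pressure profile, each run's loss is spread
  over its segments in proportion to the local velocity fall.
* **No Bernoulli recovery by default.** At an expansion the reversible
  Bernoulli pressure rise is not credited (recovery coefficient 0), the
  conservative convention for stenosis modelling; `recovery ∈ [0, 1]`
  scales the expansion loss down ( `recovery = 1` makes expansions
  lossless). With the default, the computed pressure profile is
  non-increasing.

Because `g(s)` is purely geometric, the total drop is
`ΔP = α q_in + β q_in²` and the positive root is closed-form; no iterative
solver exists anywhere in the package. `P_a = P_d` returns zero flow with a
`no-gradient` flag. A Reynolds advisory is logged above Re = 2000; the
laminar model is not otherwise gated.

**Rmicro.** `P_d / Q` in mmHg·min/L with Q in L/min. The outlet flow is
used by default (`rmicro_flow="inlet"` switches), since P_d is measured at
the outlet; on the published per-case data both conventions are consistent
with the printed values within rounding.

**Diameter sensitivity.** `diameter_sensitivity` re-solves with all
diameters shifted by ∓/±δ, quantifying the `D⁴` sensitivity of
Poiseuille-dominated flow to reconstruction error (one angiographic pixel).
The response is convex — the flow gained by +δ exceeds the flow lost by
−δ — which the tests assert qualitatively.

**Relation to 3D CFD.** The reference workflow this package parallels used
a 3D finite-volume solver on the reconstructed lumen. Here the geometry
enters through a 1D reduced-order surrogate, because the contribution being
studied is the *flow-split logic*, not the 3D discretization. Per-case
agreement with any particular 3D solver's flow values is therefore not
claimed, and only aggregate statistics of the packaged validation table are
reproduced.

## Validation statistics

Conventions pinned by recomputing the packaged 27-case table:

* **Population (divisor-n) SD** everywhere: it reproduces the printed
  61 / 96 / ±175 values (sample SD gives 63 / 98 / ±178 and does not).
* **Tukey-hinge IQR** (median of each half, overall median excluded for odd
  n): reproduces the printed [290–450].
* **Bland–Altman**: delta = test (computed) − reference (invasive); limits
  = mean ± 1.96 × pop-SD.
* **Passing–Bablok** (1983 rank procedure): slope = shifted median of
  pairwise slopes (slopes = −1 excluded, offset K = #slopes < −1; vertical
  pairs count as ±∞, 0/0 pairs dropped), intercept = median(y − m·x),
  reference method on the independent axis; CIs from the normal
  approximation of the rank offset. Published CI bounds differ slightly
  from ours (different index-rounding conventions exist across
  implementations); point estimates agree.
* **Pearson p-values are two-sided** (t distribution, n − 2 df).
* **MVD threshold** strictly greater than 460 mmHg·min/L; diagnostics are
  per *case* here — a per-patient mapping is not available in the packaged
  table, so published per-patient percentages are not recomputed.
* **Log transform** for skewed variables is available
  (`PairedSample.log_transformed`) but off by default, since which printed
  quantities used it is not recorded.

## Synthetic data generator

`synthetic` builds vessels from known ground truth so every solver and
regionalization property is testable without clinical data:

* **Branch steps** are instantaneous (one sampling interval wide), with the
  parent stepping to `(D_before^x − D_daughter^x)^(1/x)` — the sharpest
  test of the claim that regional leak localizes at branches (≥ 99 % of
  leak within ±1 mm of true take-offs on noiseless vessels).
* **Stenoses** are Gaussian diameter dips with compact support (truncated
  at 4σ and renormalized so the peak equals the requested severity): the
  downstream recovery is then exact, so a mid-vessel stenosis leaves the
  envelope endpoints — hence the total side-branch flow — bit-for-bit
  unchanged.
* **Noise** is additive Gaussian on diameter (default SD 0.05 mm in the
  noisy tests, the scale of single-pixel reconstruction error), truncated
  so the lumen stays above 0.2 mm.
* **Cohorts** default to the conditions of the clinical validation cohort:
  2–4 branches (daughter calibre 40–70 % of local parent), 0–2 focal
  stenoses of 10–50 % severity, inlet diameter 3.0–4.5 mm, length
  40–80 mm, P_a ~ N(92, 8) mmHg and hyperaemic flow ~ N(220, 60) mL/min.
  The distal pressure is *derived* from the drawn flow through the
  vessel's own loss curve (`P_d = P_a − αq − βq²`, gradient capped at
  P_a − 30 mmHg), so pressures, flow and disease burden are mutually
  consistent; drawing FFR independently of geometry produces litre-scale
  flows no clinician would accept. A consequence worth knowing: simulated
  pressure ratios run high (≳ 0.95) because only discrete focal losses are
  modelled — diffuse disease and viscous amplification at the throat are
  not.

What passing these tests shows — and does not. The generator emulates
taper, branch steps, focal stenoses with recovery, and diameter noise. It
does not emulate diffuse disease, reconstruction bias (systematic calibre
error), out-of-plane curvature, or pulsatility; conclusions about those
require clinical data.

## Numerical choices and degenerate inputs

* Default resampling step 0.1 mm, linear interpolation (profiles are
  piecewise-linear reconstructions; sampling density of real
  reconstructions is not standardized, 0.1 mm is sub-pixel for angiography).
* Profile validation is strict: strictly increasing `s` starting at 0,
  positive diameters, ≥ 2 samples; CSV errors name the offending data row.
* Envelope/leak arithmetic clips negative round-off in the discrete leak
  density at 0 and rebuilds `g` by exact summation, keeping the
  conservation identity at the 1e-9 level the tests demand.
* `P_a = P_d` → zero flow, flagged, Rmicro undefined (NaN). Zero-resistance
  geometry is unreachable through validated types (positive viscosity and
  diameters), but guarded.
* The 27-case fixture is checksummed (SHA-256) at load; statistics are
  row-order invariant.

## Known limitations

* The reduced-order solve ignores curvature, non-Newtonian rheology, wall
  compliance and pulsatility; it is steady-state by construction.
* Murray exponent default (3.0) is a convention, not a fitted value.
* Regional and homogeneous methods share total side-branch flow but can
  differ noticeably in q_in on strongly stepped geometry, because where
  the leak thins the flow changes which segments carry full flow; they
  coincide exactly only in the leak-free limit.
* Per-patient diagnostics (prevalence, sensitivity/specificity as
  published) are not reproducible from the per-case table and are not
  attempted.
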