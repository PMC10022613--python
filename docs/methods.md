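# Methods

`cavistress` models and analyses the terminal phase of leaf dehydration in
a drying woody plant: the point at which xylem cavitation stops being a
gradual loss of transport capacity and becomes a self-amplifying collapse
that severs water supply to the mesophyll.  This note documents the model,
the estimators, the synthetic-data generator, and the numerical and design
choices behind them.

## Hydraulic model and the runaway point

Leaf hydraulic conductance is a sigmoid in bulk leaf water potential Ψ
(MPa, negative under tension):

    K(Ψ) = K_max / (1 + exp((P50 − Ψ) / α)),       α > 0

with K_max the well-hydrated conductance (mmol s⁻¹ m⁻² MPa⁻¹), P50 the
potential at half loss, and α the slope parameter (MPa).  Written this way
the curve is strictly increasing in Ψ — conductance is lost as the leaf
dries — and `K(P50) = K_max/2` holds exactly.  The same expression is
sometimes printed with the sign of the exponent reversed; that form is
decreasing in tension for α > 0 and is not self-consistent with the
runaway formulas below, so this package fixes the convention to the
physical one and requires α > 0.

After stomatal closure the only demand is cuticular transpiration

    E_c = g_min · VPD / P_atm           (mmol m⁻² s⁻¹)

with the vapour-pressure deficit from the Arden–Buck saturation formula,
`VPD = (1 − RH/100) · 0.61121 · exp(17.502 T / (240.97 + T))` kPa, assuming
saturated internal airspaces.  Supply from an upstream source at Ψ_s is
`K(Ψ_l) · (Ψ_s − Ψ_l)`.  As the source dries, the supply curve's maximum
over Ψ_l shrinks; when it falls below E_c no steady state exists and leaf
water potential goes into free fall while embolism self-amplifies.  Setting
∂/∂Ψ_l [K(Ψ_l)(Ψ_s − Ψ_l)] = 0 together with supply = E_c gives the
closed-form onset:

    Ψ_runaway   = P50 − α ln(α K_max / E_c)
    PLC_runaway = 100 · x / (1 + x),   x = α K_max / E_c

`runaway_point` implements these; `runaway_point_numeric` finds the same
point with no algebra — a bounded scalar maximisation of supply over Ψ_l
nested in a bisection on Ψ_s — and the two agree to ≤ 1e−6 MPa over broad
random parameter sweeps.  With the mean study parameters (K_max 5.77,
P50 −3.73, E_c 0.19, α 0.09) the onset is −3.82 MPa at 73.2% PLC.

The slope α deserves a note: it is not separately reported with the other
means, and no single (K_max, P50, α, E_c) tuple reproduces both a −3.82 MPa
onset and a 79.2% onset PLC, because those summary values are means of
per-plant calculations with per-plant slopes.  The package's worked
examples use α = 0.09 MPa, the value for which the closed form reproduces
the mean onset potential given the mean K_max, P50 and E_c; α is always a
configuration parameter, never hard-coded in analysis paths, and the
PLC/potential pair is checked through the self-consistency identity
`plc_at_psi(Ψ_runaway) = PLC_runaway` rather than against a single printed
pair.

### Dynamic drydown

`simulate_drydown` integrates the lumped water balance

    C dΨ_l/dt = K(Ψ_l)(Ψ_s(t) − Ψ_l) − E_c

with Ψ_s declining linearly (default −0.5 → −6 MPa over 5 days) and C a
leaf capacitance in mmol m⁻² MPa⁻¹.  Capacitance is not a measured study
quantity; the default of 40 keeps the leaf within a few thousandths of a
MPa of its quasi-steady state on the default ramp, so the simulated onset
matches the closed form to better than 0.02 MPa, while still producing a
visible post-onset acceleration.  Runaway onset is flagged by loss of
existence of the quasi-steady root (maximum supply < demand), computed
once as the critical source potential by bisection — not by a slope
heuristic, which is noisy exactly where it matters.  Integration is
classical RK4 at a fixed 1-minute step; the system is non-stiff before
onset and the post-onset free fall (asymptotic slope −E_c/C) is resolved
at that step.  No spatial propagation of embolism is modelled here; the
network aspect lives in the image-based modules.

## Synthetic drydown experiments

The generator produces every input the pipeline consumes, under the study
conditions: a five-day linear stem-potential ramp sampled every 5 minutes,
13 replicate leaves for optical work, 6 plants for Fv/Fm and stem curves.
All generators are deterministic under a seed.

**Vein network.** A procedural leaf on a 256×320 grid at 20 µm/px: a 5-px
midrib across the centre (split into 4 segments), 8 major veins (2 px)
running from midrib to margin, and a reticulum of ~70 high-order-vein
(HOV) segments — 1-px transverse lines broken at each major vein, 20 µm
wide at the default scale (the order is defined by diameter < 50 µm).
HOV lines keep a 3-px standoff from major veins so that distinct veins
never abut at pixel resolution.  The mesophyll area uniquely served by
each HOV segment is the set of pixels nearer to it than to any other HOV
(the half-distance-to-neighbour rule), computed by an exact Euclidean
distance transform; midrib and major-vein pixels are excluded, being
supplied directly.  The served regions therefore tile the mesophyll
exactly, and the residual once every HOV is cavitated is the large-vein
footprint, just under 5% of the lamina.

**Event schedules.** Cavitation trigger potentials per order are drawn
from the logistic law `F(Ψ) = 1/(1+exp((Ψ−p50)/α))` so the realised
cumulative curve converges to the configured sigmoid.  Defaults are the
study's order means (midrib −3.35, major −3.80, HOV −4.07 MPa); the HOV
slope (0.202 MPa) is set so the 20% crossing sits at −3.79 MPa,
consistent with the printed P20/P50 pair, and the larger orders use
0.25 MPa.  Midrib and major segments receive `round(N(9.4, 1.17))` and
`round(N(4.53, 0.51))` events each (minimum 1); every HOV segment
cavitates exactly once.  Larger-vein events occupy vessel-scale
sub-stripes of their segment (a 3-row band of the midrib, a short run of
a major vein) so that several distinct events fit on one segment; HOV
events flash the whole segment, with a one-row halo emulating the slight
optical bleed of a flash beyond a fine conduit.  Trigger potentials are
mapped to frames through the *noiseless* ramp — events fire when the
plant truly reaches the trigger tension — while analyses join detections
to the noisy psychrometer record, as they would for real data.  Footprint
sizes set the per-order area shares of the pooled curve; at the defaults
the whole-leaf 50% crossing lands near −3.75 MPa, matching the study's
leaf-level mean.

**Image stacks.** Frames are background 40, lamina 130, veins 110
(arbitrary grey units), with iid Gaussian pixel noise (σ = 2) and flash
amplitude 10 — a per-pixel SNR of 5 — lasting 2 frames.  With margin
shrinkage enabled, the lamina half-width follows the width series.  No
optical physics is attempted; the generator reproduces the *statistics*
detection has to cope with (noise, transience, thin structures), not
photorealism, so passing tests say nothing about, e.g., illumination
drift or leaf curling in real rigs.

**Scalar series.** Leaf width follows the printed calibration
`width% = 6.1963·Ψ + 106.22` with Gaussian noise; after the configured
breakpoint the leaf potential decouples from the stem with a 3× steeper
slope (a piecewise stand-in for the runaway acceleration; the ODE route
is available but the piecewise form is the default for speed).  Fv/Fm
holds a 0.80 plateau (a typical healthy dark-adapted value; only the
death threshold < 0.2 is a study number) and declines linearly to 0.05 at
−6 MPa below its breakpoint.  The g_min trace is an exponential stomatal
phase relaxing into a linear cuticular phase whose slope encodes the
configured conductance.  The pressure–volume series uses the standard
construction: osmotic potential π(d) = π₀/(1 − d/(1−a_f)) with turgor
declining linearly to zero at the turgor loss point (defaults π₀ = −1.7
MPa, apoplastic fraction 0.3, TLP −2.01 MPa).  Rehydration-kinetics
records hold the peak flow at Ψ_init and the half-flow point, both drawn
from one vulnerability curve so the two implied conductances agree.

## Optical quantification

Detection follows the classic frame-subtraction workflow with a few
robustness choices that matter at SNR 5:

- **Threshold**: Otsu's method on the pooled nonzero differences, floored
  at 3 robust noise standard deviations (the median of |ΔI|, which is
  half-normal under pure noise, divided by 0.6745).  The floor makes the
  noise-only false-positive rate negligible where Otsu alone would split
  the noise distribution.  A fixed numeric threshold can be supplied.
- **Labelling**: per-frame connected components on a one-pixel-dilated
  mask (noise knocks pixels out of thin footprints; dilation bridges the
  gaps), with areas counted on the undilated mask and a 4-px minimum.
- **Temporal merging**: components in frames ≤ 2 apart are merged when
  their dilated sets touch *and* they share at least half of the smaller
  one's pixels — a transient flash produces an onset and an offset episode
  on the same footprint, while two distinct events that brush the same
  pixels share far less.  Merged events spanning only one difference frame
  are rejected as noise (every transient flash spans two).
- **Assignment**: order by majority pixel overlap with the label mask,
  ties toward the lower order; events store every segment they touch
  (≥ 3 px), so a detection spanning a junction counts for each vein it
  empties, and cumulative curves weight events by their on-skeleton
  (xylem) pixel area.

At the default rendering this recovers the scheduled per-segment counts to
within ~3% (the residual is physical: two events on one segment within two
frames and overlapping footprints are indistinguishable from one), order
assignment errors are not observed, and HOV segments come out at one event
each.  Cumulative curves are normalised per order by final cumulative
area — the optical convention of "% of total embolism" — not by anatomical
xylem area.  The 20%-of-HOV threshold is computed on cumulative area;
under the uniform vein widths of the generator the area- and length-based
readings coincide.

Leaf width is measured per frame as the midrib-edge-to-margin distance
along three transects (median), with per-frame missing flags rather than
hard failures when the margin is not found.  Functional-area loss
subtracts each cavitated HOV segment's served region ("area" mode) or
paints a stripe of diameter equal to the mean neighbouring-HOV distance
("brush" mode, the ImageJ-paintbrush convention); area mode is the
default and the reported one.

## Estimators

- **Cumulative-curve fits**: least-squares two-parameter sigmoid
  (default) and a monotone alternative (isotonic regression + PCHIP) for
  shape-free cross-checks; P-levels invert the sigmoid analytically,
  `Ψ_p = p50 + α ln((100−p)/p)`.
- **Breakpoint regression**: the segmented-model iteration — OLS on
  `[1, x, (x−ψ)₊, 1{x>ψ}]` with the update `ψ ← ψ − γ̂/β̂₂` — with an SSE
  grid search over interior x values as fallback, an F-test against the
  single line so flat data reports "no breakpoint" instead of a spurious
  one, and a seeded nonparametric bootstrap for the breakpoint standard
  error (the closed-form SE is implementation-specific across packages,
  the bootstrap is not).
- **K_leaf**: per-record conductance `F/(area·|Ψ|)` standardised to 20 °C
  by the Vogel viscosity ratio; records whose two implied values differ
  by more than 10% are flagged.  The vulnerability curve is the
  four-parameter sigmoid `y = y0 + a/(1+exp(−(Ψ−x0)/b))` fitted from 8
  seeded multistarts; the reduction used by the runaway formulas is
  K_max = y0 + a (the wet plateau), P50 the numerically solved
  half-plateau crossing, α = |b|.  This mapping is explicit because the
  handling of a non-zero y0 in the slope entering the runaway formulas is
  genuinely open; absorbing it into the plateau is the choice made here.
- **g_min**: the steady phase is the longest terminal window with a
  rolling mass-loss slope stable to 5%; the slope there converts to
  `g_min = WL · P_atm / VPD` (WL in mmol m⁻² s⁻¹ via the molar mass of
  water).
- **TLP**: 1/Ψ against water deficit (fraction of saturated mass lost);
  the post-turgor segment is the largest dry-end segment with OLS
  r² ≥ 0.995 (≥ 4 points) — taking the largest passing segment rather
  than stopping at the first dip makes the rule robust to small-sample r²
  noise.  TLP is the wettest retained point; π₀ is 1/intercept at zero
  deficit.  The criterion values are package choices; no linearity rule
  is stated for the original analysis.
- **Group statistics**: one-way ANOVA with Tukey HSD (statsmodels); no
  additional multiplicity layer.

## Pipeline

`run_pipeline` runs synthesis → optical quantification → fitting →
reporting with per-stage seeds spawned from one root seed, so a run is
reproducible end to end.  Replicate sizes default to the study's (13
leaves, 6 Fv/Fm plants, 5 g_min and 5 PV leaves, 6 stem curves).  The
optical stage renders and re-detects by default (`optical_mode="render"`);
`"schedule"` feeds the ground-truth events to the identical downstream
analysis and is used where image rendering would dominate runtime (the
bundled tests).  The trait table carries pooled mean ± sd with provenance
tags resolving to the producing stage; the threshold report holds the
antisymmetric pairwise residual matrices (MPa, and minutes via the ramp)
between breakpoint-of-width, breakpoint-of-Fv/Fm, 20%-HOV, runaway, TLP
and deep stem cavitation, plus the ANOVA/Tukey contrasts of per-order
P50s and event counts.  With `couple_thresholds=True` the width and Fv/Fm
breakpoints are generated at the runaway potential of the configured
hydraulics, and the three recovered thresholds then agree to within
0.05 MPa — the coincidence scenario — while the default uses the
independently observed values (−3.62 and −3.53 MPa).

Stacks and psychrometer records are joined by nearest timestamp with a
maximum gap of half the frame cadence.

## Problem sizes

The bundled tests run the full-resolution geometry but keep rendered
stacks to half- or two-day ramps and use schedule-mode pipelines; the
acceptance script renders and re-detects thirteen full five-day stacks
(1441 frames of 256×320) for the event-count targets and uses the exact
closed forms where the quantity is analytic.  These sizes reproduce the
study's sampling structure while keeping a complete run in the minutes
range on one CPU.

## Known limitations

- The lumped ODE has no spatial structure; runaway here is a supply–demand
  existence argument, not a percolation model of embolism spread.
- The detector's residual ~3% undercount of larger-vein event counts is
  irreducible at the configured cadence: coincident overlapping events on
  one segment are one optical event.
- The renderer's noise is stationary and Gaussian; real OVT imagery drifts
  (illumination, leaf movement), and the width transects assume the leaf
  only shrinks perpendicular to the midrib.
- The smoother route for vulnerability curves is a cross-check, not a
  reimplementation of GAM smoothing; parametric sigmoids are the default.
- PV analysis reports deficit relative to saturated mass; dry-mass-based
  relative water content is not computed (it cancels from the TLP reading
  but not from absolute capacitance estimates, which are out of scope).
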