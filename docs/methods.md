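# Methods

This note documents the models, algorithms and numerical choices behind
`wkident`, in the order the method runs: the arterial model, the
closed-loop generator that provides validation data with an embedded
ground truth, the measurement pipeline, the per-cycle identifier, the
genetic cold start and the sensitivity analysis.

## 1. The five-element arterial model

The systemic arterial tree is lumped into five elements: a
characteristic resistance R_sa,0 at the aortic root, a proximal
compliance C_sa,1, an inertance L_sa, a distal compliance C_sa,2 and a
peripheral resistance R_sa draining into the venous bed.  With state
X = [p_ao, p_sa, Q_Csa1]^T, inputs U = [Q_ao, dQ_ao/dt, p_sv]^T and
output Y = p_ao, the element laws

    C_sa,1 d(p_ao − R_sa,0 Q_Csa1)/dt = Q_Csa1
    L_sa   d(Q_ao − Q_Csa1)/dt        = p_ao − p_sa
    C_sa,2 dp_sa/dt                   = Q_Csa2
    R_sa (Q_ao − Q_Csa1 − Q_Csa2)     = p_sa − p_sv

reduce to Ẋ = AX + BU, Y = CX with the matrices spelled out in
`wkident.windkessel`.  Useful closed forms used as test anchors: the DC
gain per input channel is [R_sa, L_sa, 1], and the first and third
columns of B are proportional with factor R_sa, so G₁(s) = R_sa·G₃(s)
at every frequency.

Units everywhere: mmHg, mL/s, mmHg·s/mL, mL/mmHg, mmHg·s²/mL, seconds.

The parameter vector Θ = (R_sa,0, R_sa, C_sa,1, C_sa,2, L_sa) has normal
values (0.1, 1.0, 0.9, 0.25, 0.0003) and a physiological search box
lb = (0.01, 0.5, 0.1, 0.1, 1e−5), ub = (0.5, 2.0, 2.0, 2.0, 0.1),
deliberately wider than the normal range.

**Discretisation.**  The predictor inside the identifier is forward
Euler, `X[k+1] = X[k] + h(A X[k] + B U[k])`, *not* a higher-order
scheme: the optimiser's constraint must be exactly the predictor, so
that the cost is exactly zero when the data were generated by that same
recursion.  The fast eigenvalue at normal parameters is ≈ R_sa,0/L_sa ≈
333 s⁻¹, so Euler needs h ≲ 1–2 ms there; corners of the search box
(small L_sa, large R_sa,0) are Euler-unstable at 1 ms and the predictor
reports divergence (with the step index and offending Θ) instead of
silently producing NaNs.  Inside the optimiser such parameter sets are
penalised with a large finite residual plateau.

## 2. Closed-loop cardiovascular generator

`wkident.cardio_sim` implements a fixed-topology lumped circulation:
four chambers (LV, LA, RV, RA) with periodic time-varying elastances,
four diode valves (mitral, aortic, tricuspid, pulmonic) each with a
series resistance and inertance, a five-element arterial block for each
of the systemic and pulmonary trees, and an RC bed for each venous
return.  The systemic arterial block is *bit-for-bit the model of
section 1*, so every generated trace has a well-defined parameter
ground truth for the identifier — the central design property of the
validation.

**Elastance.**  Chamber activation is the standard double-Hill wave
e(t) ∝ [(t/τ₁)^n1 / (1+(t/τ₁)^n1)]·[1/(1+(t/τ₂)^n2)], rescaled to peak
at exactly 1, with E(t) = E_min + (E_max−E_min)·e and p = E(t)(V−V₀).
Atrial activation uses the same form with short time constants and an
onset at 85% of the beat (atrial kick in late diastole).

**Valves.**  Ideal diode + R + L: when open, L dQ/dt = Δp − RQ; the
flow state is clamped to zero on closure (sign test on flow and
gradient), the standard lumped-valve treatment that avoids chatter.

**Integration.**  Explicit RK4 at dt = 0.1 ms internally (the valve and
characteristic-impedance dynamics are the stiff-ish part), sampled to a
1 kHz output grid.  Total stressed volume is recorded per sample; with
constant parameters it is conserved to ~1e−12 mL over 100 s.  During a
compliance ramp the stored volume C·p is deliberately *not* conserved
(the element law uses C(t)·dp/dt), which mirrors the idealisation of a
commanded compliance change; the drift over a 50 s ramp is ≈ −9 mL.

**Calibration.**  The chamber/valve/venous constants are this package's
own calibration: with the systemic arterial block fixed at the normal Θ,
the defaults were tuned so the normal 60 bpm run reproduces textbook
adult haemodynamics — cycle-mean aortic flow ≈ 84 mL/s (CO ≈ 5 L/min),
peak ejection flow ≈ 450 mL/s, aortic pressure ≈ 65–125 mmHg, LV
pressure ≈ 5–130 mmHg.  The shipped defaults give 84.3 mL/s, 447 mL/s
and 125.8 mmHg.  The main knobs were the LV activation time constants
(τ₁ = 0.45, τ₂ = 0.42 of the beat — a slower upstroke than the
τ₁ ≈ 0.27 often quoted for normalised elastance, needed to keep peak
flow near 450 mL/s while preserving stroke volume), the aortic valve
resistance (0.028 mmHg·s/mL) and the total stressed volume (886 mL).

**Experiment protocols.**  Piecewise-linear ramps on R_sa (1.0→1.3) and
C_sa,1 (0.9→0.8): baseline 0–50 s, rise 50–100 s, hold 100–150 s,
return 150–200 s.  A parameter sits at baseline outside its explicit
segments, so hold windows are explicit segments.

**Noise.**  Measurement noise is additive white Gaussian, by default
variance 10 in native units applied independently to all three measured
channels (p_ao, Q_ao, p_sv).  The variance is interpreted per channel;
whether a real acquisition would corrupt all three equally is a modelling
choice documented here — variance 10 on p_sv (≈ 8 mmHg signal) is a
much harsher relative corruption than on p_ao.

**What the generator does not emulate:** baroreflex and autonomic
control, respiratory modulation, beat-to-beat variability, distributed
(wave-propagation) arterial dynamics, valve regurgitation/stenosis and
pathological states.  Passing tests therefore demonstrate correctness
of the identification machinery against a known lumped truth, not
performance on clinical recordings.

## 3. Measurement pipeline

Traces are CSV files `t,pao,qao,psv[,extras]` on a strictly uniform
grid (tolerance 1e−9 s).  Cycles are cut either at fixed period (the
generator beats at exactly 60 bpm and anchors beats at end-diastole) or
by an upward flow-threshold trigger (default 5% of peak flow) for
variable-rate data; a trailing partial cycle is dropped.

The flow derivative is estimated by second-order differences (central
interior, one-sided ends).  Before buffering, *all* measured channels
pass through a Savitzky–Golay filter, default window 21 samples (21 ms
at 1 kHz), polynomial order 3.  This is part of the method, not
cosmetics: noise on the *input* channels makes the fit an
errors-in-variables problem and biases an output-error criterion toward
zero gains — with unfiltered variance-10 noise the identified R_sa,0
collapses to ≈ 0.05 and L_sa inflates by two orders of magnitude.  The
21 ms window is ~2% of a beat and well below the ~100 ms ejection
upstroke, so clean waveforms pass through essentially unchanged
(< 0.05 mmHg distortion); smoothing is configurable off.

## 4. Per-cycle identification

For each buffered cycle the cost is J(Θ) = Σ_k h (Y_k − Ŷ_k)², with Ŷ
from the Euler predictor, minimised subject to the box lb ≤ Θ ≤ ub.

**Solver.**  Bound-constrained least squares (SciPy trust-region
reflective), an active-set-style KKT-terminating method appropriate for
a 5-parameter box problem.  Termination: relative cost change 1e−4,
at most 100 iterations (a per-cycle budget suited to on-line use);
variables are scaled by their box widths (the parameters span four
orders of magnitude).  The Jacobian is analytic: forward sensitivities
S_k = dX_k/dΘ propagate through the same Euler recursion,
S_{k+1} = S_k + h(A S_k + (∂A/∂Θ_i) X_k + (∂B/∂Θ_i) U_k), seeded with
the derivative of the initial state.  A reflective method approaches an
active bound asymptotically rather than landing on it exactly; bound
activity is asserted to ~1e−4.

**Initial predictor state.**  Cycles start at end-diastole where
Q_ao ≈ 0, so p_ao ≈ p_sa = Y₁.  The compliances, however, are still
discharging through R_sa: the quasi-static split of that run-off gives
Q_Csa1(0) = −C_sa,1/(C_sa,1+C_sa,2)·(Y₁ − p_sv,1)/R_sa.  The naive
choice Q_Csa1(0) = 0 leaves a residual transient that persists over the
slow time constant R_sa(C_sa,1+C_sa,2) ≈ 1.15 s — essentially the whole
beat — and biases C_sa,2 by ≈ −23% and L_sa by ≈ +100% even on clean
data; the quasi-static policy reduces the clean-data cost at the truth
from 6.6 to 0.008 mmHg²·s.  Because this state depends on Θ, its
gradient enters the Jacobian seed.  The naive policy remains available
("pressure-only"), as does "zero" for open-loop synthetic cycles.

**Chaining.**  Cycle 1 starts from the cold start (below or an explicit
guess); every later cycle is warm-started from the previous estimate.
No per-cycle multi-start is performed — temporal continuity plus the
global cold start carry the burden, which is exactly what makes the
method on-line.  On clean constant-parameter data the chain is a fixed
point (drift < 0.1%/cycle); under baseline noise the per-cycle
estimates scatter and their means over ≥ 30 cycles recover the truth
(see `scripts/acceptance.py`).

## 5. Genetic cold start

The first cycle has no warm start, and the box contains deceptive local
minima (notably a family near the L_sa upper bound).  A binary-coded GA
searches globally: each parameter is linearly quantised to 2^16 levels
over its box interval and the five codes concatenated in Θ order
(all-zeros ↔ lb, all-ones ↔ ub); population 100, tournament selection
(size 2), single-point crossover p = 0.8, per-bit mutation p = 0.01,
one elite, at most 100 generations, stall when the relative best-cost
improvement over 20 generations falls below 1e−6.  Individuals whose
cost evaluation diverges receive worst fitness.

A single run of this textbook GA prematurely converges into the
deceptive basin on a noticeable fraction of noise realisations, and the
raw sample cost there can undercut a coarse sample of the true basin.
`ga_initialize` therefore runs three independently seeded populations,
refines each champion with the bounded local solver of section 4, and
returns the lowest *refined* cost — a memetic best-of-restarts.  The GA
runs once at start-up only; everything is reproducible from one seed.

## 6. Parameter sensitivity

The MISO transfer function is G(s) = C(sI−A)⁻¹B (1×3).  The sensitivity
to parameter Θ_i at an expansion point Θ₀ is the analytic derivative

    S_i(s) = C(sI−A)⁻¹(∂A/∂Θ_i)(sI−A)⁻¹B + C(sI−A)⁻¹(∂B/∂Θ_i),

with the ∂A/∂Θ_i, ∂B/∂Θ_i matrices hard-coded from symbolic
differentiation of the model entries (no runtime symbolic dependency);
∂C = 0.  A central-finite-difference evaluator built only on the
transfer function serves as an independent oracle; agreement is 1e−4
relative (curve-peak normalised) at the reference point
Θ₀ = (0.1, 1.0, 0.9, 0.25, 0.0003) with step 1e−6.  Near box corners
(L_sa ~ 1e−5) the FD oracle itself loses digits to cancellation, so the
100-random-draw cross-check uses step 1e−5 and a 5e−4 band — a limit of
the oracle, not the analytic formula (FD's second-order convergence is
verified separately).

Structure worth knowing: because B's flow and venous columns are
proportional by R_sa, the sensitivities from those two input channels
coincide (at Θ₀, where R_sa = 1) for every parameter except R_sa
itself.  Above the physiological band the sensitivity magnitudes of the
four resistive/capacitive parameters roll off while the inertance
sensitivity keeps rising — asserted over the 3→30 Hz decade; in this
model |S_Lsa| peaks near 40 Hz and rolls off beyond, so the claim is a
band statement, not an asymptotic one.  The default Bode grid is 200
log-spaced points over 0.01–100 Hz.

## 7. Known limitations

* The identifier assumes the five-element structure exactly; on data
  from a richer arterial model the estimates would absorb structural
  mismatch.
* L_sa is weakly identifiable: under baseline noise its per-cycle
  estimates scatter over roughly (0.3±3)e−4 — the same order as the
  value itself — while the other four parameters recover to a few
  percent.  Occasional single-cycle excursions to ≈ 7e−4 occur on some
  noise realisations.
* The relative scatter ordering between R_sa and C_sa,1 is
  generator-dependent; here they are within ~10% of each other (C_sa,1
  usually slightly tighter), both an order of magnitude tighter than
  C_sa,2/L_sa.
* Fixed-period segmentation presumes a constant heart rate; the trigger
  mode handles rate variation but has no protection against ectopy or
  artefact.
* Problem sizes in the shipped tests and acceptance script (60 s noise
  runs, 200 s ramp runs, 12 s calibration runs) were chosen as the
  package's own desk-scale defaults; statistics tighten with longer
  runs.
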