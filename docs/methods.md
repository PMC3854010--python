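# Methods

## The model

`spikeinit` studies spike initiation in a deliberately minimal neuron: a
spherical soma (diameter 50 µm) attached to a thin unbranched cylindrical axon
(diameter 1 µm, length 300 µm — long enough that the sealed distal end does
not influence the proximal dynamics, since the passive space constant is
λ = √(d·R_m/4R_i) ≈ 707 µm). The membrane carries only a leak current and
non-inactivating sodium channels:

    C_m dV/dt = g_L (E_L − V) + g_Na m (E_Na − V) + axial currents
    dm/dt     = (m_inf(V) − m) / τ_m
    m_inf(V)  = 1 / (1 + exp((V_1/2 − V)/k_a))

with first-order (m¹) activation, which matches voltage-clamp measurements of
central-neuron Na channels better than the cubed gate of the squid model and
keeps the Boltzmann parameters directly interpretable. Na inactivation and K
currents are deliberately excluded: they shape repolarization and threshold
adaptation, not the initiation instability under study. Consequently the model
does not repolarize on its own; experiments either run under somatic voltage
clamp, stop at the upstroke, or use an explicit reset rule.

Default parameters (all exposed on `PassiveParams` / `NaChannelSet`):

| parameter | value | meaning |
|---|---|---|
| R_m | 30 000 Ω·cm² | specific membrane resistance |
| C_m | 0.75 µF/cm² | specific membrane capacitance (τ = R_m·C_m = 22.5 ms) |
| R_i | 150 Ω·cm | axial resistivity |
| E_L | −75 mV | leak reversal |
| V_1/2, k_a | −40 mV, 6 mV | Nav1.6-like Boltzmann activation |
| E_Na | 60 mV | Na reversal |
| τ_m | 0.1 ms | activation time constant |
| g_Na | 2 × somatic leak ≈ 5.24 nS | total conductance of available channels |

The optional second population ("Nav1.2", for the spike-shape study) is
shifted +15 mV in V_1/2 and 20× larger in conductance, placed proximally.

## Units

Everything uses one internally consistent unit system — mV, ms, µm, pA, nS,
pF, MΩ — in which `nS·mV = pA`, `pF·mV/ms = pA` and `GΩ·nS = 1`. This is the
convention of compartmental neural simulators; it removes any conversion layer
between the interface and the solver, at the cost of one factor of 10³
(MΩ → GΩ) that appears exactly once, in the reduced model's coupling product.

## Cable solver

The axon is discretized into nodes at multiples of dx (default 1 µm), the
soma being a single lumped node at x = 0. Coupling conductances come from the
exact closed-form segment resistances — `4R_i dx/(πd²)` on the cylinder, the
analytic `∫ds/d(s)²` on the linearly tapered hillock — so the discrete
soma→x resistance equals the continuum value at every node at any dx.
This matters: the phenomenon under study is controlled by the product
R_a·g_Na, and making R_a exact removes the leading discretization error.

Time stepping is backward Euler (dt default 0.025 ms) on the tridiagonal
system, solved by the Thomas algorithm, with gating advanced first by one
exact exponential step using the pre-step voltage; the freshly updated m
enters the voltage solve implicitly (on the diagonal). The staggered
semi-implicit scheme is unconditionally stable, which is required with
τ_m = 0.1 ms and 20-fold conductance contrasts between neighbouring nodes.
A refinement test (dt and dx halved) moves steady axonal voltages by well
under 0.1 mV.

Voltage clamp is a Dirichlet row substitution, so the somatic row of the
solution equals the command bit-exactly. The clamp current is reported as the
current the electrode must supply; the I–V curve negates it (inward-positive
membrane current), which is the convention in which the curve has a *minimum*
at V_T. Steady state is declared when max |dV/dt| < 10⁻⁴ mV/ms across free
nodes, sustained for 1 ms, with a 200 ms cap per level; hitting the cap is
reported (`converged=False`), never silent — near the fold the relaxation
critically slows and the flag is the honest answer.

Channel placement: a point cluster is split linearly between the two
bracketing nodes (so off-grid locations keep the right axial resistance);
interval profiles integrate the density over each node's dx cell and are
renormalized so the totals are conserved exactly.

Numerical blow-up (|V| > 200 mV, possible only under current clamp in this
K-less model when driven absurdly hard) aborts with a diagnostic rather than
returning garbage.

## Reduced model

The analysis model replaces the neuron by two points: the initiation site
(all Na conductance) coupled through the axial resistance R_a to the soma,
which is treated as a voltage source because its membrane area — hence its
current sink capacity — dwarfs the axon's. Balancing lateral and Na currents
gives the scalar fixed-point equation `(V_a − V_s)/R_a = f(V_a)` with
`f(V) = g_Na·m_inf(V)·(E_Na − V)`.

Roots are located by sign changes on a 0.01 mV grid and polished with Brent's
method (≤3 roots of a smooth scalar function: robustness over speed); a root
is stable iff f′(V_a) < 1/R_a. The fold — where the resting root annihilates
with the unstable root, i.e. the spike threshold — solves the tangency
condition 1/R_a = f′(V_a) directly, again bracketed and polished; the second
tangency (the de-activation fold met on downward sweeps) is reported
separately for hysteresis studies. The critical coupling product is computed
as `1/max_V d/dV[m_inf(V)(E_Na−V)]` by numerical maximization rather than
taken from any printed approximation; the printed ≈0.27 (and the critical
distance ≈27 µm, and the mixed form R_i·g_Na·x/d² ≈ 0.21) are *tests* of this
computation, not constants in the code. The distal passive axon's load is
ignored in the reduced model (its input conductance, ≈0.3 nS, is small
against the relevant slopes); the resulting discrepancies against the cable
simulation are measured and reported, not hidden — the simulated
half-activation threshold sits 0.5–0.9 mV above the reduced fold over
x = 30–100 µm.

Where the reference analysis printed closed-form *approximations* (ΔV ≈ 33 mV
and the kink rate ΔV/(C·R_a) ≈ 7.5 mV/ms at 40 µm), the exact numerical fold
gives slightly different values (31.4 mV, 7.0 mV/ms); the package reports the
exact computation.

## Measurements

**Sharpness.** Defined as half the somatic-voltage interval over which the
conductance-weighted open fraction rises from 27% to 73% (these landmarks are
V_1/2 ± k_a for an isopotential membrane, so the isopotential half-width *is*
k_a). Each evaluation relaxes the neuron from rest to steady state under
somatic clamp — starting from rest selects exactly the branch a quasi-static
upward sweep follows — and the three crossings (27/50/73%) are located by
adaptive bisection to 0.01 mV. Uniform grids cannot reach the sub-0.1 mV
regime at sane cost. Above the critical distance the steady-state activation
curve is genuinely discontinuous (the lower branch tops out at m ≈ 0.20,
below the 27% landmark, before folding), so both landmarks collapse onto the
fold: the measured half-width is then an upper bound set by the bisection
resolution, and is flagged as such (`discontinuous=True`). Any small nonzero
width quoted for such configurations is a property of a finite-resolution
sweep protocol, not of the steady-state curve.

**Kink.** The pulse experiments drive the soma with a rectangular current at
1.1× the minimal amplitude that opens half the channels (found by geometric
bisection to 1%; just-suprathreshold is the conventional choice and makes the
pre-spike baseline derivative small). The somatic phase plot (centered
differences at dt, no smoothing — the kink *is* the signal) shows a
near-vertical segment when the axonal channels open; the measurement reports
the baseline below it, the jump across it, and the level at its top (the
first prominent local maximum of dV/dt, so that a later somatic Na spike
riding on the kink does not contaminate the measure — the search window also
ends when any soma-placed channel set starts opening). Onset rapidness is the
slope of dV/dt vs V at the first upward crossing of α = 10 mV/ms,
least-squares over the ±1 mV/ms band (secant fallback when the rise crosses
the band within one sample).

**Energy.** The fluctuating input is a stationary Ornstein–Uhlenbeck current,
τ_I = 5 ms, mean I_0 = 18.3 pA, stationary SD σ_I = 31.4 pA, generated by the
exact discrete update `I ← I_0 + (I−I_0)e^(−dt/τ) + σ_I√(1−e^(−2dt/τ)) ξ`
(moments correct at any dt; bit-reproducible for a given seed, and one seed
is shared across all conductance conditions so subthreshold activity is
identical). The SDE convention — σ_I as the stationary SD — is a declared
assumption. Since the model cannot repolarize, a spike is registered when
half of the channels are open, whereupon the whole neuron is reset to E_L and
clamped there for 5 ms. Firing rates discard the first 500 ms; the mean Na
current averages over the run excluding the artificial 5 ms clamp windows.
The default conductance grid is 6 log-spaced values spanning 1–8× the somatic
leak for both sites (soma and 40 µm), 60 s per row.

## What the experiments do and do not show

All inputs are synthetic by construction (the study has no external data):
step ladders, pulses and the seeded OU current emulate standard
electrophysiology protocols. What passing tests establish is internal
consistency of the theory chain — exact cable behaviour against the sealed-end
closed form, fixed points against a brute-force scan, simulated thresholds
against the analytic fold — not agreement with any recorded neuron. Known
quantitative limits, measured rather than assumed:

- the simulated-vs-reduced threshold gap is 0.5–0.9 mV, tighter than the ≈2 mV
  quoted for closed-form approximate thresholds;
- V_a* − V_s* approaches k_a only asymptotically in distance (9.2 mV at
  30 µm, 6.7 mV at 100 µm, vs k_a = 6);
- the effective-location rule (0.6·x1 + 0.4·x2) reproduces distributed-profile
  thresholds within 1 mV for all tested (x1, x2) pairs, but sharpness
  half-widths only within a factor ≈2.5 away from the critical distance — near
  it the width plunges to zero over ~2 µm and no single-point summary is
  stable;
- the energy experiment's axonal/somatic rate-slope ratio is ≈1.55 and the
  matched-rate normalized-current ratio ≈1.5–1.7 under the default grid
  (the somatic rate–conductance curve saturates at the top of the grid, where
  the incremental slope ratio approaches ≈1.9).

## Problem sizes

The default experiments use 301 compartments (dx = 1 µm over 300 µm),
dt = 0.025 ms, sharpness sweeps of ~40–50 steady-state relaxations per
configuration, and 60 s of simulated time per energy-study row; these sizes
were chosen so that each figure-stage runs in seconds to a few minutes on one
CPU while refinement checks confirm the discretization errors are far below
every tolerance asserted in the tests.
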