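# Methods

## Scope and assumptions

`socesim` models store-operated calcium entry (SOCE) in a non-excitable cancer
cell (A549) with three well-mixed calcium pools: cytosol, ER, and the ER-PM
junction.  The junction — the nanoscale gap where STIM1 clusters activate
ORAI1 — is treated as a single representative cylinder (d = 100 nm,
h = 10 nm, V_Ju = 7.854e-20 L) replicated n_Ju = 150 times; its lateral ring
surface (A_diff = π·d·h ≈ 3.14e-3 µm²) is a linear diffusion layer of length
d_diff = 0.35 µm to the bulk cytosol.  A junction sits inside a microdomain
surrounded by other junctions rather than directly by cytosol, which is why
d_diff is an adjustable effective length rather than a measured geometric one,
and why it is the natural knob for setting junctional Ca²⁺ independently of
the cytosol.

The CRAC current is the only Ca²⁺ influx into the cell (TRP channels,
Na⁺/Ca²⁺ exchange, mitochondria and lysosomes are out of scope).  All gating
is deterministic (occupancy fractions, no single-channel stochasticity).  The
membrane potential is fixed at +5 mV for SOCE-only runs; a pluggable hook
co-integrates `C·dV_m/dt = −I_whole_cell` when a whole-cell current model is
supplied (positive/outward current hyperpolarizes).

## Units and conservation

Concentrations are µM, time s, volumes L, currents A, potentials mV (converted
to V inside the Nernst and current formulas).  Pump/release fluxes are stated
in µM/s of their source compartment; the ER continuity equation scales the
cytosol-side fluxes by V_Cyt/V_ER and the junctional SERCA term by
n_Ju·V_Ju/V_ER, so that the *amount* of calcium leaving one compartment equals
the amount entering the other.  With PMCA and CRAC disabled the total cell
calcium

    V_Cyt·([Ca]_Cyt + [Ca]_B,Cyt) + V_ER·([Ca]_ER + [CSQ]_bound) + n_Ju·V_Ju·[Ca]_Ju

is conserved; the test suite verifies this to 0.1% over 600 s.  The
junction-cytosol diffusion term is carried as an amount flux (µM·L/s) so the
same quantity feeds both sides with the correct volume scalings.

## Flux laws

* **CRAC**: i = n_CRAC·g_CRAC·ρ·(V_m − E_Ca), with E_Ca the junction-based
  Nernst potential recomputed every evaluation, inward rectification
  (driving force clamped at 0 if outward), and conversion to junctional µM/s
  by 1/(F·z·V_Ju).  With defaults and a depleted store the per-channel current
  is ~1 fA and the whole-cell CRAC and PMCA currents during the SOCE plateau
  are both ~0.9 pA.
* **SERCA**: R·c/(c + K)·1/(1 + I·E), identical law for the cytosolic and
  junctional pump populations.  The cytosolic activation is Michaelis
  (Hill 1) by default.  This was a genuinely open design point (the source
  material prints only R, K and I): Hill 1 is the most literal reading of a
  rate "controlled by a single dissociation constant", and it is the choice
  that reproduces the reported Ca-free baseline (~13 nM) and the resting
  state (69 nM cytosol / ~600 µM ER); a Hill-2 pump under-pumps at
  sub-100 nM calcium and more than doubles the baseline.  The exponent is a
  config parameter (`serca.hill`) so the alternative can be tested.
* **PMCA**: R·c²/(c² + K²) (Hill 2, `pmca.hill` configurable).  Hill 2 here is
  required by the half-maximal rate of 19 µM/s at 0.9 µM and is what balances
  the reported resting junctional calcium of ~0.9 µM.
* **Leak**: R_leak·(E − c) with R_leak = 0.002 /s.
* **IP3R/RyR release**: R·P_open·(E − c)/E_ref with E_ref = 250 µM (the
  initial ER level), making the printed rates (0.18 and 200 µM/s) maximal
  fluxes in µM/s at the full reference gradient.  The alternative — rate
  times the absolute gradient — would give the rate constants units of
  µM²/s, contradicting their printed units.

## Receptor state models

**IP3R** is a six-state scheme (R, O, A, I1, I2, S) with saturable transition
functions φᵢ(c); the transition graph is a tree (R–O, O–A, O–S, R–I1, A–I2),
so its stationary distribution obeys detailed balance edge by edge.  The rate
constants k±1..k±4, L1/L3/L5 and j±2/j±4/j±6 are taken verbatim from the
parameter table; open probability is (0.1·O + 0.9·A)⁴ for the tetramer.  With
R_IP3R = 0.18 µM/s the IP3R contributes little flux in the single-cell
parameterization; the `combined_model` config raises it to 1.8 µM/s.

**RyR** is a four-state two-gate cycle (X00 rest, X10/X11 conducting, X01
inactivated-closed).  The exact transition diagram of the source model was
not available, so the package adopts a documented reconstruction constrained
by the printed rate names, values and units:

    X00 -> X10  k6·c·w          X10 -> X00  k-6 (= k-4)
    X10 -> X11  k2·c²           X11 -> X10  k-2
    X01 -> X11  k7·c·w (k7=k4)  X11 -> X01  k-4
    X00 -> X01  k11·c²          X01 -> X00  k_rec = k-2·k4·k11/(k2·k6)

where w = [CSQ]_free/[CSQ]_total is the luminal regulation factor: gating
reads the dynamic calsequestrin state, so a replete ER (little free CSQ)
suppresses opening and a depleting ER disinhibits it.  The recovery rate
k_rec ≈ 9.4 /s is fixed by detailed balance around the cycle, making the
scheme thermodynamically consistent at any (c, w).  The reconstruction was
selected, before any trajectory was simulated, by requiring the scheme to be
consistent with the reported stationary operating points (the resting release
balance at a ~600 µM ER and the 139 µM ER plateau after a tenfold rate
increase); the opposite luminal sign (direct Ca_ER activation) is
quantitatively incompatible with the latter.  Consequences: the stationary
open fraction is monotone in cytosolic Ca²⁺, the resting open fraction is
~2e-3, and during store depletion the release current is bell-shaped (rising
with c and w, collapsing with the gradient).  The printed constants Kd1,
Kd3 and Kd8 are validated and retained in the registry but are not placed by
this reconstruction (Kd8 = 638.3 µM duplicates the CSQ dissociation constant
that enters through w; the kinetic pair k_off/k_on = 650 µM is used).  The
coupling is switchable (`ryr.csq_coupling`); with it off CSQ is a pure ER
buffer.

**CRAC formation** (STIM1/ORAI1) uses the two uncoupled mass-action equations
given in the flux section of the README; STIM1 acts catalytically in complex
formation.  The closed-form equilibrium chain

    ρ_ss(E) = f_o·S_ss/(f_o·S_ss + b_o),  S_ss(E) = b_s/(f_s·E³ + b_s)

is exposed (`crac_equilibrium_chain`) and serves as an integration-free
cross-check: ≈0.95 at E = 0, ≈0.032 at E = 594 µM, ≈0.69 at E = 139 µM.

## Buffers and IP3

Both buffers are single-site mass action.  Cytosolic: 660 µM sites,
k_on = 100 /(µM·s), k_off = 500 /s (K_d = 5 µM).  Calsequestrin: 14 µM total,
k_on = 100 /(µM·s), k_off = 65000 /s (K_d = 650 µM); a fully depleted ER
leaves all 14 µM calcium-free.  IP3 follows Ca-stimulated production
(Hill 2 in c, half-max 1.1 µM) with first-order relaxation toward the 0.25 µM
resting level — relaxation to rest rather than to zero, because the parameter
set prints a resting IP3 and the initial condition starts there.

## Parameters and initial conditions

The shipped `table2_default` config carries every rate constant, conductance,
geometry value and buffer total with units; `combined_model` overrides
n_Ju = 300 and R_IP3R = 1.8 µM/s (the whole-cell embedding).  Temperature
defaults to 273 K exactly as printed in the source parameter table (not
310 K); it is overridable.  The junction height is 10 nm (the table value,
which reproduces the printed V_Ju; accompanying prose mentions 20 nm).  The
initial condition is 64 nM cytosol/junction, 250 µM ER, 16 µM buffered
cytosolic Ca²⁺, 7 µM free CSQ, 0.25 µM IP3, no activated STIM1 or formed
CRAC, IP3R fully at rest, RyR at {X00: 0.998, X01: 0.002} (the source table
lists the fourth state under a duplicated label; the 0.002 is assigned to
X01, documented as an erratum assumption).

Initializing the cytosolic buffer at 16 µM, above its 8.3 µM equilibrium at
64 nM free Ca²⁺, produces a steep artificial calcium spike in the first
milliseconds of every run as the buffer re-equilibrates.  It is a documented
transient with no effect on later dynamics; summary metrics apply a 10 s
burn-in.  Instantaneous bath changes likewise produce sharp numerical spikes;
plateau metrics skip a 1 s post-event blanking window.  Metric conventions:
baseline = mean over the 10 s before the first event; peak = maximum after
blanking; plateau = mean over the final 30 s before the next event (final
value for runs that end in steady state).

## Numerics

The default integrator is adaptive stiff (LSODA) with rel_tol = 1e-8 and
abs_tol = 1e-12 µM; the stiffest modes are the calsequestrin kinetics
(k_on·E + k_off ≈ 9e4 /s) and the junction diffusion relaxation
(≈2.5e4 /s).  A fixed-step forward Euler mode is retained for validation; its
stability limit is ≈2e-5 s, and the solver cross-checks in the test suite run
it at 1e-6–5e-6 s on horizons of 0.01–0.5 s (a full 600 s protocol at a
stable explicit step would take ~1e8 steps and adds nothing for these
dynamics — the adaptive and Euler solutions agree within 1% where compared,
with the expected first-order convergence).  Protocols integrate piecewise
between events; each event mutates its dotted parameter path exactly at its
timestamp, so discontinuities are sharp and recorded fluxes switch exactly at
event times.  Concentrations are floored at 1e-12 µM inside logarithms only;
recorded states more negative than −1e-6 µM abort the run with the variable
name and time.  The engine contains no randomness: identical settings produce
bit-identical traces.

Steady-state detection integrates in 5 s chunks until the maximum relative
state change per second (on a 1e-6 µM floor) falls below tolerance;
non-convergence is reported by flag, not exception.  At the default
parameters the resting state reached after ~130 s still drifts at ~1e-4/s in
the slowest variable; the steady-state experiment reports the 130 s endpoint
(matching the protocol of the RyR experiment), while `find_steady_state` with
tolerance 1e-7 converges to the true fixed point, which a Newton root of the
assembled right-hand side confirms to better than 1%.

## What the canned experiments emulate — and what they do not

The TG protocol emulates a calcium-imaging experiment (Ca-free bath, 2 µM
thapsigargin at 66 s modeled as SERCA rate -> 0, 2 mM Ca²⁺ perfusion at 231 s,
100 µM 2-APB at 429 s modeled as n_CRAC -> 0.001 per junction — not zero).
The RyR activation run emulates drug-triggered ER calcium release as a
tenfold R_RyR increase at 130 s from the 1.8 mM resting state.  Fluorescence
itself is not modeled: the underlying measurements are relative fluorescence
without a calibrated concentration mapping, so agreement is assessed on
levels and shapes of the simulated concentrations, and none of the default
parameters were obtained by fitting quality-assured quantitative data.
Passing tests therefore demonstrate internal consistency and reproduction of
the reference simulation, not validated predictions of absolute cellular
calcium concentrations.

## Known limitations

* The RyR transition topology is a reconstruction (see above); alternative
  wirings of the rarely occupied X11/X01 states are compatible with the same
  printed constants.
* Single generic cytosolic buffer and CSQ-only ER buffering; no calreticulin,
  no mitochondrial or lysosomal stores, no Na⁺/Ca²⁺ exchanger, no TRP influx.
* The IP3 description is a two-term caricature (no receptor-driven PLC
  signaling), adequate only for basal IP3R activation.
* All junctions are identical and well-mixed; there is no spatial profile
  within a junction or across the microdomain.
* The ER volume (5% of the cell) and junction count are literature-guided
  assumptions, not A549 measurements.
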