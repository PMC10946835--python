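# Methods

`stomasim` is a mechanistic simulator of stomatal gas exchange.  Instead of
prescribing a stomatal conductance model, it integrates the molecular
kinetics of a single (averaged) guard cell — ion channels, pumps and coupled
carriers on the plasma membrane and tonoplast, sucrose/malate metabolism,
Ca²⁺/pH/ABA signalling — under strict charge and mass conservation, and lets
aperture, g_s, E, A, pC_i and WUE emerge from the resulting osmotic and
mechanical state of the cell coupled to leaf-scale diffusion.

## The computational cycle

Each time step runs one loop:

1. **Environment** — the diurnal protocol supplies blue/red light, pCO₂,
   RH, the relative water feed (RWF) and apoplastic ABA at the current time.
2. **Regulation** — cytosolic free Ca²⁺, pH, cytosolic ABA, pC_i and blue
   light are mapped to bounded multipliers on their target transporter
   classes (Hill forms in the signal's excess over its resting level, so
   every factor is exactly 1 at rest).
3. **Transport** — every transporter population is evaluated at the current
   voltages and concentrations (forms below).
4. **Voltages** — `C dV/dt = −I` per membrane.  The plasma membrane uses an
   exponential-relaxation step: the current is linearized at the working
   point, the applied fluxes are evaluated at the step's path-average
   voltage, and `ΔV = −I_applied·Δt/C` exactly.  This is stable far beyond
   the membrane RC time and makes the charge ledger exact by construction.
   The tonoplast is quasi-steady by default (its RC time is far below the
   stepping time; the zero-current root is found each step by damped Newton
   with a Brent fallback); a capacitive mode is available and is used by the
   conservation tests.
5. **Contents** — cytosol and vacuole amounts advance by the applied fluxes
   plus metabolic source terms; the bulk apoplast is a reservoir.  Proton
   fluxes go to per-compartment pH ledgers (below), not to a free pool.
6. **Water and mechanics** — van't Hoff osmotic potential, linear-elastic
   turgor, transmembrane water flux against the wall water potential, and a
   viscoelastic first-order relaxation of aperture toward its
   turgor-balance target against epidermal back-pressure.
7. **Gas exchange** — end-corrected elliptical-pore diffusion gives g_s;
   the Kelvin relation gives the substomatal vapour pressure from the wall
   water potential; E follows from the vapour gradient; pC_i solves the
   diffusion/fixation balance `g_CO₂(pCO₂ − pC_i) = A(pC_i)` in closed form
   (the A–C_i response is a rectangular hyperbola with compensation point;
   a Farquhar-type callable can be substituted).
8. **CRR exchange** — the apoplastic subdomain shared with the adjacent
   epidermal cell relaxes toward the bulk reservoir while guard-cell
   transport draws on it, and epidermal turgor relaxes toward a target
   raised by the solute the guard cell releases (the antagonistic
   back-pressure).

An adaptive controller keeps |ΔV_pm| ≤ 1 mV, the fractional change of any
compartment pool and of the cell volume ≤ 0.5 %, and |ΔpH| ≤ 0.01 per step
within Δt ∈ [1 ms, 2 s], halving on a breach and doubling after ten clean
steps.  Steps land exactly on the logging grid, so runs are bitwise
reproducible and a pause/resume splice is the identity.  There is no
randomness anywhere in the engine.

## Transporter kinetics

* **Channels** — Goldman–Hodgkin–Katz constant-field unitary flux (series
  expansion for |zFV/RT| < 10⁻⁴), times Boltzmann steady-state gating
  `1/(1+exp(−g(V−V½)/(RT/F)))` (plus an optional residual open fraction
  `p_min` for constitutively active sub-populations), times the bounded
  regulation product, times population.  Channel flux vanishes exactly at
  the Nernst potential.
* **Pumps** — a single-loop reversible cycle.  The total cycle free energy
  ΔG sums the energized substrate term (ATP −45 kJ mol⁻¹; PPi −25 kJ mol⁻¹)
  and the stoichiometric electrochemical potentials; the rate is a bounded,
  odd, saturating function of u = −ΔG/RT with symmetry factor δ = 0.5 and
  an effective n = 4 serial transitions sharing the driving force.  The
  n = 4 spread keeps a physiological current–voltage slope over the working
  range (a fully concentrated voltage step saturates unrealistically early
  and leaves the pump with no stabilizing conductance).  Pumps stall
  exactly at ΔG = 0 and always run downhill.
* **Carriers** — flux = population × V_max × Michaelis saturation ×
  tanh(−ΔG/2RT), with exact stoichiometric coupling.  Saturation acts on
  the side each substrate moves from (`k_m`) with optional trans-side
  product inhibition (`k_i`).

Sign conventions: V = ψ(cytosol) − ψ(apoplast) at the plasma membrane and
ψ(cytosol) − ψ(vacuole) at the tonoplast; fluxes positive into the cytosol;
currents outward-positive, I = −96.485·Σz·Φ pA.

## Protons, Ca²⁺ buffering and the malate pH-stat

Protons carry charge in every flux and thermodynamic term but have no free
compartment pool: cytosolic and vacuolar pH are ledgers, moved by the net
H⁺ flux divided by a buffer capacity β (100 and 30 mM per pH unit).  Free
cytosolic Ca²⁺ is a rapid-buffer fraction of the total pool
(free = total/(1+κ), κ = 999; vacuole κ = 49).  Malate carries valence −2
with fixed speciation: each Mal²⁻ synthesized releases two
proton-equivalents to the ledger and each one consumed removes two.  Malate
synthesis is light-driven and favoured in an alkaline cytosol, breakdown in
an acidic one (the Davies pH-stat, slopes 0.5 and 1 per pH unit): this
couples the diurnal carbon store to the proton budget of the H⁺-ATPase and
stabilizes cytosolic pH at the light/dark transitions.

## Signal relays

The hard-wired relays follow the stated target map: cytosolic ABA activates
the plasma-membrane Ca²⁺ channel and inhibits the plasma-membrane and
endomembrane Ca²⁺-ATPases and the plasma-membrane H⁺-ATPase; elevated
[Ca²⁺]_i inactivates the inward K⁺ channel, suppresses the H⁺-ATPase and
the tonoplast H⁺-PPase, and activates the plasma-membrane anion channels
and the vacuolar K⁺/anion release channels; pC_i above its 400 µbar
reference acts on the same target set as ABA with its own half-saturations.
ROS/NO and kinase/phosphatase intermediates are deliberately subsumed in
these bounded Hill forms.  ABA enters the cytosol through a saturable
plasma-membrane carrier (with a small tonoplast pathway), so cytosolic ABA
lags an apoplastic pulse by minutes.

## The reference fixture

`build_reference_model` emits a deterministic Arabidopsis-like parameter
set: 16 transporter populations (plasma membrane: H⁺-ATPase, Ca²⁺-ATPase
as a Ca²⁺/2H⁺ countertransporter, hyperpolarization-activated Ca²⁺
channel, inward and outward K⁺ channels, Cl⁻ and Mal²⁻ anion channels,
2H⁺/Cl⁻ and H⁺/Suc symporters; tonoplast: 3H⁺/ATP V-ATPase, H⁺-PPase,
Ca²⁺-ATPase, Ca²⁺/H⁺ antiporter, K⁺, Cl⁻ and Mal²⁻ channels), plus in the
`with_aba` variant ABA uptake on both membranes and the ABA relay wiring.
All populations and unitary rates are order-of-magnitude literature-typical
calibration choices of this package (resting net fluxes of 0.01–0.3
fmol s⁻¹ per guard cell, pump currents of a few pA); they are documented in
the source and are not claimed to reproduce any published parameter table.

Calibration decisions worth knowing about:

* **Apoplastic composition** is dilute (0.5 mM K⁺, 2 mM Cl⁻) so the dark
  resting potential, pinned near E_K, is hyperpolarized (≈ −170 mV).
* **Ca²⁺ pumps are Ca²⁺/2H⁺ countertransporters** (electroneutral): a
  charge-translocating 1 Ca²⁺/ATP pump stalls thermodynamically at
  physiological gradients near −150 mV and cannot hold resting free Ca²⁺.
* **The tonoplast Ca²⁺/H⁺ antiporter is 1:1**, so it equilibrates and can
  reverse: vacuolar Ca²⁺ has a genuine steady state instead of filling
  forever (the steep 3:1 form never reverses at tonoplast gradients).
* **Initial compositions sit on the model's own diurnal limit cycle**: they
  are the dawn state of a month-long spin-up under the stock 12 h/12 h
  protocol, so a fresh run is on its attractor within a day.  An impermeant
  fixed-charge anion (`Aorg`, osmotically silent macromolecular charge)
  balances each compartment exactly; the conjugate charge of the explicit
  ions otherwise lives on the pH-buffer ledger.
* The guard-cell voltage shows abrupt, deterministic transitions between a
  hyperpolarized (pump-dominated) and a depolarized (anion/K⁺-efflux)
  state in some regimes; [Ca²⁺]_i transients ride on these.  This
  excitability is an emergent property of the channel complement, not a
  numerical artifact; the fixture is calibrated so the stock protocols stay
  clear of sustained flicker.

## What the fixture does and does not emulate

The fixture reproduces the qualitative systems behaviour: hyperpolarized
dark rest, light-driven opening (blue-light pump activation, K⁺/Cl⁻ uptake,
malate accumulation), a reproducible diurnal aperture/g_s rhythm,
ABA-evoked closure with a [Ca²⁺]_i rise, vacuolar K⁺/Cl⁻ release, relative
vacuolar malate retention, and sensitivity to water restriction through the
RWF.  It does not claim quantitative parameter fidelity to any real
genotype; absolute magnitudes (aperture in µm, g_s in mol m⁻² s⁻¹) are
order-of-magnitude plausible, not fitted.  Temperature is fixed at
298.15 K; boundary-layer conductance is infinite; there is no energy
balance, no mesophyll conductance, and a single endomembrane compartment.

## Numerical choices

* Units close exactly: time s, voltage mV, concentration mM, amount fmol,
  volume pL, flux fmol s⁻¹, current pA, pressure MPa, partial pressures
  mbar (ppm ≡ µbar at 1013 mbar), RT/F = 25.693 mV.
* Electroneutrality tolerance for initial compositions: 1 mM net charge.
* Voltage guard rails [−300, +100] mV; cytosolic pH guard rails [5, 9]
  (vacuolar [3.8, 9]); negative-amount clips above 10⁻³ fmol fault.
* Quasi-steady tonoplast root: |I| < 10⁻⁹ pA; `steady_voltage` refines a
  2 mV scan bracket by Brent's method to 0.01 mV.
* The substomatal CO₂ balance is solved by the closed-form quadratic of the
  hyperbolic A–C_i form, verified against (and backed by) a bracketed
  root-find; diffusion conductance is floored at 10⁻⁶ mol m⁻² s⁻¹ so a
  fully sealed leaf still has a defined (respiration-loaded) pC_i.
* Problem sizes in the shipped tests and acceptance runs: 1 h conservation
  audit, 8 h ABA scenario, 72 h diurnal (three cycles) plus a 24 h
  water-restricted run — all at the full adaptive resolution, logged at
  1–5 min intervals.

## Known limitations

* A single parameter set represents the "ideal" averaged stoma; no
  population heterogeneity.
* The CRR formulation (subdomain relaxation, viscoelastic aperture lag,
  epidermal turgor response) is a deliberate two-relaxation simplification.
* The pump/carrier cycle is a one-loop stand-in that preserves the
  thermodynamic contract (stall at ΔG = 0, bounded rate) but not the full
  multi-state kinetics of detailed cycle models.
* Guard-cell photosynthesis contributes osmotica only (Suc/Mal synthesis);
  it is not coupled to the leaf carbon balance.
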