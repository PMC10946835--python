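# stomasim

A mechanistic simulator of stomatal gas exchange.  Stomata — the pores in
the leaf epidermis formed by pairs of guard cells — control the trade
between CO₂ uptake for photosynthesis and water loss by transpiration.
Phenomenological conductance models treat the pore aperture as an empirical
input; `stomasim` instead computes it.  Guard-cell membrane transport
(channels, pumps, coupled carriers on the plasma membrane and tonoplast),
sucrose/malate metabolism and Ca²⁺/pH/ABA signalling are integrated under
strict charge and mass conservation, and stomatal aperture, conductance
(g_s), transpiration (E), assimilation (A), intercellular CO₂ (pC_i) and
water-use efficiency evolve from that molecular state, second by second,
under user-defined diurnal environments.

It is written for quantitative plant physiologists and membrane biologists
who want to connect single-transporter kinetics to whole-leaf gas exchange:
knock out a channel population, rewire a signalling edge, restrict the
water supply, pulse abscisic acid — and watch the macroscopic consequences.

## The model in brief

Per time step Δt the engine runs one cycle (details in
[docs/methods.md](docs/methods.md)):

* transporter fluxes: channels by the Goldman–Hodgkin–Katz constant-field
  equation with Boltzmann gating, `Φ = N·P·(zFV/RT)·(c_in − c_out·e^{−zFV/RT})/(1 − e^{−zFV/RT})`-type
  unitary flux; pumps and carriers by a reversible cycle that stalls
  exactly where the coupled ΔG (including ATP or PPi) vanishes;
* membrane voltages by charge conservation, `C·dV/dt = −I` with
  `I = −F·Σ z·Φ`, on both the plasma membrane and tonoplast;
* compartment contents by mass conservation (the bulk apoplast is a
  reservoir; protons live on pH-buffer ledgers; free Ca²⁺ is a rapid-buffer
  fraction of the total pool);
* water, turgor and aperture: van't Hoff osmotic potential
  (π = RT·Σφᵢcᵢ), a linear-elastic wall (P = ε·(V−V₀)/V₀), and a
  viscoelastic aperture relaxation against epidermal back-pressure;
* leaf gas exchange: end-corrected pore diffusion gives g_s, vapour
  equilibration with the wall water potential (Kelvin relation) gives the
  substomatal vapour pressure, and pC_i solves
  `g_CO₂·(pCO₂ − pC_i) = A(pC_i)` against a hyperbolic A–C_i response.

A bundled, deterministic Arabidopsis-like reference model (16 transporter
populations; a `with_aba` variant hard-wires abscisic-acid action onto the
plasma-membrane Ca²⁺ channel, the Ca²⁺-ATPases and the H⁺-ATPase) supplies
a working starting point; every parameter is plain JSON (`.ogj` files) and
everything — populations, kinetics, wiring, environments — is editable.
Null mutants are a one-line change (`population = 0`).

## Worked example

```python
import stomasim as ss

model = ss.build_reference_model("base")
protocol = ss.default_protocol()          # 12 h light / 12 h dark, 400 ppm CO2
config = ss.SimulationConfig(duration_s=24 * 3600, mode="fast")
result = ss.run_simulation(model, protocol, config)
df = result.to_dataframe()

for hours in (6, 12, 18, 24):
    row = df.iloc[(df["time_s"] - hours * 3600).abs().idxmin()]
    print(f"t={hours:>2d} h  aperture={row.aperture_um:5.2f} um  "
          f"gs={row.gs_mol_m2_s:6.3f} mol m-2 s-1  "
          f"A={row.A_umol_m2_s:5.2f} umol m-2 s-1  "
          f"E={row.E_mmol_m2_s:5.2f} mmol m-2 s-1  "
          f"pCi={row.pci_ubar:5.1f} ubar  Vpm={row.v_pm_mV:6.1f} mV")
```

prints

```
t= 6 h  aperture= 1.92 um  gs= 0.280 mol m-2 s-1  A= 3.41 umol m-2 s-1  E= 2.62 mmol m-2 s-1  pCi=380.5 ubar  Vpm=-180.6 mV
t=12 h  aperture= 2.03 um  gs= 0.293 mol m-2 s-1  A= 3.42 umol m-2 s-1  E= 2.73 mmol m-2 s-1  pCi=381.3 ubar  Vpm=-179.4 mV
t=18 h  aperture= 1.56 um  gs= 0.239 mol m-2 s-1  A=-1.00 umol m-2 s-1  E= 2.23 mmol m-2 s-1  pCi=406.7 ubar  Vpm=-171.7 mV
t=24 h  aperture= 1.34 um  gs= 0.211 mol m-2 s-1  A=-1.00 umol m-2 s-1  E= 1.98 mmol m-2 s-1  pCi=407.6 ubar  Vpm=-173.2 mV
```

In the light the cell is hyperpolarized (≈ −180 mV), the stoma is open and
the leaf assimilates at 3.4 µmol m⁻² s⁻¹ with pC_i drawn ~20 µbar below
ambient.  After lights-off the guard cell sheds osmotica, the aperture and
g_s fall, net CO₂ exchange turns to dark respiration (A = −R_d = −1) and
pC_i rises above ambient.  Runs are fully deterministic; `mode="full"`
additionally logs every individual transporter flux.

Closure experiments use the same machinery: running
`ss.build_reference_model("with_aba")` under `ss.aba_pulse_protocol()`
(1 µM apoplastic ABA over hours 4–6 in the light) evokes a cytosolic Ca²⁺
rise, K⁺/Cl⁻ efflux from the vacuole (with malate retained), and a decline
of aperture, g_s, E, A and pC_i together with a rise of the substomatal
vapour pressure.

## Command line

```
stomasim fixture --variant base --out arab.ogj     # write the bundled model
stomasim validate arab.ogj                         # structural + physical checks
stomasim iv --model arab.ogj --membrane pm --out iv.csv
stomasim preview --model arab.ogj --hours 24 --out metabolism.csv
stomasim run --model arab.ogj --hours 24 --mode fast --out run.csv [--plot run.png]
```

Simulations can pause at a preset time (`--pause-at`), emit a resumable
checkpoint, and continue — with identical results to an uninterrupted run,
or with parameters edited at the pause.

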