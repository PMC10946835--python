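"""Physical constants and the global unit conventions.

Units used throughout the package:

* time            s
* voltage         mV
* concentration   mM
* amount          fmol   (1 pL x 1 mM = 1 fmol)
* volume          pL
* flux            fmol s^-1 per guard cell
* current         pA     (I = 96.485 * z * flux, flux in fmol s^-1)
* pressure        MPa
* partial pressure mbar; ppm == ubar at 1013 mbar total pressure
* temperature     K, fixed at 298.15 K

These conventions give closed units everywhere: a pA is exactly
96.485 * z fmol s^-1 of charge, a pL of a 1 mM solution holds 1 fmol.
"""

import math

#: absolute temperature the model runs at (kinetics are not temperature-scaled)
TEMPERATURE_K = 298.15

#: RT/F at 298.15 K, in mV
RT_F_MV = 25.693

#: RT at 298.15 K, in kJ mol^-1
RT_KJ = 2.4789

#: Faraday constant expressed as kJ mol^-1 per mV
F_KJ_PER_MV = 0.096485

#: current conversion: I [pA] = FARADAY_PA * z * flux [fmol s^-1]
FARADAY_PA = 96.485

#: voltage step [mV] produced by 1 pA flowing for 1 s onto 1 pF is 1000 mV
MV_PER_PA_S_PF = 1000.0

#: van't Hoff factor: osmotic pressure per unit concentration at 298.15 K,
#: MPa per mM (RT = 2.4789 kJ mol^-1 = 2.4789e-3 MPa L mmol^-1)
VANT_HOFF_MPA_PER_MM = 2.4789e-3

#: default free energy of ATP hydrolysis under cytosolic conditions, kJ mol^-1
DG_ATP_KJ = -45.0

#: default free energy of pyrophosphate hydrolysis, kJ mol^-1
DG_PPI_KJ = -25.0

#: partial molar volume of water, m^3 mol^-1
V_W_M3_PER_MOL = 18.05e-6

#: gas constant, J mol^-1 K^-1
R_J = 8.314

#: diffusivity of water vapour in air at 25 C, m^2 s^-1
D_H2O_M2_S = 2.49e-5

#: ratio of water-vapour to CO2 diffusivity through the stomatal pore
GS_GCO2_RATIO = 1.6

#: standard atmospheric pressure, mbar
P_ATM_MBAR = 1013.0

#: molar density of air at 1013 mbar and 298.15 K, mol m^-3
AIR_MOLAR_DENSITY = P_ATM_MBAR * 100.0 / (R_J * TEMPERATURE_K)


def saturation_vapour_pressure_mbar(temperature_k: float = TEMPERATURE_K) -> float:
    """Saturation water-vapour pressure by the Tetens formula, in mbar.

    Tetens constants 6.1078 / 17.27 / 237.3 over liquid water; at 25 C this
    evaluates to 31.67 mbar.
    """
    t_c = temperature_k - 273.15
    return 6.1078 * math.exp(17.27 * t_c / (t_c + 237.3))
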