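"""Physical constants and instrument characteristics.

All delta values are per-mil (permil) internally; atom fractions and product
ratios are dimensionless in [0, 1]. Percentages appear only at the I/O layer.
"""

# International reference isotope ratios (overridable via config).
R15_AIR_N2 = 0.0036765     # 15N/14N of atmospheric N2
R18_VSMOW = 0.0020052      # 18O/16O of Vienna Standard Mean Ocean Water

# Ideal-gas constant in chamber-friendly units.
R_GAS_L_ATM = 0.0820573    # L atm mol-1 K-1
ZERO_CELSIUS_K = 273.15
N_MOLAR_MASS = 14.0        # g mol-1 per N atom

# Ambient air composition used for background subtraction and simulation.
N2_AIR_PPM = 780_900.0     # mole fraction of N2 in dry air, ppm
N2O_AIR_PPM = 0.33         # ambient N2O, ppm

# Laboratory-air N2O isotopic end members (emitted-signature extraction),
# measured prior to jar closure.
SP_AIR = 17.43             # permil, site preference of ambient N2O
O18_AIR_VSMOW = 45.33      # permil vs VSMOW
D18O_SOIL_WATER = -4.7     # permil vs VSMOW, local precipitation estimate

# 1-sigma instrument precisions.
GC_SIGMA_PPM = 0.006       # N2O concentration, gas chromatograph (6 ppb)
IRMS_SIGMA_R29 = 1.5e-6    # N2 isotopologue ratio 29/28
IRMS_SIGMA_R30 = 9.3e-6    # N2 isotopologue ratio 30/28
IRMS_SIGMA_R45 = 3.1e-5    # N2O isotopologue ratio 45/44
IRMS_SIGMA_R46 = 8.2e-5    # N2O isotopologue ratio 46/44
DELTA_SIGMA_BULK = 0.1     # permil, d15N-bulk
DELTA_SIGMA_SP = 0.1       # permil, d15N-SP
DELTA_SIGMA_O18 = 0.5      # permil, d18O

# Number of excess standard deviations below which an isotopologue excess is
# treated as indistinguishable from zero.
DETECTION_SIGMA_FACTOR = 3.0

# Quartz/mineral particle density used to estimate soil solids volume when the
# headspace volume is not given explicitly.
SOIL_PARTICLE_DENSITY = 2.65  # kg L-1
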