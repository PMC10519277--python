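"""Internal unit system and physical constants.

All internal quantities are expressed in micrometre-second-picogram units:

* length   : um
* time     : s
* mass     : pg

Derived units: velocity um/s, force pg*um/s^2, pressure/stress pg/(um*s^2)
(= 1e-9 Pa), dynamic viscosity pg/(um*s) (1 cP = 1e6 units), energy
pg*um^2/s^2 (= 1e-27 J).

Wall shear stress is reported externally in dyne/cm^2 (1 Pa = 10 dyne/cm^2),
the unit endothelial-cell mechanobiology uses.
"""

# conversion factors: multiply an external value by these to get internal units
CP = 1.0e6            # 1 centipoise in pg/(um*s)
PA = 1.0e9            # 1 pascal in pg/(um*s^2)
DYNE_PER_CM2 = 1.0e8  # 1 dyne/cm^2 = 0.1 Pa in internal stress units
JOULE = 1.0e27         # 1 joule in pg*um^2/s^2
NEWTON_PER_M = 1.0e15  # 1 N/m (membrane modulus) = 1 kg/s^2 in pg/s^2

#: plasma dynamic viscosity, 1.2 cP (close to water at body temperature)
MU_PLASMA = 1.2 * CP
#: cytosol (hemoglobin solution) viscosity ratio relative to plasma
LAMBDA_VISCOSITY = 5.0
#: fluid density ~ water, pg/um^3
RHO = 1.0

#: membrane shear elastic modulus G_s, 2.5 uN/m in pg/s^2
GS_DEFAULT = 2.5e-6 * NEWTON_PER_M
#: bending modulus k_b, 2e-19 J in pg*um^2/s^2
KB_DEFAULT = 2.0e-19 * JOULE
#: Skalak area-dilatation penalty constant
C_DILATATION = 100.0


def stress_to_dyne_cm2(value):
    """Convert an internal stress value to dyne/cm^2."""
    return value / DYNE_PER_CM2


def dyne_cm2_to_stress(value):
    """Convert dyne/cm^2 to internal stress units."""
    return value * DYNE_PER_CM2
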