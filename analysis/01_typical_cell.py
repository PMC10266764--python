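#!/usr/bin/env python
"""Self-consistency of the coarse-grained description of a typical
mammalian cell.

From the measured ion concentrations alone (160 mM cations and 20 mM
anions inside, 150 mM salt outside) the Pump-Leak model pins down the
pumping efficiency, the impermeant osmolyte pool, its mean charge and the
membrane potential; the steady-state solver then reproduces the same
composition from the other direction.  Writes results/typical_cell.json.
"""

from cellscale import io, pumpleak as pl

NPLUS, NMINUS, N0 = 160.0, 20.0, 150.0

alpha0 = pl.alpha0_from_concentrations(NPLUS, NMINUS, N0)
x = pl.impermeant_concentration_from_balance(NPLUS, NMINUS, N0)
z = pl.mean_charge_from_electroneutrality(NPLUS, NMINUS, x)
uc = pl.donnan_potential_mV(NMINUS, N0, T=300.0)
pi0_290 = pl.osmotic_pressure(2 * N0, T=290.0)

print(f"pumping efficiency alpha0      = {alpha0:.4f}  (prints as {alpha0:.2f})")
print(f"impermeant concentration x     = {x:.1f} mM")
print(f"mean valence magnitude z       = {z:.4f}  (prints as {z:.1f})")
print(f"Donnan potential               = {uc:.1f} mV at 300 K")
print(f"external osmotic pressure      = {pi0_290:.3g} Pa at 290 K")

# round trip: solving the model with (n0, alpha0, z) recovers the ion pair
params = pl.PumpLeakParams(n0=N0, alpha0=alpha0, z=z, X=1e10, R=20.0)
state = pl.solve_steady_state(params)
print(
    f"steady-state round trip        : n+ = {state.nplus:.2f} mM, "
    f"n- = {state.nminus:.2f} mM, x = {state.x:.2f} mM"
)

io.write_report(
    {
        "alpha0": alpha0,
        "x_mM": x,
        "z": z,
        "Uc_mV": uc,
        "Pi0_Pa_290K": pi0_290,
        "roundtrip": {"nplus": state.nplus, "nminus": state.nminus, "x": state.x},
    },
    "results/typical_cell.json",
    config={"nplus": NPLUS, "nminus": NMINUS, "n0": N0},
)
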