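"""Calibrate an optical trap from bead fluctuations, then convert a tether
pull into apparent membrane tension.

A 500 nm bead in water is simulated for 60 s at 20 kHz in a harmonic trap
of stiffness 0.05 pN/nm at 37 C. The power-spectrum method fits the
Lorentzian S(f) = D/(fc^2 + f^2); fc = k/(2 pi zeta) returns the
stiffness. The calibrated stiffness then converts a bead displacement into
a tether force F0 = k dx, and T = F0^2/(8 pi^2 B) into tension.
"""

import cgtension as cg

zeta = cg.zeta_from_stokes(radius_nm=500.0, viscosity_mpas=1.0)
print(f"Stokes drag zeta = {zeta:.3e} pN s/nm")

traj = cg.gen_bead_trajectory(
    k=0.05, zeta=zeta, kBT=4.28, fs=20_000.0, duration=60.0, seed=7
)
spec = cg.compute_psd(traj, n_blocks=32)
cal = cg.fit_lorentzian(spec, zeta=zeta)
print(f"corner frequency fc = {cal.fc_hz:.0f} Hz  (true: 845 Hz)")
print(f"trap stiffness k   = {cal.k_trap:.4f} pN/nm  (true: 0.0500)")

# a tether held 400 nm from the trap center, membrane B = 81 pN nm (~19 kBT)
meas = cg.TetherMeasurement.from_displacement(400.0, cal.k_trap, B_pnnm=81.0)
print(f"tether force F0    = {meas.f0_pn:.1f} pN")
print(f"apparent tension T = {meas.tension_pn_per_nm:.4f} pN/nm (B = 81 pN nm)")
# 'apparent': in cells this number mixes in-plane tension with
# membrane-cytoskeleton adhesion, which a tether pull cannot separate.
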