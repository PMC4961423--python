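"""Unit conventions and conversions.

The package works in a single consistent mechanical unit system throughout
the solvers:

========= ==========================
length    mm
force     N
stress    MPa (= N/mm^2)
mass      tonne (= 1e3 kg)
density   tonne/mm^3
time      s
velocity  mm/s
energy    mJ (= N*mm)
========= ==========================

With these units ``sqrt(E/rho)`` is a wave speed in mm/s and Newton's second
law holds without hidden scale factors — the classic way to avoid FE unit
bugs when mixing mm geometry with SI material data.

User-facing quantities keep the units practitioners use (apparent density in
g/cm^3, impact velocity in m/s, event times in ms) and are converted once at
ingest with the constants below.
"""

#: 1 g/cm^3 expressed in tonne/mm^3.
GCM3_TO_TMM3 = 1.0e-9

#: 1 m/s expressed in mm/s.
MS_TO_MMS = 1.0e3

#: 1 ms expressed in s.
MS_TO_S = 1.0e-3

#: mass in kg of 1 mm^3 at 1 g/cm^3 (used for model-mass bookkeeping).
KG_PER_MM3_AT_1GCM3 = 1.0e-6


def density_gcm3_to_solver(rho_gcm3):
    """Apparent density g/cm^3 -> tonne/mm^3 (solver mass density)."""
    return rho_gcm3 * GCM3_TO_TMM3


def velocity_ms_to_solver(v_ms):
    """Velocity m/s -> mm/s."""
    return v_ms * MS_TO_MMS


def time_ms_to_solver(t_ms):
    """Time ms -> s."""
    return t_ms * MS_TO_S
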