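"""Unit conventions.

Internal unit system is g-mm-ms, the consistent mechanical system in which
stresses come out in MPa, forces in N and energies in mJ (1 g*mm/ms^2 = 1 N,
1 N/mm^2 = 1 MPa, 1 N*mm = 1 mJ).  Pressures cross the API boundary in mmHg
(the clinical unit) and are converted on entry.
"""

#: 1 mmHg in MPa.
MMHG_TO_MPA = 1.33322e-4

#: Gravitational acceleration in mm/ms^2.
GRAVITY = 9.81e-3

#: Soft-tissue / humor mass density in g/mm^3 (1.0 g/cm^3).
TISSUE_DENSITY = 1.0e-3


def mmhg_to_mpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_MPA


def mpa_to_mmhg(p_mpa: float) -> float:
    return p_mpa / MMHG_TO_MPA
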