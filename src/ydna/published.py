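"""Published summary tables from the R1b-DF27 target-capture study.

The underlying sequences are controlled-access, but the printed summary
statistics — per-branch and per-region rho TMRCAs with their rate-derived
CIs, per-region diversity measures, and the pairwise phi_ST matrix — are
public and serve as inputs for reanalysis: CI propagation from point ages,
the pi = MPD / L identity, distance-matrix scans and MDS embedding.
"""

from __future__ import annotations

import pandas as pd

#: mutation-rate constants the study's dating rests on
MU_POINT = 0.76e-9
MU_LOW = 0.67e-9
MU_HIGH = 0.86e-9
TARGET_LENGTH = 8_900_000

#: per-branch rho TMRCA point estimates (years BP) with printed 95% CI
#: (from the mutation-rate CI)
BRANCH_RHO_TMRCA: dict[str, tuple[int, int, int]] = {
    "DF27": (5173, 4571, 5868),
    "A432": (3992, 3527, 4480),
    "CTS11567": (4028, 3560, 4570),
    "CTS6519": (5100, 4507, 5785),
    "DF81": (4368, 3876, 4975),
    "Z222": (3548, 3136, 4025),
    "Z195": (5374, 4749, 6096),
    "L176.2": (4505, 3981, 5110),
    "Z292": (4173, 3688, 4733),
    "M167": (4027, 3559, 4568),
    "Z205": (3941, 3488, 4470),
    "Z208": (3366, 2975, 3818),
    "CTS4299": (3414, 3017, 3872),
    "CTS4188": (4553, 4024, 5165),
    "Z272": (4832, 4271, 5482),
    "Z220": (4710, 4162, 5343),
    "Z295": (4043, 3573, 4587),
    "Z278": (3941, 3483, 4471),
    "S348": (3440, 3040, 3902),
    "M153": (2920, 2580, 3312),
    "CTS4065": (3918, 3462, 4444),
    "DF17": (3647, 3223, 4137),
}

#: per-region rho TMRCA point estimates (years BP) with printed CI bounds
REGION_RHO_TMRCA: dict[str, tuple[int, int, int]] = {
    "Andalusia": (4922, 4349, 5583),
    "Asturias": (5052, 4465, 5730),
    "Catalonia": (5424, 4793, 6152),
    "Central Spain": (4673, 4130, 5301),
    "Basque Country": (5473, 4804, 6167),
    "Galicia": (4991, 4411, 5662),
    "NW Europe": (5307, 4690, 6020),
    "Pooled": (5173, 4571, 5868),
}

#: per-region diversity: n, S, pi x 1000, MPD, Tajima's D
REGION_DIVERSITY: dict[str, tuple[int, int, float, float, float]] = {
    "Andalusia": (31, 868, 0.0071, 62.78, -2.766),
    "Asturias": (23, 670, 0.0073, 65.06, -2.616),
    "Catalonia": (32, 860, 0.0077, 68.37, -2.632),
    "Central Spain": (23, 614, 0.0067, 60.02, -2.606),
    "Basque Country": (53, 963, 0.0073, 65.09, -2.517),
    "Galicia": (21, 576, 0.0072, 64.10, -2.484),
    "NW Europe": (20, 582, 0.0075, 67.13, -2.471),
    "Pooled": (207, 4509, 0.0072, 65.74, -2.947),
}

#: AMOVA percent of variation among regions
AMOVA_PCT_AMONG = 1.51

_PHIST_REGIONS = [
    "Andalusia", "Asturias", "NW Europe", "Catalonia",
    "Central Spain", "Basque Country", "Galicia",
]

_PHIST_ROWS = [
    [0.0,      0.00805, 0.00927, 0.0244,  -0.00339, 0.01645, 0.0006],
    [0.00805,  0.0,     0.01231, 0.02435,  0.00435, 0.02055, 0.00577],
    [0.00927,  0.01231, 0.0,     0.00215,  0.00093, 0.02039, 0.00326],
    [0.0244,   0.02435, 0.00215, 0.0,      0.01356, 0.03741, 0.01291],
    [-0.00339, 0.00435, 0.00093, 0.01356,  0.0,     0.00842, -0.00103],
    [0.01645,  0.02055, 0.02039, 0.03741,  0.00842, 0.0,     0.02161],
    [0.0006,   0.00577, 0.00326, 0.01291, -0.00103, 0.02161, 0.0],
]


def pairwise_phist_matrix() -> pd.DataFrame:
    """Published pairwise phi_ST distances among geographical regions."""
    return pd.DataFrame(_PHIST_ROWS, index=_PHIST_REGIONS, columns=_PHIST_REGIONS)
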