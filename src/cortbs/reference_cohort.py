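"""Published cohort summary statistics used to calibrate the synthetic generator.

The synthetic cohort generator reproduces the statistical structure of an
in-vivo CortBS study population: aged controls and patients with type-1 or
type-2 diabetes mellitus (T1DM / T2DM), each split by prevalent fragility
fracture status (Fx / nFx).  The per-cell means and standard deviations below
are the published group summaries of that cohort (CortBS ultrasound
parameters, DXA densitometry, anthropometrics) and define the generator's
default study conditions.

Parameter naming follows the field's conventions: ``Ct.`` prefixes cortical
parameters, ``Dm.D`` the pore-diameter distribution and its derived metrics,
``aBMD``/``T-score`` the DXA quantities.
"""

from __future__ import annotations

import numpy as np

GROUPS = ("control", "T1DM", "T2DM")
FRACTURE_LABELS = ("Fx", "nFx")

ANTHRO_PARAMS = ["age", "height_cm", "weight_kg", "bmi"]

DXA_PARAMS = [
    "aBMD_Femur(Neck)",
    "aBMD_Femur(Total)",
    "aBMD_Spine",
    "T-score_Femur(Neck)",
    "T-score_Femur(Total)",
    "T-score_Spine",
]

CORTBS_PARAMS = [
    "α_0",
    "α_f",
    "α_6-MHz",
    "Ct.Po",
    "Ct.Po.Dm.D_peak",
    "Ct.Po.Dm.D_Q10",
    "Ct.Po.Dm.D_Q90",
    "Ct.Po.Dm.D_FWHM",
    "Ct.Po.Dm.D_FWHM,min",
    "Ct.Po.Dm.D_FWHM,max",
    "Ct.Po.Dm.I",
    "AIB_Average",
    "BSC_Mean",
]

ALL_PARAMS = ANTHRO_PARAMS + DXA_PARAMS + CORTBS_PARAMS

#: Observed subjects per (group, fracture) cell.
CELL_SIZES = {
    ("control", "Fx"): 16,
    ("control", "nFx"): 55,
    ("T1DM", "Fx"): 8,
    ("T1DM", "nFx"): 23,
    ("T2DM", "Fx"): 17,
    ("T2DM", "nFx"): 18,
}

#: Observed male fraction per cell (M / (M + F)).
MALE_FRACTION = {
    ("control", "Fx"): 6 / 16,
    ("control", "nFx"): 7 / 55,
    ("T1DM", "Fx"): 2 / 8,
    ("T1DM", "nFx"): 16 / 23,
    ("T2DM", "Fx"): 7 / 17,
    ("T2DM", "nFx"): 9 / 18,
}

# (mean, sd) per parameter, per (group, fracture) cell ----------------------

_ANTHRO = {
    "age": {
        ("control", "Fx"): (69.17, 3.52), ("control", "nFx"): (69.09, 5.91),
        ("T1DM", "Fx"): (66.00, 9.23), ("T1DM", "nFx"): (61.04, 7.06),
        ("T2DM", "Fx"): (65.75, 7.26), ("T2DM", "nFx"): (63.26, 5.85),
    },
    "height_cm": {
        ("control", "Fx"): (166.78, 6.87), ("control", "nFx"): (163.64, 7.10),
        ("T1DM", "Fx"): (169.62, 11.10), ("T1DM", "nFx"): (174.91, 9.84),
        ("T2DM", "Fx"): (169.10, 7.93), ("T2DM", "nFx"): (170.32, 10.05),
    },
    "weight_kg": {
        ("control", "Fx"): (68.33, 10.37), ("control", "nFx"): (63.77, 10.45),
        ("T1DM", "Fx"): (72.62, 20.01), ("T1DM", "nFx"): (79.87, 17.70),
        ("T2DM", "Fx"): (82.45, 18.09), ("T2DM", "nFx"): (85.16, 17.22),
    },
    "bmi": {
        ("control", "Fx"): (24.61, 3.78), ("control", "nFx"): (23.78, 3.33),
        ("T1DM", "Fx"): (24.95, 5.11), ("T1DM", "nFx"): (25.88, 3.99),
        ("T2DM", "Fx"): (28.70, 5.25), ("T2DM", "nFx"): (29.11, 3.70),
    },
}

_DXA = {
    "aBMD_Femur(Neck)": {
        ("control", "Fx"): (0.74, 0.09), ("control", "nFx"): (0.80, 0.11),
        ("T1DM", "Fx"): (0.77, 0.13), ("T1DM", "nFx"): (0.86, 0.15),
        ("T2DM", "Fx"): (0.83, 0.21), ("T2DM", "nFx"): (0.96, 0.16),
    },
    "aBMD_Femur(Total)": {
        ("control", "Fx"): (0.75, 0.09), ("control", "nFx"): (0.83, 0.13),
        ("T1DM", "Fx"): (0.82, 0.17), ("T1DM", "nFx"): (0.91, 0.16),
        ("T2DM", "Fx"): (0.90, 0.24), ("T2DM", "nFx"): (1.03, 0.19),
    },
    "aBMD_Spine": {
        ("control", "Fx"): (0.93, 0.11), ("control", "nFx"): (1.03, 0.19),
        ("T1DM", "Fx"): (1.14, 0.23), ("T1DM", "nFx"): (1.10, 0.16),
        ("T2DM", "Fx"): (1.10, 0.26), ("T2DM", "nFx"): (1.22, 0.17),
    },
    "T-score_Femur(Neck)": {
        ("control", "Fx"): (-1.78, 1.66), ("control", "nFx"): (-1.53, 0.89),
        ("T1DM", "Fx"): (-1.90, 1.10), ("T1DM", "nFx"): (-1.40, 1.21),
        ("T2DM", "Fx"): (-1.40, 1.57), ("T2DM", "nFx"): (-0.54, 1.17),
    },
    "T-score_Femur(Total)": {
        ("control", "Fx"): (-2.31, 0.73), ("control", "nFx"): (-1.50, 1.01),
        ("T1DM", "Fx"): (-1.62, 1.42), ("T1DM", "nFx"): (-1.13, 1.34),
        ("T2DM", "Fx"): (-1.09, 1.77), ("T2DM", "nFx"): (-0.13, 1.35),
    },
    "T-score_Spine": {
        ("control", "Fx"): (-2.29, 1.00), ("control", "nFx"): (-1.27, 1.50),
        ("T1DM", "Fx"): (-0.41, 1.88), ("T1DM", "nFx"): (-0.79, 1.34),
        ("T2DM", "Fx"): (-0.59, 2.09), ("T2DM", "nFx"): (0.19, 1.37),
    },
}

#: DXA summaries pooled over fracture status (group-level means), used by the
#: headline-effect design where DXA carries only the diabetes signal.
DXA_GROUP_POOLED = {
    "aBMD_Femur(Neck)": {"control": (0.79, 0.11), "T1DM": (0.83, 0.14), "T2DM": (0.90, 0.19)},
    "aBMD_Femur(Total)": {"control": (0.81, 0.12), "T1DM": (0.89, 0.16), "T2DM": (0.97, 0.22)},
    "aBMD_Spine": {"control": (1.01, 0.18), "T1DM": (1.11, 0.17), "T2DM": (1.16, 0.23)},
    "T-score_Femur(Neck)": {"control": (-1.59, 1.10), "T1DM": (-1.53, 1.19), "T2DM": (-0.96, 1.43)},
    "T-score_Femur(Total)": {"control": (-1.68, 1.01), "T1DM": (-1.25, 1.35), "T2DM": (-0.60, 1.62)},
    "T-score_Spine": {"control": (-1.50, 1.46), "T1DM": (-0.69, 1.47), "T2DM": (-0.19, 1.77)},
}

_CORTBS = {
    "α_0": {
        ("control", "Fx"): (1.91, 0.38), ("control", "nFx"): (1.78, 0.47),
        ("T1DM", "Fx"): (1.78, 0.44), ("T1DM", "nFx"): (1.48, 0.56),
        ("T2DM", "Fx"): (1.72, 0.46), ("T2DM", "nFx"): (1.36, 0.46),
    },
    "α_f": {
        ("control", "Fx"): (0.05, 0.06), ("control", "nFx"): (0.10, 0.07),
        ("T1DM", "Fx"): (0.12, 0.06), ("T1DM", "nFx"): (0.13, 0.08),
        ("T2DM", "Fx"): (0.06, 0.07), ("T2DM", "nFx"): (0.13, 0.07),
    },
    "α_6-MHz": {
        ("control", "Fx"): (2.21, 0.29), ("control", "nFx"): (2.39, 0.30),
        ("T1DM", "Fx"): (2.45, 0.17), ("T1DM", "nFx"): (2.22, 0.23),
        ("T2DM", "Fx"): (2.08, 0.23), ("T2DM", "nFx"): (2.11, 0.35),
    },
    "Ct.Po": {
        ("control", "Fx"): (11.65, 9.41), ("control", "nFx"): (8.80, 6.87),
        ("T1DM", "Fx"): (7.36, 2.76), ("T1DM", "nFx"): (7.13, 5.90),
        ("T2DM", "Fx"): (12.08, 10.39), ("T2DM", "nFx"): (6.59, 3.28),
    },
    "Ct.Po.Dm.D_peak": {
        ("control", "Fx"): (31.75, 7.46), ("control", "nFx"): (27.69, 5.27),
        ("T1DM", "Fx"): (28.38, 3.89), ("T1DM", "nFx"): (28.17, 6.09),
        ("T2DM", "Fx"): (33.08, 7.20), ("T2DM", "nFx"): (27.56, 4.67),
    },
    "Ct.Po.Dm.D_Q10": {
        ("control", "Fx"): (23.56, 3.12), ("control", "nFx"): (22.11, 1.85),
        ("T1DM", "Fx"): (22.25, 1.16), ("T1DM", "nFx"): (22.43, 2.11),
        ("T2DM", "Fx"): (24.14, 2.95), ("T2DM", "nFx"): (22.00, 1.57),
    },
    "Ct.Po.Dm.D_Q90": {
        ("control", "Fx"): (77.12, 21.01), ("control", "nFx"): (66.47, 17.02),
        ("T1DM", "Fx"): (66.38, 10.81), ("T1DM", "nFx"): (69.45, 20.27),
        ("T2DM", "Fx"): (83.33, 24.75), ("T2DM", "nFx"): (65.72, 12.68),
    },
    "Ct.Po.Dm.D_FWHM": {
        ("control", "Fx"): (40.92, 15.11), ("control", "nFx"): (32.64, 12.88),
        ("T1DM", "Fx"): (33.06, 8.88), ("T1DM", "nFx"): (34.38, 15.36),
        ("T2DM", "Fx"): (45.42, 17.80), ("T2DM", "nFx"): (32.36, 10.10),
    },
    "Ct.Po.Dm.D_FWHM,min": {
        ("control", "Fx"): (20.36, 1.42), ("control", "nFx"): (20.00, 0.00),
        ("T1DM", "Fx"): (20.00, 0.00), ("T1DM", "nFx"): (20.00, 0.00),
        ("T2DM", "Fx"): (20.10, 0.40), ("T2DM", "nFx"): (20.00, 0.00),
    },
    "Ct.Po.Dm.D_FWHM,max": {
        ("control", "Fx"): (61.28, 16.24), ("control", "nFx"): (52.64, 12.88),
        ("T1DM", "Fx"): (53.06, 8.88), ("T1DM", "nFx"): (54.38, 15.36),
        ("T2DM", "Fx"): (65.52, 17.98), ("T2DM", "nFx"): (52.36, 10.10),
    },
    "Ct.Po.Dm.I": {
        ("control", "Fx"): (4.81, 2.41), ("control", "nFx"): (3.63, 1.87),
        ("T1DM", "Fx"): (3.69, 1.28), ("T1DM", "nFx"): (3.45, 1.96),
        ("T2DM", "Fx"): (5.43, 2.67), ("T2DM", "nFx"): (3.58, 1.46),
    },
    "AIB_Average": {
        ("control", "Fx"): (-1.74, 0.82), ("control", "nFx"): (-1.65, 0.52),
        ("T1DM", "Fx"): (-1.60, 0.62), ("T1DM", "nFx"): (-2.20, 0.87),
        ("T2DM", "Fx"): (-1.63, 0.78), ("T2DM", "nFx"): (-2.08, 1.63),
    },
    "BSC_Mean": {
        ("control", "Fx"): (-13.88, 2.47), ("control", "nFx"): (-13.97, 2.11),
        ("T1DM", "Fx"): (-14.21, 1.59), ("T1DM", "nFx"): (-15.53, 2.02),
        ("T2DM", "Fx"): (-15.47, 1.99), ("T2DM", "nFx"): (-15.68, 3.05),
    },
}

CELL_STATS = {**_ANTHRO, **_DXA, **_CORTBS}

#: Plausible ranges used to clip multivariate-normal draws (clipping is logged).
CLIP_RANGES = {
    "age": (40.0, 95.0),
    "height_cm": (140.0, 200.0),
    "weight_kg": (35.0, 140.0),
    "bmi": (14.0, 45.0),
    "aBMD_Femur(Neck)": (0.3, 1.6),
    "aBMD_Femur(Total)": (0.3, 1.7),
    "aBMD_Spine": (0.4, 1.8),
    "T-score_Femur(Neck)": (-6.0, 4.0),
    "T-score_Femur(Total)": (-6.0, 4.0),
    "T-score_Spine": (-6.5, 4.0),
    "α_0": (0.0, 3.5),
    "α_f": (-0.15, 0.4),
    "α_6-MHz": (0.8, 3.8),
    "Ct.Po": (0.5, 50.0),
    "Ct.Po.Dm.D_peak": (20.0, 70.0),
    "Ct.Po.Dm.D_Q10": (20.0, 45.0),
    "Ct.Po.Dm.D_Q90": (40.0, 160.0),
    "Ct.Po.Dm.D_FWHM": (10.0, 100.0),
    "Ct.Po.Dm.D_FWHM,min": (20.0, 30.0),
    "Ct.Po.Dm.D_FWHM,max": (30.0, 130.0),
    "Ct.Po.Dm.I": (1.0, 12.0),
    "AIB_Average": (-9.0, 0.0),
    "BSC_Mean": (-26.0, -6.0),
}


def default_correlation() -> np.ndarray:
    """Default inter-parameter correlation matrix over :data:`ALL_PARAMS`.

    Block structure: anthropometrics correlate through body size; DXA
    densitometry variables are strongly mutually correlated; CortBS
    pore-geometry metrics (all derived from one distribution) form a
    moderately correlated block, as do the attenuation and backscatter
    amplitude parameters.  Cross-block correlations are weak.  The matrix is
    symmetric positive definite (verified by the test suite).
    """
    p = len(ALL_PARAMS)
    idx = {name: i for i, name in enumerate(ALL_PARAMS)}
    corr = np.eye(p)

    def set_block(names, r):
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r

    def set_pair(a, b, r):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r

    set_pair("height_cm", "weight_kg", 0.5)
    set_pair("weight_kg", "bmi", 0.8)
    set_pair("height_cm", "bmi", 0.05)
    set_block(DXA_PARAMS, 0.7)
    pore_block = [
        "Ct.Po", "Ct.Po.Dm.D_peak", "Ct.Po.Dm.D_Q10", "Ct.Po.Dm.D_Q90",
        "Ct.Po.Dm.D_FWHM", "Ct.Po.Dm.D_FWHM,max", "Ct.Po.Dm.I",
    ]
    set_block(pore_block, 0.55)
    set_pair("α_0", "α_6-MHz", 0.55)
    set_pair("α_f", "α_6-MHz", 0.35)
    set_pair("α_0", "α_f", -0.5)
    set_pair("BSC_Mean", "AIB_Average", 0.5)
    # weak coupling between backscatter amplitude and porosity
    set_pair("BSC_Mean", "Ct.Po", 0.2)
    return corr
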