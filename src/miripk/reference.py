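"""Published summary-level reference values for chikusetsusaponin IVa (CS-IVa).

The originating rat study released only group-level summaries (mean +/- SD,
n = 8 per arm) of the non-compartmental parameters, not per-animal
profiles.  Those summaries are reproduced here because they serve as
*inputs*: consistency relations between them (Vz = dose / (lambda_z *
AUC0-inf), CL = dose / AUC0-inf), the dose-exposure regression over group
means, and the Welch comparison of the Nor-15 vs MI/RI-15 arms are all
recomputable from this table alone, and the synthetic study design anchors
its true kinetic parameters to these values.

Units: Cmax mg/L; Tmax min; AUC min*mg/L; T1/2 and MRT min; Vd L/kg;
CL L/min/kg.
"""

from __future__ import annotations

#: molecular weight of CS-IVa (C42H66O14), g/mol
MOLECULAR_WEIGHT = 795.0

#: bioanalytical lower limit of quantification, nM
LLOQ_NM = 1.22

GROUPS = ("Nor-7.5", "Nor-15", "Nor-30", "MIRI-15")

DOSES_MG_PER_KG = {"Nor-7.5": 7.5, "Nor-15": 15.0, "Nor-30": 30.0, "MIRI-15": 15.0}

N_PER_GROUP = 8

#: group mean (first) and SD (second) of each NCA parameter, by group,
#: in the group order of GROUPS.
SUMMARY = {
    "cmax": {
        "Nor-7.5": (5.38, 0.74),
        "Nor-15": (9.34, 0.52),
        "Nor-30": (23.66, 2.58),
        "MIRI-15": (1.52, 0.14),
    },
    "tmax": {
        "Nor-7.5": (13.13, 2.59),
        "Nor-15": (18.75, 6.94),
        "Nor-30": (37.50, 13.89),
        "MIRI-15": (54.38, 7.76),
    },
    "auc_0_t": {
        "Nor-7.5": (353.01, 34.18),
        "Nor-15": (1527.05, 69.42),
        "Nor-30": (4635.15, 485.94),
        "MIRI-15": (706.22, 19.42),
    },
    "auc_0_inf": {
        "Nor-7.5": (360.99, 36.51),
        "Nor-15": (1655.36, 102.33),
        "Nor-30": (4756.53, 512.34),
        "MIRI-15": (717.20, 18.81),
    },
    "t_half": {
        "Nor-7.5": (326.69, 110.07),
        "Nor-15": (445.89, 32.30),
        "Nor-30": (277.11, 5.28),
        "MIRI-15": (238.66, 14.91),
    },
    "mrt_0_t": {
        "Nor-7.5": (179.84, 18.43),
        "Nor-15": (319.76, 31.84),
        "Nor-30": (352.53, 28.54),
        "MIRI-15": (334.69, 9.90),
    },
    "mrt_0_inf": {
        "Nor-7.5": (219.91, 55.85),
        "Nor-15": (455.09, 65.71),
        "Nor-30": (390.03, 32.02),
        "MIRI-15": (356.94, 15.29),
    },
    "vz": {
        "Nor-7.5": (9.75, 3.10),
        "Nor-15": (5.83, 0.23),
        "Nor-30": (2.55, 0.25),
        "MIRI-15": (7.21, 0.54),
    },
    "cl": {
        "Nor-7.5": (0.02, 0.00),
        "Nor-15": (0.01, 0.00),
        "Nor-30": (0.01, 0.00),
        "MIRI-15": (0.02, 0.00),
    },
}


def mean(parameter: str, group: str) -> float:
    return SUMMARY[parameter][group][0]


def sd(parameter: str, group: str) -> float:
    return SUMMARY[parameter][group][1]


def dose_exposure_points(parameter: str = "auc_0_t"):
    """(dose, group-mean) pairs over the three normal-rat arms."""
    groups = ("Nor-7.5", "Nor-15", "Nor-30")
    return (
        [DOSES_MG_PER_KG[g] for g in groups],
        [mean(parameter, g) for g in groups],
    )
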