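"""Published cohort summary statistics used for internal-consistency checks.

Means and standard deviations reported for a validation cohort of 12
trained male athletes (mass 81.2 +/- 11.1 kg, VO2max 64.8 +/- 4.9
ml/kg/min) who performed the three running-based exercises. Values are as
printed (kJ for energies, mmol/L for lactate); they are inputs for
arithmetic identity checks (W_TOT = W_AER + W_ANA, net lactate, relative
aerobic contribution), not outputs of this package.
"""

COHORT = {"n": 12, "mass_kg": (81.2, 11.1), "vo2max_ml_kg_min": (64.8, 4.9)}

#: Pre- and peak post-exercise blood lactate means, mmol/L.
LACTATE_MEANS = {
    "continuous_shuttles": {"la_pre": 1.62, "la_peak": 1.74, "delta_la": 0.12},
    "repeated_accelerations": {"la_pre": 1.70, "la_peak": 2.07, "delta_la": 0.37},
    "repeated_sprints": {"la_pre": 1.60, "la_peak": 13.73, "delta_la": 12.13},
}

#: Mean energy supplies (kJ) per exercise, model arm and break handling.
#: Arms: mpm = metabolic power model; tcm_ind / tcm_fix = three-component
#: model with individual / fixed energy equivalent.
ENERGY_MEANS = {
    "continuous_shuttles": {
        "incl_breaks": {
            "mpm": {"w_tot": 421.1, "w_aer": 324.4, "w_ana": 96.7},
            "tcm_ind": {"w_tot": 491.7, "w_aer": 486.0, "w_ana": 5.7},
            "tcm_fix": {"w_tot": 488.7, "w_aer": 483.0, "w_ana": 5.6},
        },
    },
    "repeated_accelerations": {
        "incl_breaks": {
            "mpm": {"w_tot": 92.6, "w_aer": 41.8, "w_ana": 50.8},
            "tcm_ind": {"w_tot": 195.5, "w_aer": 190.9, "w_ana": 4.6},
            "tcm_fix": {"w_tot": 193.4, "w_aer": 188.8, "w_ana": 4.6},
        },
        "excl_breaks": {
            "mpm": {"w_tot": 55.9, "w_aer": 5.1, "w_ana": 50.8},
            "tcm_ind": {"w_tot": 13.1, "w_aer": 8.5, "w_ana": 4.6},
            "tcm_fix": {"w_tot": 12.9, "w_aer": 8.4, "w_ana": 4.6},
        },
    },
    "repeated_sprints": {
        "incl_breaks": {
            "mpm": {"w_tot": 376.1, "w_aer": 152.7, "w_ana": 223.4},
            "tcm_ind": {"w_tot": 593.1, "w_aer": 524.1, "w_ana": 69.0},
            "tcm_fix": {"w_tot": 586.6, "w_aer": 518.3, "w_ana": 68.3},
        },
        "excl_breaks": {
            "mpm": {"w_tot": 305.2, "w_aer": 81.8, "w_ana": 223.4},
            "tcm_ind": {"w_tot": 176.6, "w_aer": 107.6, "w_ana": 69.0},
            "tcm_fix": {"w_tot": 174.7, "w_aer": 106.4, "w_ana": 68.3},
        },
    },
}
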