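"""Published per-axis values for the two ultrasound-monitored prostate
cohorts (step-and-shoot IMRT and VMAT), used as inputs for arithmetic
reproduction checks.  All values in mm, printed at two decimals; axis order
SI, AP, LR."""

# van Herk-path effective errors and margins
VAN_HERK_TABLE = {
    "SS-IMRT": {
        "sigma_sys_eff": (0.11, 0.30, 0.12),
        "sigma_rand_eff": (1.34, 2.26, 0.89),
        "im": (1.22, 2.33, 0.93),
    },
    "VMAT": {
        "sigma_sys_eff": (0.16, 0.20, 0.12),
        "sigma_rand_eff": (0.82, 0.98, 0.99),
        "im": (0.96, 1.18, 1.01),
    },
}

# REML-path variance components and margins (N = 37 fractions)
REML_TABLE = {
    "SS-IMRT": {
        "sigma_pt": (0.00, 0.10, 0.00),
        "sigma_fr": (0.41, 0.80, 0.31),
        "sigma_intra": (0.34, 0.69, 0.23),
        "sigma_sys_eff": (0.07, 0.17, 0.05),
        "sigma_rand_eff": (0.53, 1.05, 0.39),
        "im": (0.54, 1.15, 0.40),
    },
    "VMAT": {
        "sigma_pt": (0.07, 0.05, 0.00),
        "sigma_fr": (0.60, 0.65, 0.60),
        "sigma_intra": (0.23, 0.32, 0.28),
        "sigma_sys_eff": (0.12, 0.12, 0.10),
        "sigma_rand_eff": (0.64, 0.72, 0.66),
        "im": (0.75, 0.80, 0.71),
    },
}

N_FRACTIONS = 37
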