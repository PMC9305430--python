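"""Reference summary statistics of the 12-week loyalty-card avatar trial.

These published summary values anchor the synthetic-data generator's
defaults and give the analysis module something to reproduce: the CONSORT
participant funnel, baseline medians and IQRs of the outcome battery, the
primary-outcome medians by 4-week period and group, and the inputs of the
trial's sample-size calculation.  All nutritional values are solid-food
FSA-NPS DI points; steps are per day; surveys are 1–7 Likert scores.
"""

from __future__ import annotations

#: participant flow of the trial
CONSORT = {
    "downloaded": 167,
    "randomized": 95,
    "intervention": 42,
    "control": 53,
    "accelerometer_failures": 3,
    "loyalty_card_failures": 28,
    "completers": 30,
    "female": 52,
    "male": 43,
}

#: participants contributing step data per period (both groups pooled)
STEP_N_BY_PERIOD = {"T0": 92, "T1": 78, "T2": 42, "T3": 30}

#: participants contributing food-purchase data at baseline
FOOD_N_BASELINE = 67

#: baseline (T0) medians and IQRs, whole cohort
BASELINE = {
    "steps": {"median": 4624.00, "iqr": 4497.79},
    "solid_di": {"median": 6.13, "iqr": 4.02},
    "sugar_pts": {"median": 0.88, "iqr": 1.20},
    "satfat_pts": {"median": 3.01, "iqr": 1.66},
    "sodium_pts": {"median": 2.50, "iqr": 1.40},
    "fvln_pts": {"median": 0.30, "iqr": 0.48},
    "fiber_pts": {"median": 1.53, "iqr": 0.77},
    "protein_pts": {"median": 3.16, "iqr": 0.93},
    "motivational_self_efficacy": {"median": 6.00, "iqr": 1.25},
    "recovery_self_efficacy": {"median": 6.00, "iqr": 1.50},
    "outcome_expectancy": {"median": 6.20, "iqr": 1.60},
    "intrinsic_motivation": {"median": 6.00, "iqr": 1.33},
    "extrinsic_motivation": {"median": 3.00, "iqr": 2.33},
}

#: primary-outcome medians (IQR) by period and group
PRIMARY_BY_PERIOD = {
    "steps": {
        "intervention": {
            "T0": (4314.83, 3620.33),
            "T1": (4577.85, 4620.26),
            "T2": (6042.45, 6242.31),
            "T3": (4556.94, 5226.94),
        },
        "control": {
            "T0": (5084.83, 5220.33),
            "T1": (5361.50, 5960.88),
            "T2": (4909.32, 5128.09),
            "T3": (4821.64, 5228.79),
        },
    },
    "solid_di": {
        "intervention": {
            "T0": (6.73, 5.03),
            "T1": (6.79, 3.67),
            "T2": (6.14, 2.63),
            "T3": (5.45, 3.19),
        },
        "control": {
            "T0": (5.83, 4.11),
            "T1": (5.79, 5.41),
            "T2": (4.42, 5.42),
            "T3": (4.86, 3.75),
        },
    },
}

#: baseline gender x group counts (male/female by intervention/control)
GENDER_BY_GROUP = {
    "intervention": {"male": 19, "female": 23},
    "control": {"male": 24, "female": 29},
}

#: demographics medians
DEMOGRAPHICS = {
    "age": {"median": 44, "iqr": 19},
    "household_size": {"median": 2, "iqr": 2},
    "bmi_class_counts": {"<25": 56, "25-30": 28, ">30": 11},
}

#: inputs of the trial's a-priori sample-size calculation
SAMPLE_SIZE_INPUTS = {
    "delta_steps": 1566.0,
    "sd_steps": 2620.0,
    "alpha": 0.05,
    "power": 0.80,
    "anticipated_dropout": 0.20,
}

#: weekly login medians by period (engagement)
LOGINS_BY_PERIOD = {
    "intervention": {"T1": 5, "T2": 1, "T3": 1},
    "control": {"T1": 4, "T2": 1, "T3": 2},
}
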