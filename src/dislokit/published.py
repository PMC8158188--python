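"""Published reference values for the nationwide Danish validation study.

These numbers are the printed results of the chart-review validation of the
stepwise dislocation-detection algorithm on 31,762 primary-osteoarthritis
THAs operated 2010-2014 with two-year follow-up. They are inputs to this
package: the implied-count reconstruction inverts the printed accuracy table
back to integer confusion counts, and the synthetic registry generator is
calibrated against them.
"""

COHORT_SIZE = 31_762          # primary THAs after inclusion/exclusion
DISLOCATION_PATIENTS = 1_094  # patients with >= 1 verified dislocation
DISLOCATION_EVENTS = 1_890    # verified dislocation episodes
TRUE_NEGATIVE_PATIENTS = COHORT_SIZE - DISLOCATION_PATIENTS  # 30,668

CUMULATIVE_INCIDENCE_PCT = 3.4  # two-year risk of >= 1 dislocation, %

STEP_ORDER = ("1", "2", "3", "4", "4A", "5", "5A")

#: Patient-level accuracy per cumulative step, % (point estimates).
PATIENT_LEVEL_ACCURACY = {
    "1":  {"sensitivity": 62.7, "specificity": 99.9, "ppv": 97.9, "npv": 98.7},
    "2":  {"sensitivity": 77.0, "specificity": 99.9, "ppv": 96.5, "npv": 99.2},
    "3":  {"sensitivity": 85.1, "specificity": 99.9, "ppv": 96.3, "npv": 99.5},
    "4":  {"sensitivity": 91.3, "specificity": 99.8, "ppv": 93.3, "npv": 99.7},
    "4A": {"sensitivity": 91.3, "specificity": 99.9, "ppv": 96.5, "npv": 99.7},
    "5":  {"sensitivity": 95.4, "specificity": 99.2, "ppv": 81.8, "npv": 99.8},
    "5A": {"sensitivity": 95.4, "specificity": 99.8, "ppv": 96.6, "npv": 99.8},
}

#: Published 95% confidence intervals (%, lower-upper) for the same table.
PATIENT_LEVEL_CI = {
    "1":  {"sensitivity": (59.8, 65.6), "specificity": (99.9, 99.9), "ppv": (96.5, 98.8), "npv": (98.6, 98.8)},
    "2":  {"sensitivity": (74.4, 79.4), "specificity": (99.9, 99.9), "ppv": (95.0, 97.6), "npv": (99.1, 99.3)},
    "3":  {"sensitivity": (82.9, 87.2), "specificity": (99.8, 99.9), "ppv": (94.9, 97.4), "npv": (99.4, 99.5)},
    "4":  {"sensitivity": (89.5, 92.9), "specificity": (99.7, 99.8), "ppv": (91.6, 94.7), "npv": (99.6, 99.7)},
    "4A": {"sensitivity": (89.5, 92.9), "specificity": (99.8, 99.9), "ppv": (95.2, 97.6), "npv": (99.6, 99.7)},
    "5":  {"sensitivity": (93.9, 96.5), "specificity": (99.1, 99.3), "ppv": (79.4, 83.7), "npv": (99.8, 99.9)},
    "5A": {"sensitivity": (93.9, 96.5), "specificity": (99.8, 99.9), "ppv": (95.4, 97.7), "npv": (99.8, 99.9)},
}

#: Event-level accuracy (whole percent) for the "count every dislocation"
#: use case; only steps 4 and 5 were published.
EVENT_LEVEL_ACCURACY = {
    "4": {"sensitivity": 88, "ppv": 94},
    "5": {"sensitivity": 95, "ppv": 84},
}

#: Literature range for the fraction of dislocators who re-dislocate,
#: used as a plausibility check on the event-multiplicity model.
REDISLOCATION_FRACTION_RANGE = (0.40, 0.68)
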