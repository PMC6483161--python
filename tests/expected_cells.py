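"""Frozen expected values for the shipped preset tables.

Each table is a mapping: metric row -> list of per-column expected values in
printed units (integer percents for metric rows, percent units for
Prevalence/Target, raw ratio for Relative Risk, integer for NNTs).
``None`` marks a cell excluded from the golden set because the printed value
is inconsistent with the other cells of its own column (see
docs/methods.md, "Known inconsistent cells").
"""

# 16 columns: rare-reasonable (4), rare-exceptional (4), common-predictive (4),
# less-effective (4: two at uniform 50%, two at 75%/25% differential).
RARE_VS_COMMON = {
    "Prevalence": [None, None, None, 2, 2, 2, 2, 2, 20, 20, 20, 20, 20, 20, 20, 20],
    "Relative Risk": [4.7, 3.0, 2.4, 2.0, 10, 9.0, 5.6, 4.0, 4.7, 3.0, 2.4, 2.0, 4.7, 4.0, 4.7, 3.0],
    "Target": [5, 10, 15, 20, 5, 10, 15, 20, 5, 10, 15, 20, 5, 10, 5, 10],
    "PPV/Precision": [8, 5, 4, 3, 14, 10, 7, 5, 79, 50, 40, 33, 79, 62, 79, 50],
    "NPV": [98, 98, 98, 98, 99, 99, 99, 99, 83, 83, 83, 83, 83, 85, 83, 83],
    "Accuracy": [94, 89, 84, 79, 94, 90, 85, 80, 83, 80, 77, 73, 83, 82, 83, 80],
    "Sensitivity": [20, 25, 30, 33, 34, 50, 50, 50, 20, 25, 30, None, 20, 31, 20, 25],
    "Specificity": [95, 90, 85, 80, 96, 91, 86, 81, 99, 94, 89, None, 99, 95, 99, 94],
    "Effectiveness": [90, 90, 90, 90, 90, 90, 90, 90, 90, 90, 90, 90, 50, 50, (75, 25), (75, 25)],
    "Percent of Preventable": [20, 25, 30, 33, 34, 50, 50, 50, 20, 25, 30, 33, 20, 31, 43, 50],
    "Percent of All Prevented": [18, 23, 27, 30, 31, 45, 45, 45, 18, 23, 27, 30, 10, 15, 15, 19],
    "NNT All": [56, 56, 56, 56, 56, 56, 56, 56, 6, 6, 6, 6, 10, 10, 14, 13],
    "NNT Targeted": [14, 22, 28, 33, 8, 11, 17, 22, 1, 2, 3, 3, 3, 3, 2, 3],
}

# 11 columns: opioid use disorder (3), cardiovascular events under intensive
# blood-pressure therapy (4, annual rate), osteoporotic bone fracture (4).
OBSERVED_CONDITIONS = {
    "Prevalence": [5, 8, 8, 2.2, 12, 12, 12, 16, 16, 16, 16],
    "Relative Risk": [6, 8.7, 2, 3.3, 2.2, 1.6, 1.2, 3, 5, 2.3, 1.3],
    "Target": [1, 5, 33, 5, 20, 50, 80, 8, 10, 50, 80],
    "PPV/Precision": [29, 50, 12, 7, 21, 15, 12, 41, 57, 22, 17],
    "NPV": [95, 94, 94, 98, 90, 91, 90, 86, 89, 90, 87],
    "Accuracy": [95, 92, 67, 93, 77, 53, 28, 83, 85, 56, 31],
    "Sensitivity": [6, 31, 50, 15, 35, 62, 83, 21, 36, 70, 84],
    "Specificity": [99, 97, 68, 95, 82, 52, 20, 94, 95, 54, 21],
    "Effectiveness": [80, 80, 50, 25, 25, 25, 25, 60, 60, 60, 60],
    "Percent of Preventable": [6, 31, 50, 15, 35, 62, 83, 21, None, 70, 84],
    "Percent of All Prevented": [5, 25, 25, 4, 9, 15, 21, 12, 21, 42, 50],
    "NNT All": [25, 16, 25, 182, 33, 33, 33, 10, 10, 10, 10],
    "NNT Targeted": [4, 2, 17, 61, 19, 27, 32, 4, 3, 7, 10],
}

PERCENT_ROWS = [
    "PPV/Precision",
    "NPV",
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "Percent of Preventable",
    "Percent of All Prevented",
]


def iter_golden_cells(expected):
    """Yield (row, column_index, expected_value), skipping excluded cells."""
    for row, values in expected.items():
        for i, value in enumerate(values):
            if value is not None:
                yield row, i, value
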