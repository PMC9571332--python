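"""Published measurement records of the validation study, transcribed.

These small fixtures are the printed inputs of the study's reported
deviation statistics: the four-method comparison on a hand model, the
knuckle-hold reference poses, the per-volunteer visual angle measurements
at three marker widths, the in-text per-volunteer mean deviations at the
1.5 mm width, and the abduction measurements.  They let the evaluation
module recompute every printed mean-deviation figure without external data.

Transcription notes: two cells in the volunteer table carry stray trailing
periods in print ("109.27.", "29.91.") and are transcribed as the plain
numbers; two angle cells (139.74 for volunteer 2 and 159.31 for volunteer
9, both at 1.5 mm) are implausible outliers — evident typos — and are kept
verbatim, since the evaluation flags rather than repairs inconsistencies.
"""

from __future__ import annotations

# Four-method comparison on the hand model (high-angle illumination).
# Reference (traditional goniometry): MCP 145, PIP 110, DIP 112 degrees.
METHOD_COMPARISON_REFERENCE = (145.0, 110.0, 112.0)

# per variant: measured (MCP, PIP, DIP) and the printed mean deviation
METHOD_COMPARISON = {
    "hsv-hoislm": {"angles": (145.02, 111.03, 111.83), "printed_mean": 0.407},
    "hsv-lsflkadm": {"angles": (144.76, 109.38, 114.07),
                     "printed_mean": 0.967},
    "ts-homldm": {"angles": (144.95, 110.48, 112.09), "printed_mean": 0.207},
    "ts-lsflm": {"angles": (144.59, 111.26, 112.34), "printed_mean": 0.670},
}

# Measured phalanx lengths (mm) per variant, reference 27 / 26 mm.
METHOD_COMPARISON_LENGTHS = {
    "hsv-hoislm": (26.94, 25.53),
    "hsv-lsflkadm": (28.24, 25.53),
    "ts-homldm": (27.37, 25.64),
    "ts-lsflm": (27.32, 25.26),
    "reference": (27.0, 26.0),
}

# Knuckle-hold reference poses (MCP, PIP, DIP) used for every volunteer.
KNUCKLE_HOLD_POSES = ((145.0, 110.0, 115.0),
                      (160.0, 130.0, 110.0),
                      (150.0, 165.0, 130.0))

# Per-volunteer visual measurements: volunteer -> marker width (mm) ->
# three (MCP, PIP, DIP) rows matching KNUCKLE_HOLD_POSES in order.
VOLUNTEER_ANGLES = {
    1: {1.5: ((144.72, 109.31, 115.42), (160.10, 130.12, 109.21),
              (149.48, 165.72, 130.31)),
        2.0: ((145.21, 109.10, 114.42), (161.71, 132.22, 109.71),
              (151.31, 167.28, 130.02)),
        2.5: ((144.72, 108.91, 115.92), (160.40, 128.93, 109.27),
              (147.32, 164.89, 133.22))},
    2: {1.5: ((145.31, 110.21, 114.71), (159.27, 130.31, 111.31),
              (150.32, 164.44, 139.74)),
        2.0: ((143.31, 110.72, 116.71), (160.44, 129.10, 110.23),
              (150.77, 165.69, 131.21)),
        2.5: ((146.21, 110.79, 114.49), (162.99, 131.44, 111.22),
              (150.55, 167.21, 131.59))},
    3: {1.5: ((144.81, 110.47, 115.69), (160.77, 130.21, 110.48),
              (150.06, 165.56, 131.81)),
        2.0: ((144.31, 111.81, 114.01), (161.17, 130.79, 112.58),
              (150.97, 163.84, 130.91)),
        2.5: ((146.79, 110.11, 115.98), (160.89, 129.33, 111.39),
              (150.34, 166.79, 130.44))},
    4: {1.5: ((145.32, 110.17, 114.87), (160.17, 130.22, 109.97),
              (150.27, 164.90, 131.07)),
        2.0: ((146.32, 110.54, 115.94), (159.12, 130.84, 110.95),
              (149.71, 165.55, 128.77)),
        2.5: ((146.71, 110.21, 116.19), (160.77, 131.44, 108.22),
              (151.45, 165.99, 130.97))},
    5: {1.5: ((145.21, 109.55, 115.94), (160.56, 129.53, 109.84),
              (150.41, 165.77, 129.92)),
        2.0: ((145.99, 109.21, 116.31), (160.77, 131.74, 109.55),
              (150.22, 166.33, 130.44)),
        2.5: ((145.97, 109.22, 115.33), (161.44, 130.55, 110.89),
              (148.97, 165.33, 131.75))},
    6: {1.5: ((145.31, 109.12, 114.33), (160.33, 130.22, 109.22),
              (150.22, 165.72, 130.33)),
        2.0: ((145.33, 110.47, 115.33), (161.43, 130.99, 109.44),
              (150.67, 165.33, 131.65)),
        2.5: ((146.12, 110.22, 115.48), (158.91, 130.21, 110.77),
              (149.23, 163.47, 131.22))},
    7: {1.5: ((145.33, 110.32, 116.12), (159.31, 130.07, 110.77),
              (150.21, 165.22, 129.22)),
        2.0: ((146.71, 110.42, 113.41), (160.12, 130.65, 110.89),
              (151.14, 164.31, 130.22)),
        2.5: ((145.42, 110.31, 114.21), (161.31, 128.64, 109.01),
              (152.12, 166.21, 129.13))},
    8: {1.5: ((145.32, 110.77, 114.57), (160.74, 129.22, 110.10),
              (151.12, 165.33, 129.38)),
        2.0: ((145.72, 110.31, 116.66), (159.21, 131.72, 110.07),
              (150.56, 166.77, 130.33)),
        2.5: ((145.32, 110.07, 115.21), (157.42, 131.72, 110.99),
              (150.22, 166.23, 129.25))},
    9: {1.5: ((145.31, 110.23, 115.76), (160.22, 130.74, 110.55),
              (159.31, 165.21, 130.90)),
        2.0: ((146.13, 111.31, 114.31), (158.91, 129.10, 110.12),
              (149.01, 165.12, 131.14)),
        2.5: ((143.21, 109.22, 115.33), (160.33, 131.55, 107.32),
              (151.33, 165.77, 129.22))},
}

# In-text per-volunteer mean deviations at the 1.5 mm width.
FLEXION_15MM_PRINTED = {1: 0.43, 2: 0.47, 3: 0.58, 4: 0.27, 5: 0.45,
                        6: 0.5, 7: 0.5, 8: 0.59, 9: 0.51}

# Abduction study: per-volunteer visual measurements of the three spread
# angles, the common reference, and the printed per-volunteer means.
ABDUCTION_REFERENCE = (25.0, 40.0, 40.0)
ABDUCTION = {
    1: {"angles": (25.73, 39.21, 40.39), "printed_mean": 0.63},
    2: {"angles": (24.32, 39.03, 40.41), "printed_mean": 0.68},
    3: {"angles": (23.91, 40.71, 40.51), "printed_mean": 0.77},
    4: {"angles": (24.41, 39.93, 40.33), "printed_mean": 0.33},
    5: {"angles": (25.22, 39.35, 40.61), "printed_mean": 0.49},
    6: {"angles": (24.12, 38.77, 41.12), "printed_mean": 0.61},
    7: {"angles": (24.52, 39.79, 40.22), "printed_mean": 0.30},
    8: {"angles": (24.91, 38.54, 40.89), "printed_mean": 0.81},
    9: {"angles": (24.33, 40.95, 40.87), "printed_mean": 0.83},
}
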