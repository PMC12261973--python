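"""Frozen reference values (validation-study tables) for the acceptance tests.

Scenario keys are ``(randomization, N, dist, rho)`` with ``dist`` in
``{"uneq", "eq"}`` (cluster-level proportions (0.70, 0.15, 0.10, 0.05)
and (0.25, 0.25, 0.25, 0.25)).  Table values are
``(independence, exchangeable)`` pairs; DEFFs at 2 dp, powers in
percent.
"""

# cluster counts M_1..M_4 by (outcome, dist, N)
COUNTS = {
    ("continuous", "uneq", 240): (112, 24, 16, 8),
    ("continuous", "uneq", 600): (280, 60, 40, 20),
    ("continuous", "eq", 240): (24, 24, 24, 24),
    ("continuous", "eq", 600): (60, 60, 60, 60),
    ("binary", "uneq", 360): (168, 36, 24, 12),
    ("binary", "uneq", 840): (392, 84, 56, 28),
    ("binary", "eq", 360): (36, 36, 36, 36),
    ("binary", "eq", 840): (84, 84, 84, 84),
}

GAMMA_UNEQ = (0.47, 0.20, 0.20, 0.13)
GAMMA_EQ = (0.1, 0.2, 0.3, 0.4)

# continuous outcome: expected DEFF
TABLE3_EXPECTED = {
    ("cluster", 240, "uneq", 0.2): (1.20, 1.16),
    ("cluster", 240, "uneq", 0.8): (1.80, 1.44),
    ("cluster", 240, "eq", 0.2): (1.40, 1.37),
    ("cluster", 240, "eq", 0.8): (2.60, 2.25),
    ("cluster", 600, "uneq", 0.2): (1.20, 1.16),
    ("cluster", 600, "uneq", 0.8): (1.80, 1.44),
    ("cluster", 600, "eq", 0.2): (1.40, 1.37),
    ("cluster", 600, "eq", 0.8): (2.60, 2.25),
    ("individual", 240, "uneq", 0.2): (1.00, 0.97),
    ("individual", 240, "uneq", 0.8): (1.00, 0.45),
    ("individual", 240, "eq", 0.2): (1.00, 0.94),
    ("individual", 240, "eq", 0.8): (1.00, 0.31),
    ("individual", 600, "uneq", 0.2): (1.00, 0.97),
    ("individual", 600, "uneq", 0.8): (1.00, 0.45),
    ("individual", 600, "eq", 0.2): (1.00, 0.94),
    ("individual", 600, "eq", 0.8): (1.00, 0.31),
}

# continuous outcome: observed (median) DEFF
TABLE3_OBSERVED = {
    ("cluster", 240, "uneq", 0.2): (1.17, 1.14),
    ("cluster", 240, "uneq", 0.8): (1.75, 1.44),
    ("cluster", 240, "eq", 0.2): (1.36, 1.33),
    ("cluster", 240, "eq", 0.8): (2.55, 2.22),
    ("cluster", 600, "uneq", 0.2): (1.19, 1.15),
    ("cluster", 600, "uneq", 0.8): (1.78, 1.44),
    ("cluster", 600, "eq", 0.2): (1.39, 1.35),
    ("cluster", 600, "eq", 0.8): (2.58, 2.24),
    ("individual", 240, "uneq", 0.2): (0.98, 0.95),
    ("individual", 240, "uneq", 0.8): (0.96, 0.48),
    ("individual", 240, "eq", 0.2): (0.97, 0.91),
    ("individual", 240, "eq", 0.8): (0.95, 0.31),
    ("individual", 600, "uneq", 0.2): (0.99, 0.96),
    ("individual", 600, "uneq", 0.8): (0.98, 0.46),
    ("individual", 600, "eq", 0.2): (0.99, 0.93),
    ("individual", 600, "eq", 0.8): (0.98, 0.31),
}

# continuous outcome: observed and expected power (percent)
TABLE4_OBSERVED = {
    ("cluster", 240, "uneq", 0.2): (42.72, 44.33),
    ("cluster", 240, "uneq", 0.8): (32.45, 37.70),
    ("cluster", 240, "eq", 0.2): (39.13, 40.34),
    ("cluster", 240, "eq", 0.8): (23.59, 26.01),
    ("cluster", 600, "uneq", 0.2): (80.34, 81.72),
    ("cluster", 600, "uneq", 0.8): (62.50, 71.74),
    ("cluster", 600, "eq", 0.2): (74.56, 75.64),
    ("cluster", 600, "eq", 0.8): (48.24, 53.12),
    ("individual", 240, "uneq", 0.2): (49.55, 51.15),
    ("individual", 240, "uneq", 0.8): (51.28, 78.58),
    ("individual", 240, "eq", 0.2): (49.91, 52.44),
    ("individual", 240, "eq", 0.8): (52.69, 93.38),
    ("individual", 600, "uneq", 0.2): (86.30, 87.50),
    ("individual", 600, "uneq", 0.8): (86.20, 99.33),
    ("individual", 600, "eq", 0.2): (86.62, 88.94),
    ("individual", 600, "eq", 0.8): (87.17, 99.97),
}

TABLE4_EXPECTED = {
    ("cluster", 240, "uneq", 0.2): (42.05, 43.14),
    ("cluster", 240, "uneq", 0.8): (29.94, 36.10),
    ("cluster", 240, "eq", 0.2): (36.99, 37.71),
    ("cluster", 240, "eq", 0.8): (22.10, 24.85),
    ("cluster", 600, "uneq", 0.2): (79.67, 80.88),
    ("cluster", 600, "uneq", 0.8): (62.39, 72.06),
    ("cluster", 600, "eq", 0.2): (73.30, 74.28),
    ("cluster", 600, "eq", 0.8): (47.25, 52.92),
    ("individual", 240, "uneq", 0.2): (48.76, 50.11),
    ("individual", 240, "uneq", 0.8): (48.76, 82.20),
    ("individual", 240, "eq", 0.2): (48.76, 51.32),
    ("individual", 240, "eq", 0.8): (48.76, 93.48),
    ("individual", 600, "uneq", 0.2): (86.37, 87.50),
    ("individual", 600, "uneq", 0.8): (86.37, 99.54),
    ("individual", 600, "eq", 0.2): (86.37, 88.46),
    ("individual", 600, "eq", 0.8): (86.37, 99.98),
}

# binary outcome, logit link: expected DEFF
TABLE5_EXPECTED = {
    ("cluster", 360, "uneq", 0.2): (1.20, 1.16),
    ("cluster", 360, "uneq", 0.8): (1.80, 1.44),
    ("cluster", 360, "eq", 0.2): (1.40, 1.37),
    ("cluster", 360, "eq", 0.8): (2.60, 2.25),
    ("cluster", 840, "uneq", 0.2): (1.20, 1.16),
    ("cluster", 840, "uneq", 0.8): (1.80, 1.44),
    ("cluster", 840, "eq", 0.2): (1.40, 1.37),
    ("cluster", 840, "eq", 0.8): (2.60, 2.25),
    ("individual", 360, "uneq", 0.2): (1.00, 0.97),
    ("individual", 360, "uneq", 0.8): (1.00, 0.45),
    ("individual", 360, "eq", 0.2): (1.00, 0.94),
    ("individual", 360, "eq", 0.8): (1.00, 0.31),
    ("individual", 840, "uneq", 0.2): (1.00, 0.97),
    ("individual", 840, "uneq", 0.8): (1.00, 0.45),
    ("individual", 840, "eq", 0.2): (1.00, 0.94),
    ("individual", 840, "eq", 0.8): (1.00, 0.31),
}

TABLE5_OBSERVED = {
    ("cluster", 360, "uneq", 0.2): (1.19, 1.16),
    ("cluster", 360, "uneq", 0.8): (1.79, 1.44),
    ("cluster", 360, "eq", 0.2): (1.38, 1.36),
    ("cluster", 360, "eq", 0.8): (2.58, 2.24),
    ("cluster", 840, "uneq", 0.2): (1.19, 1.16),
    ("cluster", 840, "uneq", 0.8): (1.79, 1.44),
    ("cluster", 840, "eq", 0.2): (1.39, 1.36),
    ("cluster", 840, "eq", 0.8): (2.59, 2.25),
    ("individual", 360, "uneq", 0.2): (0.99, 0.96),
    ("individual", 360, "uneq", 0.8): (0.98, 0.44),
    ("individual", 360, "eq", 0.2): (0.99, 0.93),
    ("individual", 360, "eq", 0.8): (0.98, 0.30),
    ("individual", 840, "uneq", 0.2): (1.00, 0.96),
    ("individual", 840, "uneq", 0.8): (0.99, 0.45),
    ("individual", 840, "eq", 0.2): (1.00, 0.93),
    ("individual", 840, "eq", 0.8): (0.99, 0.31),
}

TABLE6_OBSERVED = {
    ("cluster", 360, "uneq", 0.2): (44.87, 45.85),
    ("cluster", 360, "uneq", 0.8): (32.41, 38.42),
    ("cluster", 360, "eq", 0.2): (39.96, 40.92),
    ("cluster", 360, "eq", 0.8): (22.97, 25.95),
    ("cluster", 840, "uneq", 0.2): (78.86, 80.35),
    ("cluster", 840, "uneq", 0.8): (62.34, 71.70),
    ("cluster", 840, "eq", 0.2): (72.75, 73.84),
    ("cluster", 840, "eq", 0.8): (47.36, 52.89),
    ("individual", 360, "uneq", 0.2): (51.33, 52.81),
    ("individual", 360, "uneq", 0.8): (52.61, 90.72),
    ("individual", 360, "eq", 0.2): (51.75, 54.62),
    ("individual", 360, "eq", 0.8): (51.74, 99.56),
    ("individual", 840, "uneq", 0.2): (85.94, 87.12),
    ("individual", 840, "uneq", 0.8): (86.06, 99.98),
    ("individual", 840, "eq", 0.2): (85.07, 87.15),
    ("individual", 840, "eq", 0.8): (86.40, 100.00),
}

TABLE6_EXPECTED = {
    ("cluster", 360, "uneq", 0.2): (44.05, 45.17),
    ("cluster", 360, "uneq", 0.8): (31.43, 37.86),
    ("cluster", 360, "eq", 0.2): (38.79, 39.54),
    ("cluster", 360, "eq", 0.8): (23.20, 26.09),
    ("cluster", 840, "uneq", 0.2): (79.15, 80.38),
    ("cluster", 840, "uneq", 0.8): (61.82, 71.50),
    ("cluster", 840, "eq", 0.2): (72.75, 73.73),
    ("cluster", 840, "eq", 0.8): (46.77, 52.39),
    ("individual", 360, "uneq", 0.2): (50.95, 52.34),
    ("individual", 360, "uneq", 0.8): (50.93, 84.18),
    ("individual", 360, "eq", 0.2): (50.94, 53.57),
    ("individual", 360, "eq", 0.8): (50.89, 94.52),
    ("individual", 840, "uneq", 0.2): (85.93, 87.08),
    ("individual", 840, "uneq", 0.8): (85.91, 99.49),
    ("individual", 840, "eq", 0.2): (85.92, 88.05),
    ("individual", 840, "eq", 0.8): (85.88, 99.98),
}

# cells where the published observed-vs-expected power gap is itself large
# (3.6-6.5 points): individual randomisation, exchangeable GEE, high ICC,
# smaller N.  Value: sign of the published observed - expected gap.
DEVIANT_POWER_CELLS = {
    ("continuous", "individual", 240, "uneq", 0.8, "exchangeable"): -1,
    ("binary", "individual", 360, "uneq", 0.8, "exchangeable"): +1,
    ("binary", "individual", 360, "eq", 0.8, "exchangeable"): +1,
}
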