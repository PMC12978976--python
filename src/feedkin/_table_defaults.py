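"""Default study-scale parameters for the synthetic-trial generator.

Group medians reported for healthy right-handed adults eating solid food
with chopsticks versus semisolid food with a spoon parameterize the
generator so synthetic cohorts sit at a realistic scale: per-phase joint
angle levels (degrees), phase durations (seconds), reach-pause prevalence,
transport path-efficiency ratios and movement-unit counts. Every value is
overridable through :class:`feedkin.simulate.SimConfig`.

Angle entries are ``(max_chopsticks, max_spoon, min_chopsticks, min_spoon)``
per phase (Re, Ta, Tr, Mo).
"""

# degrees; phase -> (max_chop, max_spoon, min_chop, min_spoon)
ANGLE_MEDIANS_DEG = {
    "male": {
        "shoulder_flexion": {
            "Re": (23, 36, 16, 19), "Ta": (21, 23, 19, 22),
            "Tr": (25, 36, 18, 23), "Mo": (25, 41, 23, 36)},
        "shoulder_abduction": {
            "Re": (32, 38, 24, 28), "Ta": (30, 31, 30, 30),
            "Tr": (32, 37, 28, 31), "Mo": (32, 38, 31, 36)},
        "shoulder_internal_rotation": {
            "Re": (0, 2, -12, -7), "Ta": (-1, 4, -4, 1),
            "Tr": (-3, 4, -8, 1), "Mo": (-5, 6, -8, 1)},
        "elbow_flexion": {
            "Re": (125, 121, 97, 100), "Ta": (102, 105, 99, 98),
            "Tr": (126, 120, 101, 99), "Mo": (131, 127, 125, 119)},
        "forearm_pronation": {
            "Re": (90, 99, 26, 34), "Ta": (90, 99, 77, 75),
            "Tr": (78, 74, 31, 32), "Mo": (31, 34, 22, 24)},
        "wrist_dorsiflexion": {
            "Re": (26, 29, 13, 20), "Ta": (22, 28, 16, 21),
            "Tr": (26, 27, 19, 20), "Mo": (22, 23, 20, 20)},
        "wrist_ulnar_deviation": {
            "Re": (5, 11, -7, -5), "Ta": (1, 7, -2, -4),
            "Tr": (3, 12, -1, 5), "Mo": (2, 13, 1, 10)},
        "neck_flexion": {
            "Re": (27, 26, 19, 21), "Ta": (26, 25, 25, 24),
            "Tr": (25, 25, 21, 20), "Mo": (22, 22, 21, 18)},
        "neck_right_lateral_flexion": {
            "Re": (-1, 3, -4, -2), "Ta": (-3, -2, -3, -2),
            "Tr": (-2, 2, -3, -2), "Mo": (-2, 4, -3, 2)},
        "neck_right_rotation": {
            "Re": (4, 2, 0, 0), "Ta": (1, 1, 1, 1),
            "Tr": (4, 3, 1, 1), "Mo": (5, 3, 4, 2)},
        "hip_flexion": {
            "Re": (51, 50, 43, 44), "Ta": (44, 46, 44, 45),
            "Tr": (50, 50, 44, 46), "Mo": (51, 51, 50, 51)},
    },
    "female": {
        "shoulder_flexion": {
            "Re": (20, 37, 10, 10), "Ta": (14, 15, 14, 13),
            "Tr": (21, 37, 13, 14), "Mo": (22, 40, 20, 37)},
        "shoulder_abduction": {
            "Re": (31, 37, 21, 23), "Ta": (24, 28, 23, 28),
            "Tr": (30, 38, 24, 28), "Mo": (29, 39, 28, 36)},
        "shoulder_internal_rotation": {
            "Re": (3, 13, -5, 5), "Ta": (3, 11, 1, 9),
            "Tr": (3, 13, -1, 7), "Mo": (4, 15, 0, 13)},
        "elbow_flexion": {
            "Re": (135, 128, 106, 103), "Ta": (106, 103, 103, 97),
            "Tr": (134, 128, 104, 97), "Mo": (138, 131, 134, 127)},
        "forearm_pronation": {
            "Re": (102, 109, 17, 32), "Ta": (102, 111, 93, 80),
            "Tr": (93, 80, 26, 29), "Mo": (26, 31, 17, 27)},
        "wrist_dorsiflexion": {
            "Re": (22, 34, 9, 20), "Ta": (23, 31, 18, 23),
            "Tr": (25, 31, 17, 23), "Mo": (18, 25, 17, 22)},
        "wrist_ulnar_deviation": {
            "Re": (12, 14, 4, -1), "Ta": (10, 10, 6, -3),
            "Tr": (12, 15, 9, 10), "Mo": (10, 15, 9, 12)},
        "neck_flexion": {
            "Re": (27, 27, 19, 18), "Ta": (27, 27, 26, 26),
            "Tr": (26, 27, 18, 17), "Mo": (20, 20, 18, 14)},
        "neck_right_lateral_flexion": {
            "Re": (2, 3, -2, -1), "Ta": (-1, 0, -2, -1),
            "Tr": (2, 3, -1, 0), "Mo": (1, 4, 1, 2)},
        "neck_right_rotation": {
            "Re": (3, 3, 0, 0), "Ta": (1, 0, 0, 0),
            "Tr": (3, 3, 1, 0), "Mo": (4, 5, 3, 3)},
        "hip_flexion": {
            "Re": (52, 52, 44, 45), "Ta": (45, 45, 44, 44),
            "Tr": (53, 49, 45, 44), "Mo": (54, 53, 53, 49)},
    },
}

# seconds; (sex, condition) -> phase -> median movement time
PHASE_DURATION_MEDIANS_S = {
    ("male", "chopsticks"): {"Re": 4.9, "Ta": 1.0, "Tr": 0.8, "Mo": 0.4},
    ("male", "spoon"): {"Re": 2.9, "Ta": 1.0, "Tr": 0.9, "Mo": 0.7},
    ("female", "chopsticks"): {"Re": 4.8, "Ta": 1.1, "Tr": 0.9, "Mo": 0.5},
    ("female", "spoon"): {"Re": 2.8, "Ta": 1.5, "Tr": 1.1, "Mo": 0.9},
}

# probability of a pause during the reaching phase
PAUSE_PROBABILITY = {"chopsticks": 0.84, "spoon": 0.65}

# transporting-phase relative distance (path / straight line) medians
DETOUR_RATIO = {
    ("male", "chopsticks"): 1.17, ("male", "spoon"): 1.07,
    ("female", "chopsticks"): 1.15, ("female", "spoon"): 1.05,
}

# transporting-phase movement-unit count medians (commanded submovements)
MOVEMENT_UNIT_MEDIANS = {
    ("male", "chopsticks"): 5, ("male", "spoon"): 4,
    ("female", "chopsticks"): 5, ("female", "spoon"): 6,
}
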