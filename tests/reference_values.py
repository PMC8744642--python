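"""Published reference values from a DUD-E five-target screening study.

Used as consistency fixtures for the metric implementations: the printed
enrichment factors must back-calculate to integer active counts under the
EF = (a / A) / f definition, and the printed top-L percentages must equal
the half-up rounding of count / total.

``TOPL_TOTALS`` holds (train, validation, test) active counts per target.
For ACES the published composition table transposes the validation and
test active counts (106/107); the percentage table only back-calculates
with 107 validation / 106 test actives, which is what is recorded here.
"""

# test-set active counts (A) per target
TEST_ACTIVES = {"ACES": 107, "HIVPR": 227, "MK14": 152, "UROK": 49, "TRY1": 126}

# EF_1% values for all four test subsets; per subset six ranking methods
# (three model sizes of the enrichment-optimized models, then three docking
# programs under two-structure best-score consensus)
EF1_CELLS = {
    "ACES": [
        36.449, 26.168, 58.879, 10.280, 30.841, 14.953,
        8.411, 43.925, 9.346, 12.150, 28.972, 14.019,
        42.991, 7.477, 21.495, 10.280, 27.103, 14.953,
        14.019, 58.879, 13.084, 8.411, 28.972, 10.280,
    ],
    "HIVPR": [
        3.965, 20.705, 59.471, 7.048, 13.656, 11.454,
        14.097, 21.586, 19.383, 3.965, 12.335, 8.370,
        9.692, 34.802, 31.718, 7.048, 17.621, 10.132,
        16.300, 13.656, 51.542, 5.727, 13.656, 12.335,
    ],
    "MK14": [
        40.132, 39.474, 25.658, 10.526, 12.500, 15.789,
        20.395, 41.447, 37.500, 8.553, 9.868, 18.421,
        25.000, 23.684, 27.632, 9.868, 9.868, 23.026,
        21.711, 23.026, 36.184, 5.921, 7.895, 16.447,
    ],
    "UROK": [
        77.551, 81.633, 81.633, 4.082, 32.653, 40.816,
        69.388, 81.633, 73.469, 2.041, 28.571, 36.735,
        79.592, 75.510, 89.796, 6.122, 34.694, 42.857,
        61.224, 67.347, 79.592, 6.122, 26.531, 40.816,
    ],
    "TRY1": [
        73.810, 80.159, 58.730, 4.762, 15.873, 35.714,
        75.397, 79.365, 71.429, 4.762, 23.810, 42.857,
        76.984, 79.365, 73.016, 3.968, 26.190, 44.444,
        80.159, 76.190, 79.365, 7.143, 25.397, 46.825,
    ],
}

# (train, validation, test) active totals per target
TOPL_TOTALS = {
    "ACES": (430, 107, 106),
    "HIVPR": (912, 227, 227),
    "MK14": (608, 151, 152),
    "UROK": (200, 49, 49),
    "TRY1": (504, 125, 126),
}

# per target: four subsets x three model sizes, each entry
# ((train_count, val_count, test_count), (train_%, val_%, test_%))
TOPL_CELLS = {
    "ACES": [
        ((324, 75, 15), (75, 70, 14)),
        ((315, 72, 28), (73, 67, 26)),
        ((343, 84, 49), (80, 79, 46)),
        ((312, 68, 42), (73, 64, 40)),
        ((326, 72, 38), (76, 67, 36)),
        ((357, 79, 0), (83, 74, 0)),
        ((322, 78, 38), (75, 73, 36)),
        ((319, 74, 13), (74, 69, 12)),
        ((323, 69, 20), (75, 64, 19)),
        ((331, 73, 47), (77, 68, 44)),
        ((326, 73, 56), (76, 68, 53)),
        ((329, 75, 5), (77, 70, 5)),
    ],
    "HIVPR": [
        ((766, 187, 66), (84, 82, 29)),
        ((806, 204, 49), (88, 90, 22)),
        ((831, 202, 127), (91, 89, 56)),
        ((742, 182, 75), (81, 80, 33)),
        ((830, 201, 91), (91, 89, 40)),
        ((801, 196, 38), (88, 86, 17)),
        ((750, 192, 66), (82, 85, 29)),
        ((800, 200, 73), (88, 88, 32)),
        ((837, 206, 124), (92, 91, 55)),
        ((759, 182, 61), (83, 80, 27)),
        ((804, 197, 65), (88, 87, 29)),
        ((807, 198, 94), (88, 87, 41)),
    ],
    "MK14": [
        ((455, 111, 41), (75, 74, 27)),
        ((477, 116, 40), (78, 77, 26)),
        ((464, 110, 37), (76, 73, 24)),
        ((469, 106, 29), (77, 70, 19)),
        ((471, 111, 42), (77, 74, 28)),
        ((491, 111, 49), (81, 74, 32)),
        ((421, 114, 43), (69, 75, 28)),
        ((472, 125, 41), (78, 83, 27)),
        ((482, 122, 48), (79, 81, 32)),
        ((440, 103, 27), (72, 68, 18)),
        ((466, 107, 34), (77, 71, 22)),
        ((470, 109, 39), (77, 72, 26)),
    ],
    "UROK": [
        ((192, 46, 29), (96, 94, 59)),
        ((193, 48, 30), (97, 98, 61)),
        ((191, 47, 34), (96, 96, 69)),
        ((194, 47, 22), (97, 96, 45)),
        ((193, 47, 30), (97, 96, 61)),
        ((195, 46, 29), (98, 94, 59)),
        ((192, 46, 27), (96, 94, 55)),
        ((180, 42, 25), (90, 86, 51)),
        ((193, 47, 34), (97, 96, 69)),
        ((194, 46, 21), (97, 94, 43)),
        ((195, 46, 25), (98, 94, 51)),
        ((194, 46, 33), (97, 94, 67)),
    ],
    "TRY1": [
        ((445, 100, 75), (88, 80, 60)),
        ((460, 109, 81), (91, 87, 64)),
        ((438, 105, 55), (87, 84, 44)),
        ((449, 116, 74), (89, 93, 59)),
        ((465, 111, 84), (92, 89, 67)),
        ((456, 114, 71), (90, 91, 56)),
        ((463, 113, 83), (92, 90, 66)),
        ((465, 113, 86), (92, 90, 68)),
        ((461, 110, 77), (91, 88, 61)),
        ((455, 111, 87), (90, 89, 69)),
        ((453, 105, 79), (90, 84, 63)),
        ((464, 110, 79), (92, 88, 63)),
    ],
}

# trainval (actives, decoys) and expected (train, validation) per class
SPLIT_COMPOSITIONS = {
    "ACES": {"actives": (537, 430, 107), "decoys": (4165, 3333, 832), "test": (106, 19996)},
    "HIVPR": {"actives": (1139, 912, 227), "decoys": (4165, 3333, 832), "test": (227, 30906)},
    "MK14": {"actives": (759, 608, 151), "decoys": (4165, 3333, 832), "test": (152, 30731)},
    "UROK": {"actives": (249, 200, 49), "decoys": (2082, 1666, 416), "test": (49, 7180)},
    "TRY1": {"actives": (629, 504, 125), "decoys": (4165, 3333, 832), "test": (126, 20595)},
}
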