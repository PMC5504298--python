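"""Reference benchmark values from a published five-subject pedaling-intent study.

These numbers are inputs for cross-checking the WD arithmetic, the
averaging and the selection procedures against a real dataset's printed
results; they were not produced by this package.  ``OFFLINE_WD_4S`` holds
each subject's offline WD grid (8 electrode configurations x algorithms
A-E, 4 s windows); ``PSEUDO_WD_BEST_TWO`` the pseudo-online grids for
each subject's best two algorithms; ``OFFLINE_BEST`` / ``PSEUDO_BEST``
the best-model metric rows (TPR %, FP/min, Acc %).
"""

from __future__ import annotations

import pandas as pd

from .selection import WDMatrix

_CONFIG_IDS = list(range(1, 9))


def _grid(columns: list[str], rows: list[list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=_CONFIG_IDS, columns=columns, dtype=float)


#: Offline WD grids, 4 s processing windows (configurations 1-8 x A-E).
OFFLINE_WD_4S: dict[str, pd.DataFrame] = {
    "S1": _grid(
        ["A", "B", "C", "D", "E"],
        [
            [0.28, 0.16, 0.60, 0.51, 0.27],
            [0.32, 0.02, 0.41, 0.53, 0.47],
            [0.17, 0.27, 0.61, 0.50, 0.39],
            [0.22, -0.05, 0.61, 0.68, 0.57],
            [0.10, 0.07, 0.50, 0.33, 0.35],
            [0.18, 0.07, 0.28, 0.43, -0.01],
            [0.14, 0.12, 0.33, 0.38, 0.13],
            [0.24, -0.12, 0.56, 0.52, 0.36],
        ],
    ),
    "S2": _grid(
        ["A", "B", "C", "D", "E"],
        [
            [0.36, 0.68, 0.62, 0.74, 0.72],
            [0.07, 0.59, 0.39, 0.70, 0.70],
            [0.27, 0.71, 0.57, 0.69, 0.67],
            [0.32, 0.48, 0.25, 0.64, 0.71],
            [0.28, 0.68, 0.64, 0.76, 0.74],
            [-0.16, 0.56, 0.58, 0.74, 0.75],
            [0.27, 0.66, 0.57, 0.72, 0.76],
            [0.29, 0.68, 0.56, 0.75, 0.76],
        ],
    ),
    "S3": _grid(
        ["A", "B", "C", "D", "E"],
        [
            [0.47, 0.20, 0.51, 0.61, 0.41],
            [0.30, -0.12, 0.51, 0.57, 0.40],
            [0.36, 0.13, 0.57, 0.52, 0.41],
            [0.30, 0.11, 0.57, 0.55, 0.50],
            [0.31, 0.32, 0.58, 0.46, 0.46],
            [0.28, 0.07, 0.58, 0.59, 0.27],
            [0.21, 0.06, 0.44, 0.57, 0.35],
            [0.29, 0.11, 0.53, 0.57, 0.44],
        ],
    ),
    "S4": _grid(
        ["A", "B", "C", "D", "E"],
        [
            [0.35, 0.22, 0.60, 0.61, 0.50],
            [-0.01, 0.16, 0.41, 0.48, 0.22],
            [0.25, 0.27, 0.61, 0.59, 0.53],
            [0.14, -0.12, 0.61, 0.50, 0.30],
            [0.16, 0.21, 0.50, 0.53, 0.38],
            [0.10, 0.19, 0.28, 0.57, 0.33],
            [0.21, 0.12, 0.33, 0.57, 0.49],
            [0.14, 0.21, 0.36, 0.61, 0.40],
        ],
    ),
    "S5": _grid(
        ["A", "B", "C", "D", "E"],
        [
            [0.59, 0.25, 0.58, 0.54, 0.52],
            [0.53, 0.15, 0.32, 0.56, 0.40],
            [0.43, 0.16, 0.33, 0.53, 0.31],
            [0.48, 0.23, 0.10, 0.24, 0.31],
            [0.49, 0.11, 0.32, 0.47, 0.42],
            [0.42, 0.28, 0.45, 0.50, 0.46],
            [0.54, 0.09, 0.55, 0.53, 0.37],
            [0.50, 0.32, 0.47, 0.55, 0.41],
        ],
    ),
}

#: Printed E.C.-averaged WD rows for the offline 4 s grids.
OFFLINE_AVG_4S: dict[str, dict[str, float]] = {
    "S1": {"A": 0.21, "B": 0.07, "C": 0.49, "D": 0.48, "E": 0.32},
    "S2": {"A": 0.21, "B": 0.63, "C": 0.52, "D": 0.72, "E": 0.73},
    "S3": {"A": 0.32, "B": 0.11, "C": 0.54, "D": 0.56, "E": 0.41},
    "S4": {"A": 0.17, "B": 0.16, "C": 0.46, "D": 0.56, "E": 0.39},
    "S5": {"A": 0.50, "B": 0.20, "C": 0.39, "D": 0.49, "E": 0.40},
}

#: Pseudo-online WD grids (4 s windows) for each subject's best two algorithms.
PSEUDO_WD_BEST_TWO: dict[str, pd.DataFrame] = {
    "S1": _grid(
        ["C", "D"],
        [[0.24, -0.04], [0.22, 0.18], [0.30, 0.15], [0.29, 0.31],
         [0.22, 0.11], [0.16, 0.27], [0.17, 0.14], [0.23, 0.06]],
    ),
    "S2": _grid(
        ["B", "E"],
        [[0.81, 0.81], [0.69, 0.77], [0.61, 0.84], [0.53, 0.85],
         [0.60, 0.82], [0.73, 0.77], [0.86, 0.84], [0.89, 0.76]],
    ),
    "S3": _grid(
        ["C", "D"],
        [[0.42, 0.37], [0.33, 0.43], [0.41, 0.29], [0.38, 0.38],
         [0.36, 0.29], [0.37, 0.33], [0.28, 0.31], [0.35, 0.35]],
    ),
    "S4": _grid(
        ["C", "D"],
        [[0.74, 0.47], [0.74, 0.48], [0.67, 0.51], [0.67, 0.38],
         [0.67, 0.38], [0.68, 0.57], [0.71, 0.58], [0.70, 0.57]],
    ),
    "S5": _grid(
        ["A", "E"],
        [[0.34, 0.36], [0.35, 0.42], [0.32, 0.24], [0.23, 0.42],
         [0.35, 0.27], [0.35, 0.23], [0.29, 0.24], [0.28, 0.32]],
    ),
}

#: Best offline models (4 s windows): algorithm, E.C., TPR %, FP/min, Acc %.
OFFLINE_BEST: dict[str, dict] = {
    "S1": {"algorithm": "D", "config": 4, "tpr_pct": 63.8, "fp_per_min": 1.69, "acc_pct": 89.1},
    "S2": {"algorithm": "E", "config": 6, "tpr_pct": 50.0, "fp_per_min": 0.19, "acc_pct": 93.8},
    "S3": {"algorithm": "D", "config": 1, "tpr_pct": 71.3, "fp_per_min": 2.25, "acc_pct": 78.6},
    "S4": {"algorithm": "C", "config": 3, "tpr_pct": 67.5, "fp_per_min": 2.44, "acc_pct": 83.7},
    "S5": {"algorithm": "A", "config": 1, "tpr_pct": 82.5, "fp_per_min": 3.56, "acc_pct": 82.8},
}

#: Printed column averages of the best offline models.
OFFLINE_BEST_AVG = {"tpr_pct": 67.0, "fp_per_min": 2.03, "acc_pct": 85.6}

#: Best pseudo-online models (4 s windows).
PSEUDO_BEST: dict[str, dict] = {
    "S1": {"algorithm": "D", "config": 4, "tpr_pct": 83.3, "fp_per_min": 10.3, "acc_pct": 25.1},
    "S2": {"algorithm": "B", "config": 8, "tpr_pct": 76.7, "fp_per_min": 0.08, "acc_pct": 96.7},
    "S3": {"algorithm": "D", "config": 2, "tpr_pct": 86.7, "fp_per_min": 6.83, "acc_pct": 32.1},
    "S4": {"algorithm": "C", "config": 2, "tpr_pct": 76.7, "fp_per_min": 3.74, "acc_pct": 81.8},
    "S5": {"algorithm": "E", "config": 4, "tpr_pct": 60.0, "fp_per_min": 3.73, "acc_pct": 39.9},
}

#: Printed column averages of the best pseudo-online models.
PSEUDO_BEST_AVG = {"tpr_pct": 76.7, "fp_per_min": 4.94, "acc_pct": 55.1}

#: Starred WD values of the best models (2 d.p.), per analysis mode.
BEST_WD = {
    "offline": {"S1": 0.68, "S2": 0.75, "S3": 0.61, "S4": 0.61, "S5": 0.59},
    "pseudo-online": {"S1": 0.31, "S2": 0.89, "S3": 0.43, "S4": 0.74, "S5": 0.42},
}


def offline_matrix(subject: str) -> WDMatrix:
    """The subject's offline 4 s grid as a :class:`WDMatrix`."""
    return WDMatrix(subject, "offline", "4s", OFFLINE_WD_4S[subject])


def pseudo_online_matrix(subject: str) -> WDMatrix:
    """The subject's pseudo-online best-two-algorithm grid."""
    return WDMatrix(subject, "pseudo-online", "4s", PSEUDO_WD_BEST_TWO[subject])
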