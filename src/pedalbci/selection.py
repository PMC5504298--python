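"""WD-based model selection: personalized and uniform picks, paired comparison.

The personalized procedure, per subject and analysis mode:

1. rank algorithms by their WD averaged over the eight electrode
   configurations and keep the best two;
2. among the 16 remaining cells, preselect the maximum WD together with
   every cell within 0.01 of it;
3. choose the preselected cell with the fewest electrodes; break ties by
   the higher WD, then uniformly at random.

The uniform procedures average the E.C.-averaged WD (for the algorithm)
or the per-configuration WD of the chosen algorithm (for the
configuration) across subjects and take the argmax.  Personalized and
uniform models are compared with a two-sided Wilcoxon signed-rank test on
per-test-trial WD pairs (exact null distribution for n <= 25, normal
approximation above; zero differences dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .montage import DEFAULT_CONFIG_SIZES

#: Preselection tolerance below the maximum WD.
SELECTION_TOL = 0.01


@dataclass
class WDMatrix:
    """Per-subject WD grid: rows = configuration ids, columns = algorithms."""

    subject_id: str
    mode: str
    window_type: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if self.values.isna().any().any():
            raise ValidationError("WD matrix must be complete (no missing cells)")

    @property
    def config_ids(self) -> list[int]:
        return [int(i) for i in self.values.index]

    @property
    def algorithms(self) -> list[str]:
        return [str(c) for c in self.values.columns]


@dataclass
class SelectionResult:
    """Chosen (algorithm, configuration) with an audit trail."""

    algorithm: str
    config_id: int
    wd: float
    best_two_algorithms: list[str] = field(default_factory=list)
    preselected: list[tuple[int, str, float]] = field(default_factory=list)
    tie_broken_randomly: bool = False


def ec_averaged_wd(matrix: WDMatrix) -> pd.Series:
    """Mean WD of each algorithm across the electrode configurations."""
    return matrix.values.mean(axis=0)


def _preselect(
    cells: list[tuple[int, str, float]], tol: float
) -> list[tuple[int, str, float]]:
    best = max(c[2] for c in cells)
    return [c for c in cells if c[2] >= best - tol]


def _pick_minimal(
    preselected: list[tuple[int, str, float]],
    config_sizes: dict[int, int],
    rng: np.random.Generator | None,
) -> tuple[tuple[int, str, float], bool]:
    missing = [cid for cid, _, _ in preselected if cid not in config_sizes]
    if missing:
        raise ValidationError(f"no electrode count for configuration(s) {sorted(set(missing))}")
    min_size = min(config_sizes[cid] for cid, _, _ in preselected)
    smallest = [c for c in preselected if config_sizes[c[0]] == min_size]
    best_wd = max(c[2] for c in smallest)
    finalists = [c for c in smallest if c[2] == best_wd]
    if len(finalists) == 1:
        return finalists[0], False
    rng = rng if rng is not None else np.random.default_rng(0)
    return finalists[int(rng.integers(len(finalists)))], True


def select_personalized(
    matrix: WDMatrix,
    config_sizes: dict[int, int] | None = None,
    tol: float = SELECTION_TOL,
    rng: np.random.Generator | None = None,
    algorithms: list[str] | None = None,
) -> SelectionResult:
    """Personalized best (algorithm, configuration) for one subject.

    ``algorithms`` overrides step 1 (useful when the matrix only carries a
    subject's best-two columns); otherwise the best two algorithms by
    E.C.-averaged WD are used.  Comparisons use unrounded WD values.
    """
    sizes = config_sizes if config_sizes is not None else DEFAULT_CONFIG_SIZES
    if algorithms is None:
        avgs = ec_averaged_wd(matrix)
        algorithms = list(avgs.sort_values(ascending=False).index[:2])
    cells = [
        (int(cid), alg, float(matrix.values.loc[cid, alg]))
        for alg in algorithms
        for cid in matrix.values.index
    ]
    preselected = _preselect(cells, tol)
    chosen, random_tie = _pick_minimal(preselected, sizes, rng)
    return SelectionResult(
        algorithm=chosen[1],
        config_id=chosen[0],
        wd=chosen[2],
        best_two_algorithms=list(algorithms),
        preselected=preselected,
        tie_broken_randomly=random_tie,
    )


def select_uniform_algorithm(matrices: list[WDMatrix]) -> str:
    """Algorithm with the highest subject-averaged E.C.-averaged WD.

    Ties resolve to the first algorithm in column order.
    """
    if not matrices:
        raise ValidationError("at least one WD matrix required")
    avg = pd.concat([ec_averaged_wd(m) for m in matrices], axis=1).mean(axis=1)
    return str(avg.idxmax())


def select_uniform_configuration(matrices: list[WDMatrix], algorithm: str) -> int:
    """Configuration with the highest subject-averaged WD in one algorithm's column.

    Ties resolve to the lowest configuration id.
    """
    if not matrices:
        raise ValidationError("at least one WD matrix required")
    cols = []
    for m in matrices:
        if algorithm not in m.values.columns:
            raise ValidationError(f"matrix of {m.subject_id} lacks algorithm {algorithm}")
        cols.append(m.values[algorithm])
    avg = pd.concat(cols, axis=1).mean(axis=1)
    return int(avg.idxmax())


def select_uniform_configuration_personalized(
    matrix: WDMatrix,
    algorithm: str,
    config_sizes: dict[int, int] | None = None,
    tol: float = SELECTION_TOL,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Per-subject best configuration for a fixed (uniform) algorithm.

    Same preselection/tie-break rules as the personalized procedure but
    restricted to one algorithm column.
    """
    return select_personalized(matrix, config_sizes, tol, rng, algorithms=[algorithm])


def compare_paired_wd(wd_a: list[float], wd_b: list[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-trial WD samples.

    Zero differences are dropped (Wilcoxon's convention); identical
    samples return p = 1.  Exact null distribution for n <= 25 retained
    pairs, normal approximation above.
    """
    a = np.asarray(wd_a, dtype=float)
    b = np.asarray(wd_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    if a.size < 5:
        raise ValidationError("at least 5 pairs required")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 0.0, 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)
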