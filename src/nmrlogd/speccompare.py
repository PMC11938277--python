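"""Assignment-free comparison of computed vs experimental shift lists.

Computed and experimental ¹H shift lists are compared without assigning
individual signals to nuclei: both lists are sorted and paired rank by
rank, and the root-mean-square error over the pairs measures overall
agreement.  This mirrors how an ML featurizer reads a spectrum — by the
order in which signals appear, not by structural assignment — and it is
the statistic used to benchmark spectrum-generation methods (e.g. DFT
functional/basis-set combinations) against experimental references.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemio import DataError, ShiftList

logger = logging.getLogger("nmrlogd")


def ordered_rmse(calc: ShiftList, exp: ShiftList) -> float:
    """RMSE between two shift lists paired by rank (descending ppm).

    Both lists are sorted high-to-low and the i-th calculated shift is
    compared with the i-th experimental one; no per-nucleus matching is
    attempted.  The result is symmetric, invariant to input order, and
    zero iff the sorted lists coincide.  Lists must have equal length
    (one shift per hydrogen on both sides).
    """
    a = np.asarray(calc.shifts, dtype=float)
    b = np.asarray(exp.shifts, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("ordered_rmse requires non-empty shift lists")
    if len(a) != len(b):
        raise DataError(
            f"shift count mismatch: {calc.compound_id} has {len(a)}, "
            f"{exp.compound_id} has {len(b)}")
    a = np.sort(a)[::-1]
    b = np.sort(b)[::-1]
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class ComparisonGrid:
    """Per-molecule RMSE of every method against the reference."""

    cells: pd.DataFrame            # rows = method labels, columns = molecule ids
    solvent_of: dict[str, str]     # molecule id -> solvent tag
    mean_rmse: pd.DataFrame = field(init=False)   # method × solvent means
    ranks: pd.DataFrame = field(init=False)       # per-solvent ranks + combined

    def __post_init__(self) -> None:
        solvents = sorted(set(self.solvent_of.values()))
        means = {}
        for solv in solvents:
            cols = [m for m, s in self.solvent_of.items() if s == solv]
            means[solv] = self.cells[cols].mean(axis=1)
        self.mean_rmse = pd.DataFrame(means)
        # rank 1 = lowest mean RMSE; ties share the minimum rank
        ranks = self.mean_rmse.rank(axis=0, method="min")
        ranks["combined"] = ranks.sum(axis=1)
        self.ranks = ranks

    def to_csv(self, path: str) -> None:
        self.cells.to_csv(path)


def benchmark_methods(methods: dict[str, dict[str, ShiftList]],
                      reference: dict[str, ShiftList],
                      solvent_of: dict[str, str] | None = None) -> ComparisonGrid:
    """Grid of per-molecule ordered RMSEs plus per-solvent method ranking.

    ``methods`` maps a method label (functional+basis set, predictor name,
    ...) to its shift lists keyed by molecule id; ``reference`` holds the
    experimental lists.  Every method must cover every reference molecule.
    Per-method mean RMSEs are computed per solvent group, ranked, and the
    per-solvent ranks summed into a combined performance score (lower is
    better).
    """
    if solvent_of is None:
        solvent_of = {mid: "all" for mid in reference}
    mol_ids = sorted(reference)
    rows = {}
    for label, shift_sets in methods.items():
        missing = [m for m in mol_ids if m not in shift_sets]
        if missing:
            raise DataError(f"method {label!r} missing molecules {missing}")
        rows[label] = [ordered_rmse(shift_sets[m], reference[m]) for m in mol_ids]
    cells = pd.DataFrame.from_dict(rows, orient="index", columns=mol_ids)
    return ComparisonGrid(cells=cells, solvent_of={m: solvent_of[m] for m in mol_ids})


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-molecule errors.

    Degenerate pairing (zero variance of the differences) cannot support
    the test; it returns p = 1 with a warning, and t = 0 when the lists
    are identical (±inf for a constant nonzero difference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise DataError(f"paired_t: length mismatch {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise DataError("paired_t needs at least 2 pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        logger.warning("paired_t: zero variance of paired differences")
        mean = diff.mean()
        t = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        return t, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
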