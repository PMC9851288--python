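"""Simplified expression-pattern classification across ordered conditions.

Each feature's trajectory of condition means is reduced to a string over
{U, D, S}: per consecutive condition pair, U (up) if the log2 ratio of means
exceeds a threshold, D (down) if it falls below the negative threshold, S
(straight) otherwise.  Grouping features by identical strings surfaces
candidate co-regulated programmes without any model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, MatrixIOError, MetadataTable

__all__ = ["PatternAssignment", "classify_patterns", "pattern_summary"]


@dataclass
class PatternAssignment:
    condition_order: list[str]
    assignments: pd.Series              # feature -> pattern string
    condition_means: pd.DataFrame       # feature x condition
    transition_threshold: float
    pseudocount: float

    @property
    def groups(self) -> dict[str, list[str]]:
        """Pattern -> member feature ids."""
        out: dict[str, list[str]] = {}
        for fid, pat in self.assignments.items():
            out.setdefault(pat, []).append(fid)
        return out

    def mean_trajectory(self, pattern: str) -> pd.Series:
        members = self.groups.get(pattern)
        if not members:
            raise MatrixIOError(f"no features with pattern {pattern!r}")
        return self.condition_means.loc[members].mean(axis=0)


def classify_patterns(
    m: ExpressionMatrix,
    meta: MetadataTable,
    factor: str,
    ordered_levels: list[str],
    transition_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> PatternAssignment:
    """Label each consecutive condition transition U/D/S on log2 mean ratios.

    The ratio uses a pseudo-count (default 1) so zero-mean conditions are
    well defined.  ``transition_threshold`` is in log2 units; an infinite
    threshold maps everything to S.
    """
    if len(ordered_levels) < 2:
        raise MatrixIOError("need at least 2 ordered levels")
    if not transition_threshold > 0:
        raise MatrixIOError("transition_threshold must be > 0")
    meta = meta.harmonise(m)
    means = {}
    for lvl in ordered_levels:
        ss = meta.samples_for(factor, lvl)
        if not ss:
            raise MatrixIOError(f"level {lvl!r} not present in factor {factor!r}")
        means[lvl] = m.data[ss].mean(axis=1)
    cm = pd.DataFrame(means)[ordered_levels]

    vals = cm.to_numpy(dtype=float) + pseudocount
    ratios = np.log2(vals[:, 1:] / vals[:, :-1])
    codes = np.where(ratios > transition_threshold, "U",
                     np.where(ratios < -transition_threshold, "D", "S"))
    patterns = pd.Series(["".join(row) for row in codes], index=cm.index, name="pattern")
    return PatternAssignment(
        condition_order=list(ordered_levels),
        assignments=patterns,
        condition_means=cm,
        transition_threshold=transition_threshold,
        pseudocount=pseudocount,
    )


def pattern_summary(pa: PatternAssignment) -> pd.DataFrame:
    """Per-pattern count and fraction, sorted by count desc then pattern."""
    counts = pa.assignments.value_counts()
    df = pd.DataFrame({"pattern": counts.index, "count": counts.to_numpy()})
    df["fraction"] = df["count"] / df["count"].sum()
    df = df.sort_values(["count", "pattern"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
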