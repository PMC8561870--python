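"""Fiber-type distribution patterns of ANOVA-significant proteins.

Each FDR-significant protein is assigned to one of the canonical fiber-type
distribution patterns using linear-scale per-type medians, a >= 3-fold
ratio threshold and Tukey pairwise significance at 0.05:

* fiber-type specific (type 1, 2A or 2X at least 3-fold above both others),
* type 2-specific (both fast types at least 3-fold above type 1),
* type 1/2A-specific (both at least 3-fold above 2X),
* graded 1 > 2A > 2X and 2X > 2A > 1 (strict median ordering with a
  significant 1 vs 2X difference),
* MINOR for every remaining significant protein (including the atypical
  low-2A shape with type 1 and 2X both above 2A).

Rules are evaluated in a fixed precedence order (specific patterns first)
so every tested protein receives exactly one label.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix
from .fiber_typing import PURE_TYPES

__all__ = [
    "Pattern",
    "MAJOR_PATTERNS",
    "PatternCall",
    "group_medians",
    "classify_pattern",
    "classify_all",
    "tabulate_patterns",
]


class Pattern(str, enum.Enum):
    TYPE1_SPECIFIC = "type1_specific"
    TYPE2A_SPECIFIC = "type2a_specific"
    TYPE2X_SPECIFIC = "type2x_specific"
    TYPE2_SPECIFIC = "type2_specific"
    TYPE1_2A_SPECIFIC = "type1_2a_specific"
    GRAD_1_2A_2X = "grad_1_2a_2x"
    GRAD_2X_2A_1 = "grad_2x_2a_1"
    MINOR = "minor"
    NOT_SIGNIFICANT = "not_significant"
    NOT_TESTED = "not_tested"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five major patterns (the 2A-specific and 1/2A-specific shapes are
#: tabulated but not counted in ``major_total``).
MAJOR_PATTERNS = (
    Pattern.TYPE1_SPECIFIC,
    Pattern.TYPE2X_SPECIFIC,
    Pattern.TYPE2_SPECIFIC,
    Pattern.GRAD_1_2A_2X,
    Pattern.GRAD_2X_2A_1,
)


@dataclasses.dataclass(frozen=True)
class PatternCall:
    protein_id: str
    pattern: Pattern
    rule_trace: tuple[str, ...]


def group_medians(matrix: NormalizedMatrix) -> pd.DataFrame:
    """Per-type medians, percent-of-max and valid counts per protein.

    Medians are over non-missing linear-scale values; a type group with no
    valid value has an undefined (NaN) median.  ``pct_*`` scales medians so
    the largest defined one is 100.  Proteins with all three medians
    undefined are excluded with a warning.
    """
    vals = matrix.values.to_numpy(dtype=float)
    out = pd.DataFrame(index=matrix.values.index)
    counts = matrix.valid_counts()
    suffix = {PURE_TYPES[0]: "1", PURE_TYPES[1]: "2a", PURE_TYPES[2]: "2x"}
    med_cols = []
    for t in PURE_TYPES:
        mask = matrix.type_mask(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice medians
            med = np.nanmedian(vals[:, mask], axis=1) if mask.any() else np.full(len(out), np.nan)
        out[f"n_valid_{suffix[t]}"] = counts[t.value].to_numpy()
        out[f"median_{suffix[t]}"] = med
        med_cols.append(f"median_{suffix[t]}")
    med = out[med_cols].to_numpy()
    all_undef = np.isnan(med).all(axis=1)
    if all_undef.any():
        warnings.warn(
            f"excluding {int(all_undef.sum())} protein(s) with no valid values",
            stacklevel=2,
        )
        out = out.loc[~all_undef]
        med = med[~all_undef]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        top = np.nanmax(med, axis=1)
    for i, t in enumerate(PURE_TYPES):
        out[f"pct_{suffix[t]}"] = 100.0 * med[:, i] / top
    return out


def _fold_ge(
    num_median: float,
    num_n_valid: int,
    den_median: float,
    fold: float,
    min_valid_zero_denominator: int,
) -> bool:
    """num >= fold * den, with an undefined/zero denominator satisfied only
    when the numerator group has enough valid values to be trusted."""
    if np.isnan(num_median):
        return False
    if np.isnan(den_median) or den_median == 0:
        return num_n_valid >= min_valid_zero_denominator
    return bool(num_median >= fold * den_median)


def classify_pattern(
    summary: Mapping[str, float],
    diff: Mapping[str, float],
    fold_threshold: float = 3.0,
    alpha_pair: float = 0.05,
    min_valid_zero_denominator: int = 4,
) -> PatternCall:
    """Classify one protein from its group summary and differential result.

    ``summary`` needs ``median_*`` / ``n_valid_*``; ``diff`` needs
    ``tested``, ``fdr_significant`` and ``tukey_p_*``.  Rules are tried in
    precedence order (R1..R8, first match wins); the evaluated rule ids are
    recorded in the call's ``rule_trace``.
    """
    pid = str(summary.get("protein_id", diff.get("protein_id", "")))
    if not bool(diff.get("tested", False)):
        return PatternCall(pid, Pattern.NOT_TESTED, ())
    if not bool(diff.get("fdr_significant", False)):
        return PatternCall(pid, Pattern.NOT_SIGNIFICANT, ())

    m1, m2a, m2x = (float(summary[f"median_{s}"]) for s in ("1", "2a", "2x"))
    n1, n2a, n2x = (int(summary[f"n_valid_{s}"]) for s in ("1", "2a", "2x"))
    t_1_2a = float(diff["tukey_p_1_2a"])
    t_1_2x = float(diff["tukey_p_1_2x"])
    t_2a_2x = float(diff["tukey_p_2a_2x"])

    def sig(p: float) -> bool:
        return bool(p < alpha_pair)  # NaN (untested pair) compares False

    def ge(num, n_num, den) -> bool:
        return _fold_ge(num, n_num, den, fold_threshold, min_valid_zero_denominator)

    rules = [
        ("R1", Pattern.TYPE1_SPECIFIC,
         lambda: ge(m1, n1, m2a) and ge(m1, n1, m2x) and sig(t_1_2a) and sig(t_1_2x)),
        ("R2", Pattern.TYPE2A_SPECIFIC,
         lambda: ge(m2a, n2a, m1) and ge(m2a, n2a, m2x) and sig(t_1_2a) and sig(t_2a_2x)),
        ("R3", Pattern.TYPE2X_SPECIFIC,
         lambda: ge(m2x, n2x, m1) and ge(m2x, n2x, m2a) and sig(t_1_2x) and sig(t_2a_2x)),
        ("R4", Pattern.TYPE2_SPECIFIC,
         lambda: ge(m2a, n2a, m1) and ge(m2x, n2x, m1) and sig(t_1_2a) and sig(t_1_2x)),
        ("R5", Pattern.TYPE1_2A_SPECIFIC,
         lambda: ge(m1, n1, m2x) and ge(m2a, n2a, m2x) and sig(t_1_2x) and sig(t_2a_2x)),
        ("R6", Pattern.GRAD_1_2A_2X,
         lambda: (not np.isnan(m1) and not np.isnan(m2a) and not np.isnan(m2x))
                 and m1 > m2a > m2x and sig(t_1_2x)),
        ("R7", Pattern.GRAD_2X_2A_1,
         lambda: (not np.isnan(m1) and not np.isnan(m2a) and not np.isnan(m2x))
                 and m2x > m2a > m1 and sig(t_1_2x)),
    ]
    trace: list[str] = []
    for rule_id, pattern, predicate in rules:
        trace.append(rule_id)
        if predicate():
            return PatternCall(pid, pattern, tuple(trace))
    trace.append("R8")
    return PatternCall(pid, Pattern.MINOR, tuple(trace))


def classify_all(
    summaries: pd.DataFrame,
    diff: pd.DataFrame,
    fold_threshold: float = 3.0,
    alpha_pair: float = 0.05,
) -> pd.DataFrame:
    """Classify every protein present in both frames; returns pattern column.

    Proteins dropped from ``summaries`` (no valid values) are skipped.
    """
    shared = summaries.index.intersection(diff.index)
    patterns = []
    for pid in shared:
        call = classify_pattern(
            summaries.loc[pid].to_dict() | {"protein_id": pid},
            diff.loc[pid].to_dict(),
            fold_threshold=fold_threshold,
            alpha_pair=alpha_pair,
        )
        patterns.append(call.pattern.value)
    return pd.DataFrame({"pattern": patterns}, index=shared)


def tabulate_patterns(calls: Iterable[Pattern | str]) -> dict[str, int]:
    """Count proteins per pattern, plus derived totals.

    ``significant_total`` counts every FDR-significant protein;
    ``major_total`` counts the five major patterns only (type 2A-specific
    and type 1/2A-specific shapes excluded).
    """
    counts = {p.value: 0 for p in Pattern}
    for c in calls:
        counts[Pattern(c).value] += 1
    counts["major_total"] = sum(counts[p.value] for p in MAJOR_PATTERNS)
    counts["significant_total"] = sum(
        counts[p.value] for p in Pattern
        if p not in (Pattern.NOT_SIGNIFICANT, Pattern.NOT_TESTED)
    )
    return counts
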