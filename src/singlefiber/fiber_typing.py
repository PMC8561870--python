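"""MYH-based fiber typing.

Human limb muscle fibers are classified by their dominant myosin heavy chain
isoform: MYH7 marks slow type 1 fibers, MYH2 fast 2A fibers, MYH1 fast 2X
fibers.  A fiber whose dominant isoform accounts for at least 80% of the
summed unique-peptide MYH intensity is called "relatively pure"; everything
else is a hybrid fiber and is excluded from group comparisons.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Mapping, Sequence

from .io_tables import FiberSample

__all__ = [
    "FiberType",
    "PURE_TYPES",
    "MYH_GENES",
    "FiberTypeCall",
    "PurityPartition",
    "compute_myh_fractions",
    "call_fiber_type",
    "type_fibers",
    "filter_pure_fibers",
]


class FiberType(str, enum.Enum):
    """Fiber type labels; values are the short names used in tables."""

    TYPE1 = "1"
    TYPE2A = "2A"
    TYPE2X = "2X"
    HYBRID = "hybrid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Pure types in canonical order (slow to fast).
PURE_TYPES = (FiberType.TYPE1, FiberType.TYPE2A, FiberType.TYPE2X)

#: MYH isoform gene marking each pure type.
MYH_GENES: Mapping[FiberType, str] = {
    FiberType.TYPE1: "MYH7",
    FiberType.TYPE2A: "MYH2",
    FiberType.TYPE2X: "MYH1",
}


@dataclasses.dataclass(frozen=True)
class FiberTypeCall:
    fiber_id: str
    f_myh7: float
    f_myh2: float
    f_myh1: float
    call: FiberType
    purity: float  # max fraction


def compute_myh_fractions(sample: FiberSample) -> tuple[float, float, float]:
    """Fraction of each MYH isoform in the summed MYH7+MYH2+MYH1 intensity.

    Only the three adult isoforms enter the denominator; fractions sum to 1.
    Raises ``ValueError`` when the fiber has no MYH signal at all.
    """
    total = sample.myh7 + sample.myh2 + sample.myh1
    if total <= 0:
        raise ValueError(f"fiber {sample.fiber_id!r}: all MYH intensities are zero")
    return (sample.myh7 / total, sample.myh2 / total, sample.myh1 / total)


def call_fiber_type(
    fractions: Sequence[float], purity_threshold: float = 0.8
) -> tuple[FiberType, float]:
    """Assign a type from (f_myh7, f_myh2, f_myh1).

    The call is the isoform's type when its fraction reaches the purity
    threshold ("at least" = boundary inclusive), otherwise HYBRID.  Returns
    ``(call, purity)`` where purity is the maximum fraction.
    """
    if not 0.5 < purity_threshold <= 1.0:
        raise ValueError(f"purity_threshold must be in (0.5, 1], got {purity_threshold}")
    f7, f2, f1 = fractions
    purity = max(f7, f2, f1)
    if purity < purity_threshold:
        return FiberType.HYBRID, purity
    if f7 == purity:
        return FiberType.TYPE1, purity
    if f2 == purity:
        return FiberType.TYPE2A, purity
    return FiberType.TYPE2X, purity


def type_fibers(
    samples: Iterable[FiberSample], purity_threshold: float = 0.8
) -> list[FiberTypeCall]:
    """Compute fractions and type calls for every fiber."""
    calls = []
    for s in samples:
        f7, f2, f1 = compute_myh_fractions(s)
        call, purity = call_fiber_type((f7, f2, f1), purity_threshold)
        calls.append(FiberTypeCall(s.fiber_id, f7, f2, f1, call, purity))
    return calls


@dataclasses.dataclass(frozen=True)
class PurityPartition:
    """Disjoint, exhaustive split of fibers into kept pure groups + excluded."""

    kept: Mapping[FiberType, tuple[str, ...]]
    excluded: tuple[str, ...]

    @property
    def group_sizes(self) -> dict[FiberType, int]:
        return {t: len(ids) for t, ids in self.kept.items()}

    @property
    def kept_ids(self) -> tuple[str, ...]:
        return tuple(fid for t in PURE_TYPES for fid in self.kept[t])


def filter_pure_fibers(calls: Iterable[FiberTypeCall]) -> PurityPartition:
    """Partition fibers into pure type groups and excluded hybrids.

    An empty kept group triggers a warning but not an error; downstream
    statistics tolerate missing groups.
    """
    kept: dict[FiberType, list[str]] = {t: [] for t in PURE_TYPES}
    excluded: list[str] = []
    for c in calls:
        if c.call is FiberType.HYBRID:
            excluded.append(c.fiber_id)
        else:
            kept[c.call].append(c.fiber_id)
    for t in PURE_TYPES:
        if not kept[t]:
            warnings.warn(f"no pure fibers of type {t.value}", stacklevel=2)
    return PurityPartition(
        kept={t: tuple(ids) for t, ids in kept.items()}, excluded=tuple(excluded)
    )
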