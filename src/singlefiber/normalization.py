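"""iBAQ-style and ACTA1 normalization plus the valid-value filter.

The summed peptide intensity of each protein is divided by its number of
theoretically observable peptides (iBAQ-style scaling, making abundances
comparable across proteins), then each fiber's column is divided by that
fiber's scaled α-skeletal actin (ACTA1) value to correct for fiber volume.
Proteins quantified in fewer than ``min_valid`` fibers of every type group
are removed before testing.

Normalization stays on the linear scale; the differential module takes log2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .fiber_typing import PURE_TYPES, FiberType
from .io_tables import ProteinQuantTable

__all__ = [
    "NormalizedMatrix",
    "FilterReport",
    "ibaq_normalize",
    "acta1_normalize",
    "filter_valid_values",
]


@dataclasses.dataclass
class NormalizedMatrix:
    """ACTA1-normalized relative abundances with fiber type assignments.

    ``values`` is proteins x fibers, linear scale, NaN = missing; columns are
    restricted to pure fibers.  ``fiber_types`` maps fiber_id -> FiberType.
    """

    values: pd.DataFrame
    gene_names: pd.Series
    fiber_types: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.fiber_types.index):
            raise ValueError("values columns must match fiber_types index")
        if not self.values.index.equals(self.gene_names.index):
            raise ValueError("values and gene_names must share the protein index")

    def type_mask(self, fiber_type: FiberType) -> np.ndarray:
        """Boolean column mask selecting fibers of one type."""
        return (self.fiber_types == fiber_type).to_numpy()

    def valid_counts(self) -> pd.DataFrame:
        """Non-missing value counts per protein and fiber type group."""
        present = self.values.notna().to_numpy()
        data = {
            t.value: present[:, self.type_mask(t)].sum(axis=1) for t in PURE_TYPES
        }
        return pd.DataFrame(data, index=self.values.index)

    def subset(self, protein_ids: pd.Index) -> "NormalizedMatrix":
        return NormalizedMatrix(
            values=self.values.loc[protein_ids],
            gene_names=self.gene_names.loc[protein_ids],
            fiber_types=self.fiber_types,
        )


def ibaq_normalize(table: ProteinQuantTable) -> pd.DataFrame:
    """Divide each protein's intensities by its theoretical peptide count.

    Missing values propagate.  Returns a proteins x fibers frame.
    """
    npep = table.meta["n_theoretical_peptides"].to_numpy(dtype=float)
    if (npep < 1).any():
        raise ValueError("n_theoretical_peptides must be >= 1")
    return table.intensities.div(npep, axis=0)


def acta1_normalize(
    ibaq: pd.DataFrame,
    gene_names: pd.Series,
    fiber_types: pd.Series,
    acta1_gene: str = "ACTA1",
) -> NormalizedMatrix:
    """Divide each fiber's column by that fiber's ACTA1 iBAQ value.

    Columns are restricted to the fibers listed in ``fiber_types`` (i.e. the
    pure fibers kept by the purity filter).  ACTA1 is located by exact
    gene-name match and must be quantified in every fiber: it is the
    denominator, so absence is an error rather than something to impute.
    """
    hits = gene_names.index[gene_names == acta1_gene]
    if len(hits) == 0:
        raise ValueError(f"no protein with gene_name {acta1_gene!r}")
    if len(hits) > 1:
        raise ValueError(f"multiple proteins with gene_name {acta1_gene!r}: {list(hits)}")
    missing_fibers = [f for f in fiber_types.index if f not in ibaq.columns]
    if missing_fibers:
        raise ValueError(f"fibers absent from the intensity table: {missing_fibers}")
    sub = ibaq.loc[:, list(fiber_types.index)]
    acta1 = sub.loc[hits[0]]
    bad = acta1.index[~(acta1 > 0)].tolist()
    if bad:
        raise ValueError(f"ACTA1 missing or zero in fiber(s): {bad}")
    values = sub.div(acta1, axis=1)
    return NormalizedMatrix(
        values=values, gene_names=gene_names.copy(), fiber_types=fiber_types.copy()
    )


@dataclasses.dataclass(frozen=True)
class FilterReport:
    n_in: int
    n_kept: int
    n_dropped: int


def filter_valid_values(
    matrix: NormalizedMatrix, min_valid: int = 4
) -> tuple[NormalizedMatrix, FilterReport]:
    """Keep proteins with >= min_valid valid values in at least one type group."""
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    counts = matrix.valid_counts()
    keep = (counts >= min_valid).any(axis=1)
    kept_ids = counts.index[keep]
    report = FilterReport(
        n_in=len(counts), n_kept=int(keep.sum()), n_dropped=int((~keep).sum())
    )
    if report.n_kept == 0:
        warnings.warn("valid-value filter removed every protein", stacklevel=2)
    return matrix.subset(kept_ids), report
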