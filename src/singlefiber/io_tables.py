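"""Tab-separated I/O for single-fiber proteomics tables.

Two on-disk dialects are supported for protein quantification tables:

* ``native`` — the package's own interchange format: one row per protein
  group with columns ``protein_id``, ``gene_name``,
  ``n_theoretical_peptides`` and one ``intensity_<fiber_id>`` column per
  fiber.  Missing quantifications are stored as empty cells; a stored ``0``
  is converted to missing on load (LFQ convention: absent = not detected).
* ``maxquant`` — a best-effort mapping of a MaxQuant ``proteinGroups.txt``:
  ``LFQ intensity <sample>`` columns become fiber intensity columns and rows
  flagged as reverse hits or potential contaminants are dropped.

All files are UTF-8, tab-separated, ``.`` decimal, no thousands separators.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "FiberSample",
    "ProteinQuantTable",
    "read_fiber_table",
    "write_fiber_table",
    "read_protein_table",
    "write_protein_table",
    "RESULT_COLUMNS",
    "write_results",
    "read_results",
]


class TableFormatError(ValueError):
    """Raised when an input table violates the documented format."""


@dataclasses.dataclass(frozen=True)
class FiberSample:
    """One dissected fiber with its summed unique-peptide MYH intensities.

    Intensities are arbitrary label-free quantification units; a missing
    isoform is stored as 0 (absence of unique peptides = not detected).
    """

    fiber_id: str
    subject_id: str
    myh7: float
    myh2: float
    myh1: float

    def __post_init__(self) -> None:
        for name in ("myh7", "myh2", "myh1"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"fiber {self.fiber_id!r}: {name} must be finite and >= 0, got {v}"
                )
        if self.myh7 == self.myh2 == self.myh1 == 0:
            raise ValueError(
                f"fiber {self.fiber_id!r}: all three MYH intensities are zero"
            )


@dataclasses.dataclass
class ProteinQuantTable:
    """Raw summed peptide intensities, proteins x fibers.

    ``meta`` is indexed by ``protein_id`` and carries ``gene_name`` and
    ``n_theoretical_peptides``; ``intensities`` shares the index and has one
    column per fiber, with ``NaN`` marking a missing quantification.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensities must share the protein index")
        if self.meta.index.has_duplicates:
            dups = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate protein_id(s): {dups}")
        for col in ("gene_name", "n_theoretical_peptides"):
            if col not in self.meta.columns:
                raise TableFormatError(f"missing mandatory column: {col}")
        npep = self.meta["n_theoretical_peptides"]
        if (npep < 1).any():
            bad = self.meta.index[npep < 1].tolist()
            raise ValueError(f"n_theoretical_peptides < 1 for: {bad}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def fiber_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def gene_names(self) -> pd.Series:
        return self.meta["gene_name"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_float_column(df: pd.DataFrame, col: str, *, missing_to: float) -> np.ndarray:
    raw = df[col].to_numpy()
    out = np.empty(len(raw), dtype=float)
    for i, cell in enumerate(raw):
        cell = cell.strip()
        if cell == "" or cell.upper() in ("NA", "NAN"):
            out[i] = missing_to
            continue
        try:
            out[i] = float(cell)
        except ValueError:
            raise TableFormatError(
                f"non-numeric value {cell!r} in column {col!r}, data row {i + 1}"
            ) from None
    return out


def read_fiber_table(path: str | Path) -> list[FiberSample]:
    """Read the per-fiber MYH table (fiber_id, subject_id, myh7, myh2, myh1).

    Empty MYH cells become 0.  Duplicate fiber ids and fibers with no MYH
    signal at all are format errors.
    """
    df = _read_tsv(path)
    required = ["fiber_id", "subject_id", "myh7", "myh2", "myh1"]
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column: {col}")
    ids = df["fiber_id"].tolist()
    seen: set[str] = set()
    for fid in ids:
        if fid in seen:
            raise TableFormatError(f"duplicate fiber_id: {fid!r}")
        seen.add(fid)
    cols = {c: _parse_float_column(df, c, missing_to=0.0) for c in ("myh7", "myh2", "myh1")}
    samples = []
    for i, fid in enumerate(ids):
        try:
            samples.append(
                FiberSample(
                    fiber_id=fid,
                    subject_id=df["subject_id"].iloc[i],
                    myh7=cols["myh7"][i],
                    myh2=cols["myh2"][i],
                    myh1=cols["myh1"][i],
                )
            )
        except ValueError as exc:
            raise TableFormatError(str(exc)) from None
    return samples


def write_fiber_table(path: str | Path, samples: Iterable[FiberSample]) -> None:
    rows = [
        {
            "fiber_id": s.fiber_id,
            "subject_id": s.subject_id,
            "myh7": s.myh7,
            "myh2": s.myh2,
            "myh1": s.myh1,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows, columns=["fiber_id", "subject_id", "myh7", "myh2", "myh1"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


_NATIVE_META_COLS = ["protein_id", "gene_name", "n_theoretical_peptides"]
_INTENSITY_PREFIX = "intensity_"


def read_protein_table(path: str | Path, dialect: str = "native") -> ProteinQuantTable:
    """Read a protein quantification table.

    Stored zeros are converted to missing.  Row order is preserved.  The
    ``maxquant`` dialect drops rows flagged reverse / potential contaminant
    (count reported on the returned table as ``n_dropped_rows``).
    """
    if dialect == "native":
        return _read_native(path)
    if dialect == "maxquant":
        return _read_maxquant(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _finalize_table(
    protein_ids: Sequence[str],
    gene_names: Sequence[str],
    n_pep: np.ndarray,
    intensities: pd.DataFrame,
    n_dropped: int,
) -> ProteinQuantTable:
    index = pd.Index(protein_ids, name="protein_id")
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate protein_id(s): {dups}")
    meta = pd.DataFrame(
        {"gene_name": list(gene_names), "n_theoretical_peptides": n_pep.astype(int)},
        index=index,
    )
    intensities = intensities.set_axis(index, axis=0)
    # LFQ convention: a stored 0 means "not detected", not a true zero.
    intensities = intensities.mask(intensities == 0.0, np.nan)
    return ProteinQuantTable(meta=meta, intensities=intensities, n_dropped_rows=n_dropped)


def _read_native(path: str | Path) -> ProteinQuantTable:
    df = _read_tsv(path)
    for col in _NATIVE_META_COLS:
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column: {col}")
    fiber_cols = [c for c in df.columns if c.startswith(_INTENSITY_PREFIX)]
    if not fiber_cols:
        raise TableFormatError(f"no '{_INTENSITY_PREFIX}<fiber_id>' columns found")
    n_pep = _parse_float_column(df, "n_theoretical_peptides", missing_to=np.nan)
    if np.isnan(n_pep).any():
        raise TableFormatError("empty cell in column 'n_theoretical_peptides'")
    data = {
        c[len(_INTENSITY_PREFIX):]: _parse_float_column(df, c, missing_to=np.nan)
        for c in fiber_cols
    }
    intensities = pd.DataFrame(data)
    return _finalize_table(df["protein_id"].tolist(), df["gene_name"].tolist(),
                           n_pep, intensities, 0)


_MQ_LFQ_PREFIX = "LFQ intensity "


def _read_maxquant(path: str | Path) -> ProteinQuantTable:
    df = _read_tsv(path)
    id_col = next((c for c in ("Majority protein IDs", "Protein IDs") if c in df.columns), None)
    if id_col is None:
        raise TableFormatError("missing mandatory column: Protein IDs")
    lfq_cols = [c for c in df.columns if c.startswith(_MQ_LFQ_PREFIX)]
    if not lfq_cols:
        raise TableFormatError(f"no '{_MQ_LFQ_PREFIX}<sample>' columns found")
    keep = np.ones(len(df), dtype=bool)
    for flag_col in ("Reverse", "Potential contaminant", "Contaminant"):
        if flag_col in df.columns:
            keep &= df[flag_col].str.strip() != "+"
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    protein_ids = [cell.split(";")[0] for cell in df[id_col]]
    if "Gene names" in df.columns:
        genes = [cell.split(";")[0] if cell else pid
                 for cell, pid in zip(df["Gene names"], protein_ids)]
    else:
        genes = list(protein_ids)
    if "Number of theoretical peptides" in df.columns:
        n_pep = _parse_float_column(df, "Number of theoretical peptides", missing_to=np.nan)
        if np.isnan(n_pep).any():
            raise TableFormatError("empty cell in column 'Number of theoretical peptides'")
    else:
        # Column absent from most proteinGroups exports; treat intensities as
        # already peptide-count scaled.
        n_pep = np.ones(len(df))
    data = {
        c[len(_MQ_LFQ_PREFIX):]: _parse_float_column(df, c, missing_to=np.nan)
        for c in lfq_cols
    }
    return _finalize_table(protein_ids, genes, n_pep, pd.DataFrame(data), n_dropped)


def write_protein_table(path: str | Path, table: ProteinQuantTable) -> None:
    """Write a ProteinQuantTable in the native dialect (missing -> empty cell)."""
    out = pd.DataFrame({"protein_id": table.meta.index})
    out["gene_name"] = table.meta["gene_name"].to_numpy()
    out["n_theoretical_peptides"] = table.meta["n_theoretical_peptides"].to_numpy()
    for fid in table.intensities.columns:
        out[f"{_INTENSITY_PREFIX}{fid}"] = table.intensities[fid].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="")


#: Fixed column order of the per-protein results table.
RESULT_COLUMNS = [
    "protein_id", "gene_name",
    "n_valid_1", "n_valid_2a", "n_valid_2x",
    "median_1", "median_2a", "median_2x",
    "pct_1", "pct_2a", "pct_2x",
    "F", "p", "fdr_significant",
    "tukey_p_1_2a", "tukey_p_1_2x", "tukey_p_2a_2x",
    "pattern",
]

_RESULT_INT_COLS = ["n_valid_1", "n_valid_2a", "n_valid_2x"]
_RESULT_FLOAT_COLS = [
    "median_1", "median_2a", "median_2x", "pct_1", "pct_2a", "pct_2x",
    "F", "p", "tukey_p_1_2a", "tukey_p_1_2x", "tukey_p_2a_2x",
]


def write_results(path: str | Path, results: pd.DataFrame) -> None:
    """Write the per-protein results table with the fixed column order.

    Floats are serialized with 12 significant digits so a write/read
    round-trip preserves values to ~1e-12 relative accuracy; missing values
    are empty cells.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table lacks columns: {missing}")
    out = results.loc[:, RESULT_COLUMNS].copy()
    out["fdr_significant"] = out["fdr_significant"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    df = _read_tsv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"results table lacks columns: {missing}")
    out = pd.DataFrame({"protein_id": df["protein_id"], "gene_name": df["gene_name"]})
    for col in _RESULT_INT_COLS:
        vals = _parse_float_column(df, col, missing_to=np.nan)
        out[col] = vals.astype(int)
    for col in _RESULT_FLOAT_COLS:
        out[col] = _parse_float_column(df, col, missing_to=np.nan)
    out["fdr_significant"] = df["fdr_significant"].str.strip().str.lower() == "true"
    out["pattern"] = df["pattern"]
    return out.loc[:, RESULT_COLUMNS]
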