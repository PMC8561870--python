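"""Quality-control summaries: fiber PCA and volcano-plot records.

The PCA follows the conventions of label-free single-fiber studies: only
proteins quantified in at least ``min_fibers_per_type`` fibers of *every*
type enter, MYH isoform rows are excluded (they define the grouping and
would trivially dominate), remaining missing values are imputed from a
downshifted normal per fiber, and components come from the SVD of the
log2, per-protein centered matrix.
"""

from __future__ import annotations

import dataclasses
import fnmatch
from typing import Sequence

import numpy as np
import pandas as pd

from .fiber_typing import PURE_TYPES
from .normalization import NormalizedMatrix

__all__ = ["PcaResult", "pca_fibers", "volcano_table"]

_P_FLOOR = 1e-300


@dataclasses.dataclass
class PcaResult:
    coordinates: pd.DataFrame  # fibers x components
    explained_variance_fraction: np.ndarray  # non-increasing, sums to <= 1
    proteins_used: list[str]


def _impute_downshifted(
    X: np.ndarray, rng: np.random.Generator, shift: float, width: float
) -> np.ndarray:
    """Replace NaNs per fiber (column) with draws from a downshifted normal.

    The replacement distribution for a fiber is N(mu - shift*sd, (width*sd)^2)
    where mu, sd summarize that fiber's observed log2 values — the standard
    LFQ stand-in for values below the detection limit.
    """
    out = X.copy()
    for j in range(X.shape[1]):
        col = out[:, j]
        missing = ~np.isfinite(col)
        if not missing.any():
            continue
        observed = col[~missing]
        mu, sd = observed.mean(), observed.std(ddof=1)
        out[missing, j] = rng.normal(mu - shift * sd, width * sd, size=missing.sum())
    return out


def pca_fibers(
    matrix: NormalizedMatrix,
    min_fibers_per_type: int = 5,
    exclude_genes: Sequence[str] = ("MYH*",),
    n_components: int = 5,
    seed: int = 0,
    impute_shift: float = 1.8,
    impute_width: float = 0.3,
) -> PcaResult:
    """PCA of fibers on filtered, imputed, log2-centered abundances.

    Proteins must be quantified in >= ``min_fibers_per_type`` fibers of every
    type; gene names matching any ``exclude_genes`` glob are removed.
    Imputation is seeded and reproducible.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 fibers")
    counts = matrix.valid_counts()
    keep = (counts >= min_fibers_per_type).all(axis=1)
    genes = matrix.gene_names
    excluded = genes.map(
        lambda g: any(fnmatch.fnmatchcase(str(g), pat) for pat in exclude_genes)
    )
    keep &= ~excluded.to_numpy()
    if not keep.any():
        raise ValueError("no proteins survive the PCA filters")
    sub = matrix.values.loc[keep]
    X = np.log2(sub.to_numpy(dtype=float))
    X = _impute_downshifted(X, np.random.default_rng(seed), impute_shift, impute_width)
    X = X.T  # fibers x proteins
    X -= X.mean(axis=0, keepdims=True)
    n_fibers = X.shape[0]
    n_components = min(n_components, n_fibers - 1, X.shape[1])
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    total_var = (S**2).sum()
    coords = U[:, :n_components] * S[:n_components]
    return PcaResult(
        coordinates=pd.DataFrame(
            coords,
            index=sub.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained_variance_fraction=(S[:n_components] ** 2) / total_var,
        proteins_used=list(sub.index),
    )


def volcano_table(pair_results: pd.DataFrame, gene_names: pd.Series | None = None) -> pd.DataFrame:
    """Plot-ready volcano records: log2fc, -log10 p, label per tested protein.

    p-values are floored at 1e-300 so every y coordinate is finite.
    """
    p = pair_results["p"].to_numpy(dtype=float).clip(min=_P_FLOOR)
    out = pd.DataFrame(
        {
            "log2fc": pair_results["log2fc"].to_numpy(dtype=float),
            "neg_log10_p": -np.log10(p),
        },
        index=pair_results.index,
    )
    if gene_names is not None:
        out["label"] = gene_names.reindex(out.index).fillna("").to_numpy()
    else:
        out["label"] = list(out.index)
    return out
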