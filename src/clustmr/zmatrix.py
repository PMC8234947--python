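"""Variant × trait z-score matrix construction.

The clustering substrate is the matrix of association z-scores z = beta/se,
one row per panel variant, one column per trait, with every effect aligned to
the disease risk-increasing allele upstream (see :mod:`clustmr.sumstats`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, PipelineError
from .sumstats import AssociationRecord, VariantPanelEntry

__all__ = ["ZScoreMatrix", "build_zscore_matrix", "filter_complete", "missingness_report"]


@dataclass
class ZScoreMatrix:
    """z-scores with a per-cell availability mask.

    ``z`` is a float DataFrame (variants × traits); ``mask`` is a boolean
    DataFrame of the same shape, True where the cell was observed.  Unobserved
    cells are NaN until :func:`filter_complete` imputes them to 0.
    """

    z: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        if not self.z.index.equals(self.mask.index) or not self.z.columns.equals(
            self.mask.columns
        ):
            raise ValueError("z and mask must share index and columns")
        if not np.isfinite(self.z.values[self.mask.values]).all():
            raise ValueError("z must be finite wherever mask is True")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.z.columns)

    @property
    def values(self) -> np.ndarray:
        return self.z.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def standardized(self) -> "ZScoreMatrix":
        """Column-standardized copy (mean 0, sd 1 per trait) for sensitivity runs."""
        vals = self.z.to_numpy(dtype=float)
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return ZScoreMatrix(
            z=pd.DataFrame((vals - mu) / sd, index=self.z.index, columns=self.z.columns),
            mask=self.mask.copy(),
        )


def build_zscore_matrix(
    tables: Mapping[str, Sequence[AssociationRecord]],
    panel: Sequence[VariantPanelEntry],
    trait_order: Optional[Sequence[str]] = None,
) -> ZScoreMatrix:
    """Assemble z[i, j] = beta/se of panel variant i in trait j.

    ``tables`` maps trait id to harmonized records.  Cells for panel variants
    absent from a trait's table are masked.  A trait listed in ``trait_order``
    with no table is a configuration error.
    """
    traits = list(trait_order) if trait_order is not None else list(tables)
    missing_traits = [t for t in traits if t not in tables]
    if missing_traits:
        raise ConfigurationError(f"no table for configured trait(s): {missing_traits}")
    variant_ids = [e.variant_id for e in panel]
    z = np.full((len(variant_ids), len(traits)), np.nan)
    mask = np.zeros_like(z, dtype=bool)
    row_of = {v: i for i, v in enumerate(variant_ids)}
    for j, trait in enumerate(traits):
        for rec in tables[trait]:
            i = row_of.get(rec.variant_id)
            if i is None:
                continue
            z[i, j] = rec.beta / rec.se
            mask[i, j] = True
    return ZScoreMatrix(
        z=pd.DataFrame(z, index=variant_ids, columns=traits),
        mask=pd.DataFrame(mask, index=variant_ids, columns=traits),
    )


def filter_complete(matrix: ZScoreMatrix, max_missing_per_variant: float = 0.25) -> ZScoreMatrix:
    """Drop variants missing from too many traits; impute the rest to 0.

    A variant whose fraction of masked cells exceeds
    ``max_missing_per_variant`` is removed.  Remaining masked cells are set to
    0 (null association) — the mask keeps marking them as imputed, which
    :func:`missingness_report` surfaces.
    """
    if not 0 <= max_missing_per_variant <= 1:
        raise ValueError("max_missing_per_variant must be in [0, 1]")
    missing_frac = 1.0 - matrix.mask.mean(axis=1)
    keep = missing_frac <= max_missing_per_variant
    if not keep.any():
        raise PipelineError("no variants remain after missingness filtering")
    z = matrix.z.loc[keep].copy()
    mask = matrix.mask.loc[keep].copy()
    z.values[~mask.values] = 0.0
    return ZScoreMatrix(z=z, mask=mask)


def missingness_report(matrix: ZScoreMatrix) -> pd.DataFrame:
    """Per-variant missingness summary (counts refer to the mask, i.e. cells
    that were unobserved — whether still NaN or already imputed to 0)."""
    n_missing = (~matrix.mask).sum(axis=1)
    return pd.DataFrame(
        {
            "variant_id": matrix.variant_ids,
            "n_traits": matrix.mask.shape[1],
            "n_missing": n_missing.to_numpy(),
            "missing_frac": (n_missing / matrix.mask.shape[1]).to_numpy(),
            "imputed_traits": [
                ",".join(matrix.mask.columns[~matrix.mask.loc[v]]) for v in matrix.variant_ids
            ],
        }
    ).reset_index(drop=True)
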