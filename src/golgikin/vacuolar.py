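"""Percent vacuolar-to-total fluorescence per cell, and replicate summaries.

A mislocalized Golgi protein accumulates in the vacuole lumen; the readout is
the percentage of a cell's (background-corrected) fluorescence that lies
inside its vacuole mask. Masks are inputs — label images aligned to the
fluorescence image, 0 = background — and the camera/cytosol background is
estimated robustly as the median intensity outside all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateObjectError, InvalidParameterError

__all__ = ["VacuolarSummary", "vacuolar_ratio", "vacuolar_percentages", "batch_vacuolar_summary"]


@dataclass
class VacuolarSummary:
    """Replicate-level aggregation of per-cell vacuolar percentages."""

    per_replicate_mean: pd.Series  # index: replicate_id
    grand_mean: float
    sd_across_replicates: float
    n_cells: int
    single_replicate: bool = False


def _estimate_background(img: np.ndarray, outside: np.ndarray) -> float:
    return float(np.median(img[outside])) if outside.any() else 0.0


def vacuolar_ratio(
    img: np.ndarray,
    cell_mask: np.ndarray,
    vacuole_mask: np.ndarray,
    background: float | None = None,
) -> float:
    """Percent of one cell's corrected fluorescence inside its vacuole.

    ``background`` defaults to the median intensity outside the cell mask
    (pass the field-wide estimate when the image holds several cells).
    Vacuole pixels outside the cell are dropped with a warning. The corrected
    intensity is ``max(img - background, 0)``.
    """
    img = np.asarray(img, dtype=float)
    cell = np.asarray(cell_mask, dtype=bool)
    vac = np.asarray(vacuole_mask, dtype=bool)
    if not cell.any():
        raise InvalidParameterError("empty cell mask")
    if (vac & ~cell).any():
        warnings.warn("vacuole mask extends outside the cell mask; outside pixels dropped")
        vac = vac & cell
    if background is None:
        background = _estimate_background(img, ~cell)
    corrected = np.clip(img - background, 0.0, None)
    total = corrected[cell].sum()
    if total <= 0:
        raise DegenerateObjectError("cell has zero corrected fluorescence")
    return float(100.0 * corrected[vac].sum() / total)


def vacuolar_percentages(
    img: np.ndarray,
    cell_labels: np.ndarray,
    vacuole_labels: np.ndarray,
    replicate_id: str = "rep1",
) -> pd.DataFrame:
    """Per-cell vacuolar percentages for a multi-cell field.

    ``cell_labels``/``vacuole_labels`` are label images (0 = background,
    matching positive ids per cell). Background is the median intensity
    outside all cells, shared by every cell of the field. Degenerate cells
    (no corrected signal) are skipped with a warning.
    """
    img = np.asarray(img, dtype=float)
    cell_labels = np.asarray(cell_labels)
    vacuole_labels = np.asarray(vacuole_labels)
    background = _estimate_background(img, cell_labels == 0)
    rows = []
    for cid in np.unique(cell_labels[cell_labels > 0]):
        try:
            pct = vacuolar_ratio(
                img, cell_labels == cid, vacuole_labels == cid, background=background
            )
        except DegenerateObjectError:
            warnings.warn(f"cell {cid}: zero corrected fluorescence, skipped")
            continue
        rows.append({"replicate_id": replicate_id, "cell_id": int(cid), "vacuolar_percent": pct})
    return pd.DataFrame(rows, columns=["replicate_id", "cell_id", "vacuolar_percent"])


def batch_vacuolar_summary(records: pd.DataFrame) -> VacuolarSummary:
    """Aggregate per-cell percentages: replicate means, grand mean, SD.

    ``records`` needs columns ``replicate_id`` and ``vacuolar_percent``. The
    grand mean is the mean of replicate means (each independent experiment
    weighted equally); the SD is across replicate means. With a single
    replicate the SD is reported as 0 and flagged.
    """
    if records.empty:
        raise InvalidParameterError("no cell records to summarize")
    if not records["vacuolar_percent"].between(0, 100).all():
        raise InvalidParameterError("vacuolar_percent must lie in [0, 100]")
    rep_means = records.groupby("replicate_id")["vacuolar_percent"].mean()
    single = len(rep_means) == 1
    sd = 0.0 if single else float(rep_means.std(ddof=1))
    return VacuolarSummary(
        per_replicate_mean=rep_means,
        grand_mean=float(rep_means.mean()),
        sd_across_replicates=sd,
        n_cells=int(len(records)),
        single_replicate=single,
    )
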