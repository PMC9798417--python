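"""Cross-specimen marker tracking and single-point serum quantitation.

A tissue-derived marker earns diagnostic value only if it survives in the
far more accessible specimen: serum.  :func:`track_markers` intersects an
annotated tissue marker table with the serum differential table and keeps a
metabolite when its serum change is significant (q < 0.05), its direction
agrees with the tissue direction, and its serum fold change clears the same
2.0 / 0.5 cut-offs used in tissue.

Absolute serum concentrations are estimated by a single-point ratio against
a known standard spiked into serum: with TIC-normalized intensities on both
sides, the sample's TIC scale factor cancels, so

    c_sample = c_standard * I_sample / I_standard .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrackedMarker", "track_markers", "estimate_concentration"]


@dataclass
class TrackedMarker:
    """A tissue marker interrogated in serum."""

    metabolite: str
    tissue_fc: float
    tissue_direction: str
    serum_fc: float
    serum_direction: str
    serum_q: float
    consistent: bool
    concentration_uM: float | None = None


def track_markers(
    tissue: pd.DataFrame,
    serum: pd.DataFrame,
    q_threshold: float = 0.05,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
) -> tuple[list[TrackedMarker], int]:
    """Trace annotated tissue markers through the serum differential table.

    Both tables are marker tables (as from
    :func:`metafinger.markers.select_markers`) whose ``annotation`` column
    carries metabolite identities; rows without an annotation are skipped
    and counted.  Only tissue-*selected* markers are interrogated.  A marker
    is retained (``consistent=True``) iff its serum q-value is below
    ``q_threshold``, serum and tissue fold-change directions agree, and the
    serum fold change is strictly above ``fc_high`` or strictly below
    ``fc_low``.

    Returns
    -------
    (tracked, n_skipped)
        One :class:`TrackedMarker` per tissue marker found in serum, and
        the number of unannotated or serum-absent tissue markers skipped.
    """
    for col in ("annotation", "fold_change", "direction", "q_value", "selected"):
        if col not in tissue.columns or col not in serum.columns:
            raise ValueError(f"marker tables must carry a {col!r} column")

    serum_by_met = {
        str(row.annotation): row
        for row in serum.itertuples(index=False)
        if str(row.annotation)
    }
    tracked: list[TrackedMarker] = []
    skipped = 0
    for row in tissue[tissue["selected"]].itertuples(index=False):
        met = str(row.annotation)
        if not met or met not in serum_by_met:
            skipped += 1
            continue
        srow = serum_by_met[met]
        serum_fc = float(srow.fold_change)
        consistent = (
            float(srow.q_value) < q_threshold
            and str(srow.direction) == str(row.direction)
            and (serum_fc > fc_high or serum_fc < fc_low)
        )
        tracked.append(TrackedMarker(
            metabolite=met,
            tissue_fc=float(row.fold_change),
            tissue_direction=str(row.direction),
            serum_fc=serum_fc,
            serum_direction=str(srow.direction),
            serum_q=float(srow.q_value),
            consistent=bool(consistent),
        ))
    return tracked, skipped


def tracked_to_frame(tracked: list[TrackedMarker]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tracked])


def estimate_concentration(
    sample_norm_intensity: float,
    standard_norm_intensity: float,
    standard_concentration: float,
) -> float:
    """Single-point concentration estimate against a spiked standard (µM)."""
    if standard_norm_intensity <= 0:
        raise ValueError("standard intensity must be positive")
    if sample_norm_intensity < 0:
        raise ValueError("sample intensity must be non-negative")
    return standard_concentration * sample_norm_intensity / standard_norm_intensity
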