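"""Per-cell compartment intensities and the nucleolar normality score.

For each nucleus, every channel's integrated (summed) intensity is split
into a nucleolar part (pixels inside that nucleus's nucleoli) and a
nucleoplasmic part (the remainder), so that

    I_nucleoplasm = I_nucleus - I_nucleolar   (exactly, every channel).

The **nucleolar normality score** of a cell is the ratio of
nucleolar/nucleoplasmic ratios of the granular-component marker (e.g.
nucleolin) and the fibrillar-center marker (e.g. UBF):

    score = [I_nucleolar(GC) / I_nucleoplasm(GC)]
          / [I_nucleolar(FC) / I_nucleoplasm(FC)]

Under nucleolar stress the GC marker disperses into the nucleoplasm while
the FC marker condenses, so the score decreases. Cells with no detected
nucleoli, or with a non-positive denominator, carry an undefined score: they
are excluded from aggregates but tallied in QC columns.

All measurements here are taken on background-subtracted, *unblurred*
channels; smoothing exists only to define masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageField
from .segmentation import (
    LabelMask,
    SegmentationParams,
    segment_nuclei,
    segment_nucleoli,
    subtract_background_rolling_ball,
)

__all__ = [
    "CellMeasurement",
    "measure_cell",
    "normality_score",
    "compartment_ratio",
    "measure_field",
    "score_field",
    "field_intensity_summary",
    "normalize_to_vehicle",
]


@dataclass
class CellMeasurement:
    """Integrated intensities of one nucleus split by compartment."""

    nucleus_label: int
    i_nucleus: dict[str, float]
    i_nucleolar: dict[str, float]
    i_nucleoplasm: dict[str, float]
    n_nucleoli: int
    nucleolar_area_px: int
    nucleus_area_px: int
    normality_score: float = math.nan
    score_defined: bool = False
    field_id: str = ""
    well_id: str | None = None


def measure_cell(
    field: ImageField,
    nuclei: LabelMask,
    nucleoli: LabelMask,
    nucleus_label: int,
    channels: list[str] | None = None,
) -> CellMeasurement:
    """Measure one nucleus's per-channel compartment intensities.

    ``field`` must already hold background-subtracted channels (see
    :func:`score_field` for the full pipeline). Nucleolar and nucleoplasmic
    compartments are exhaustive and mutually exclusive within the nucleus.
    """
    if not 1 <= nucleus_label <= nuclei.n_objects:
        raise KeyError(f"nucleus label {nucleus_label} absent from mask")
    if channels is None:
        channels = field.channel_names
    nucleus_mask = nuclei.labels == nucleus_label
    own = [lab for lab, par in nucleoli.parent.items() if par == nucleus_label]
    nucleolar_mask = np.isin(nucleoli.labels, own) if own else np.zeros_like(nucleus_mask)
    nucleolar_mask &= nucleus_mask  # invariant: nucleolus pixels lie in the nucleus
    i_nucleus: dict[str, float] = {}
    i_nucleolar: dict[str, float] = {}
    i_nucleoplasm: dict[str, float] = {}
    for name in channels:
        arr = field[name]
        total = float(arr[nucleus_mask].sum())
        nucleolar = float(arr[nucleolar_mask].sum())
        i_nucleus[name] = total
        i_nucleolar[name] = nucleolar
        i_nucleoplasm[name] = total - nucleolar
    return CellMeasurement(
        nucleus_label=nucleus_label,
        i_nucleus=i_nucleus,
        i_nucleolar=i_nucleolar,
        i_nucleoplasm=i_nucleoplasm,
        n_nucleoli=len(own),
        nucleolar_area_px=int(nucleolar_mask.sum()),
        nucleus_area_px=int(nucleus_mask.sum()),
        field_id=field.field_id,
        well_id=field.well_id,
    )


def normality_score(
    meas: CellMeasurement, gc_channel: str, fc_channel: str
) -> float:
    """GC (nucleolar/nucleoplasm) ratio divided by the FC ratio.

    Returns NaN (and leaves ``score_defined`` False) when the cell has no
    nucleoli, any nucleoplasmic intensity is <= 0, or the FC nucleolar
    intensity is 0 — such cells are excluded from aggregates.
    """
    meas.score_defined = False
    meas.normality_score = math.nan
    if meas.n_nucleoli == 0:
        return meas.normality_score
    gc_np = meas.i_nucleoplasm[gc_channel]
    fc_np = meas.i_nucleoplasm[fc_channel]
    fc_no = meas.i_nucleolar[fc_channel]
    if gc_np <= 0 or fc_np <= 0 or fc_no <= 0:
        return meas.normality_score
    gc_ratio = meas.i_nucleolar[gc_channel] / gc_np
    fc_ratio = fc_no / fc_np
    meas.normality_score = gc_ratio / fc_ratio
    meas.score_defined = True
    return meas.normality_score


def compartment_ratio(meas: CellMeasurement, channel: str) -> float:
    """Nucleolus / nucleoplasm integrated-intensity ratio of one channel.

    This is the readout used for e.g. RNA Pol I (POLR1A) nucleolar
    occupancy; normalization to vehicle controls happens at the screen
    level, not here. NaN when the nucleoplasmic intensity is not positive.
    """
    denominator = meas.i_nucleoplasm[channel]
    if denominator <= 0:
        return math.nan
    return meas.i_nucleolar[channel] / denominator


def measure_field(
    field: ImageField,
    nuclei: LabelMask,
    nucleoli: LabelMask,
    channels: list[str] | None = None,
) -> list[CellMeasurement]:
    """Measure every nucleus of a field. Channels must be pre-subtracted."""
    return [
        measure_cell(field, nuclei, nucleoli, label, channels)
        for label in range(1, nuclei.n_objects + 1)
    ]


def score_field(
    field: ImageField,
    *,
    dna_channel: str = "dapi",
    fc_channel: str = "fc",
    gc_channel: str = "gc",
    extra_channels: list[str] | None = None,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Full single-field pipeline: segment, measure, score.

    Returns one row per nucleus with per-channel compartment intensities,
    the normality score, the per-channel nucleolus/nucleoplasm ratios, and
    QC flags. Marker channels are background-subtracted with the small
    rolling-ball radius before measurement; the DNA channel with the large
    radius (used for segmentation only).
    """
    params = params or SegmentationParams()
    nuclei = segment_nuclei(field[dna_channel], params)
    marker_names = [fc_channel, gc_channel] + list(extra_channels or [])
    rows: list[dict] = []
    if nuclei.n_objects == 0:
        return _cell_frame(rows, marker_names)
    nucleoli = segment_nucleoli(field[fc_channel], nuclei, params)
    subtracted = ImageField(
        channels={
            name: subtract_background_rolling_ball(
                field[name], params.nucleolus_bg_radius
            )
            for name in marker_names
        },
        pixel_size_um=field.pixel_size_um,
        field_id=field.field_id,
        well_id=field.well_id,
    )
    for meas in measure_field(subtracted, nuclei, nucleoli, marker_names):
        normality_score(meas, gc_channel, fc_channel)
        row = {
            "well_id": meas.well_id,
            "field_id": meas.field_id,
            "nucleus_label": meas.nucleus_label,
            "nucleus_area_px": meas.nucleus_area_px,
            "nucleolar_area_px": meas.nucleolar_area_px,
            "n_nucleoli": meas.n_nucleoli,
            "normality_score": meas.normality_score,
            "score_defined": meas.score_defined,
        }
        for name in marker_names:
            row[f"i_nucleolar_{name}"] = meas.i_nucleolar[name]
            row[f"i_nucleoplasm_{name}"] = meas.i_nucleoplasm[name]
            row[f"ratio_{name}"] = compartment_ratio(meas, name)
        rows.append(row)
    return _cell_frame(rows, marker_names)


def _cell_frame(rows: list[dict], marker_names: list[str]) -> pd.DataFrame:
    columns = [
        "well_id",
        "field_id",
        "nucleus_label",
        "nucleus_area_px",
        "nucleolar_area_px",
        "n_nucleoli",
        "normality_score",
        "score_defined",
    ]
    for name in marker_names:
        columns += [f"i_nucleolar_{name}", f"i_nucleoplasm_{name}", f"ratio_{name}"]
    return pd.DataFrame(rows, columns=columns)


def field_intensity_summary(
    per_cell: pd.DataFrame,
    value_column: str,
    *,
    field_column: str = "field_id",
) -> pd.DataFrame:
    """Per-field mean and dispersion of a per-cell quantity.

    Used for 5-EU / anti-rRNA style readouts where per-field averages over
    hundreds of cells precede group statistics. Empty fields are skipped;
    the ``n_cells`` column records how many cells entered each mean.
    """
    if per_cell.empty:
        raise ValueError("at least one field with at least one cell is required")
    grouped = per_cell.dropna(subset=[value_column]).groupby(field_column)
    summary = grouped[value_column].agg(["mean", "std", "count"]).reset_index()
    summary.columns = [field_column, "mean", "sd", "n_cells"]
    return summary


def normalize_to_vehicle(
    summary: pd.DataFrame,
    vehicle_fields: list[str],
    *,
    field_column: str = "field_id",
    value_column: str = "mean",
) -> pd.DataFrame:
    """Divide per-field averages by the vehicle-group mean (vehicle -> 1)."""
    vehicle = summary[summary[field_column].isin(vehicle_fields)]
    if vehicle.empty:
        raise ValueError("no vehicle fields found in summary")
    baseline = float(vehicle[value_column].mean())
    if baseline <= 0:
        raise ValueError("vehicle baseline must be positive")
    out = summary.copy()
    out["normalized"] = out[value_column] / baseline
    return out
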