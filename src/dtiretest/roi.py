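"""Region-of-interest means: the measurement layer feeding reliability analysis.

Region means are computed over integer-labelled voxels, optionally restricted
to voxels whose *template* FA exceeds a threshold (strictly ``>``), the usual
guard against partial-volume contamination at white-matter ROI edges.  The
template is a group-level mean FA image, not the subject's own map, so the
surviving voxel set is identical for every subject in a processing stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tensor import METRICS, ScalarMap

__all__ = [
    "LabelNotFoundError",
    "EmptyRegionError",
    "RegionMeasurement",
    "region_mean",
    "build_measurement_table",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = [
    "subject_id",
    "group",
    "repeat",
    "region",
    "metric",
    "value",
    "n_voxels",
]


class LabelNotFoundError(ValueError):
    """The requested label id does not occur in the label volume."""


class EmptyRegionError(ValueError):
    """No voxels of the region survive the FA threshold (region unusable)."""


@dataclass(frozen=True)
class RegionMeasurement:
    """One cell of the measurement table."""

    subject_id: str
    group: str
    repeat_index: int
    region_name: str
    metric: str
    value: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.repeat_index not in (1, 2):
            raise ValueError("repeat_index must be 1 or 2")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


def _map_data(m) -> np.ndarray:
    return np.asarray(m.data if isinstance(m, ScalarMap) else m, dtype=float)


def region_mean(
    scalar_map,
    labels: np.ndarray,
    label_id: int,
    fa_template=None,
    fa_threshold: float = 0.2,
) -> tuple[float, int]:
    """Mean of a scalar map over one labelled region.

    With ``fa_template`` given, only voxels with template FA strictly above
    ``fa_threshold`` contribute.  Returns ``(mean, n_voxels)``.

    Raises :class:`LabelNotFoundError` if the label is absent and
    :class:`EmptyRegionError` if the threshold removes every voxel — two
    distinct failure modes.
    """
    data = _map_data(scalar_map)
    labels = np.asarray(labels)
    if data.shape != labels.shape:
        raise ValueError(
            f"map shape {data.shape} does not match labels shape {labels.shape}"
        )
    in_region = labels == label_id
    if not in_region.any():
        raise LabelNotFoundError(f"label {label_id} not present in label volume")
    if fa_template is not None:
        template = _map_data(fa_template)
        if template.shape != labels.shape:
            raise ValueError("fa_template shape does not match labels shape")
        in_region = in_region & (template > fa_threshold)
        if not in_region.any():
            raise EmptyRegionError(
                f"label {label_id}: no voxels survive template FA > {fa_threshold}"
            )
    return float(data[in_region].mean()), int(in_region.sum())


def build_measurement_table(
    maps: dict,
    labels: np.ndarray,
    regions,
    groups: dict,
    fa_templates: dict | None = None,
    fa_threshold: float = 0.2,
) -> pd.DataFrame:
    """Complete crossing subjects × repeats × regions × metrics.

    Parameters
    ----------
    maps : dict
        ``{(subject_id, repeat): {metric: ScalarMap or array}}``; every
        subject must have repeats 1 and 2 with all four metrics.
    regions : iterable of (label_id, region_name, thresholded)
        ``thresholded`` regions use the per-repeat FA template filter.
    groups : dict
        ``subject_id -> "control" | "hd"``.
    fa_templates : dict, optional
        ``{repeat: FA template}``; required if any region is thresholded.

    Returns a DataFrame with :data:`MEASUREMENT_COLUMNS`, deterministically
    ordered by (subject, repeat, region, metric).
    """
    subjects = sorted({sid for sid, _ in maps})
    for sid in subjects:
        missing = [rep for rep in (1, 2) if (sid, rep) not in maps]
        if missing:
            raise ValueError(f"subject {sid} is missing repeat(s) {missing}")
    regions = list(regions)
    if fa_templates is None and any(thr for _, _, thr in regions):
        raise ValueError("fa_templates required when any region is thresholded")

    rows = []
    for sid in subjects:
        if sid not in groups:
            raise ValueError(f"subject {sid} has no group assignment")
        for rep in (1, 2):
            metric_maps = maps[(sid, rep)]
            for label_id, region_name, thresholded in regions:
                template = fa_templates[rep] if thresholded else None
                for metric in METRICS:
                    if metric not in metric_maps:
                        raise ValueError(
                            f"subject {sid} repeat {rep} is missing metric {metric}"
                        )
                    value, n_vox = region_mean(
                        metric_maps[metric],
                        labels,
                        label_id,
                        fa_template=template,
                        fa_threshold=fa_threshold,
                    )
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": groups[sid],
                            "repeat": rep,
                            "region": region_name,
                            "metric": metric,
                            "value": value,
                            "n_voxels": n_vox,
                        }
                    )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df.sort_values(
        ["subject_id", "repeat", "region", "metric"], kind="stable"
    ).reset_index(drop=True)
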