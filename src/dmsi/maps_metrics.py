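"""Source-map combination, thresholding and spatial-accuracy metrics.

Metrics quantify how well a distributed source map points at a reference
cortical region (the epileptic focus):

* ``dmin`` — Euclidean distance (mm) from the map maximum to the nearest
  focus vertex.
* ``dmin_reproducibility`` — within-patient, within-method interquartile
  range of dmin across studies.
* ``inter_dmsi_distance`` — for each method, the mean distance between its
  map maximum and the maxima of the other methods on the same study.
* ``spatial_dispersion`` (SD, mm) — amplitude-weighted RMS distance of map
  energy from the focus:
  ``SD = sqrt( sum_i d_i^2 j_i^2 / sum_i j_i^2 )`` with
  ``d_i = min_{j in focus} D_ij``.
* ``map_size`` — number of active vertices of a thresholded map.
* ``map_dmin`` — distance from the nearest active vertex of a thresholded
  (binarized) map to the focus.

Thresholding at level t% keeps vertices whose amplitude is at least t% of
the map maximum; curves are evaluated at 0, 10, ..., 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .anatomy import CorticalMesh, FocusRegion, distance_to_region
from .inverse_linear import SourceMap

__all__ = [
    "THRESHOLD_GRID",
    "ThresholdCurve",
    "rescale_map",
    "average_maps",
    "threshold_map",
    "dmin",
    "dmin_reproducibility",
    "inter_dmsi_distance",
    "spatial_dispersion",
    "map_size",
    "map_dmin",
    "threshold_curves",
    "metrics_for_study",
    "save_map_csv",
    "save_map_gifti",
]

THRESHOLD_GRID = tuple(range(0, 101, 10))  # 11 levels, 0..100% in 10% steps


@dataclass
class ThresholdCurve:
    """One metric evaluated on the 11-point threshold grid for one map."""

    thresholds: tuple
    metric_name: str
    values: np.ndarray
    study_id: str = ""
    method_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.thresholds) != THRESHOLD_GRID:
            raise ValueError(f"thresholds must be {THRESHOLD_GRID}")
        if self.metric_name not in ("SD", "MapSize", "MapDmin"):
            raise ValueError("metric_name must be SD, MapSize or MapDmin")
        if len(self.values) != len(THRESHOLD_GRID):
            raise ValueError("one value per threshold required")
        d = np.diff(self.values)
        if self.metric_name == "MapSize" and np.any(d > 0):
            raise ValueError("MapSize must be nonincreasing in threshold")
        if self.metric_name == "MapDmin" and np.any(d < -1e-9):
            raise ValueError("MapDmin must be nondecreasing in threshold")


def rescale_map(m: SourceMap) -> SourceMap:
    """Min-max rescale to [0, 1]; a constant map maps to all zeros."""
    v = m.amplitudes
    lo, hi = v.min(), v.max()
    if hi == lo:
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return replace(m, amplitudes=out, units_note="rescaled [0, 1]")


def average_maps(maps: list[SourceMap]) -> SourceMap:
    """Per-vertex arithmetic mean of rescaled maps (the "Ave" method)."""
    n = {m.n_vertices for m in maps}
    if len(n) != 1:
        raise ValueError("maps live on different meshes (vertex counts differ)")
    for m in maps:
        if m.amplitudes.min() < 0 or m.amplitudes.max() > 1:
            raise ValueError("average_maps expects rescaled maps in [0, 1]")
    mean = np.mean([m.amplitudes for m in maps], axis=0)
    study_ids = {m.study_id for m in maps}
    sid = study_ids.pop() if len(study_ids) == 1 else ""
    return SourceMap(mean, "Ave", study_id=sid, units_note="mean of rescaled maps")


def threshold_map(m: SourceMap, t_pct: float) -> SourceMap:
    """Keep vertices with amplitude >= (t_pct/100) * max, zero the rest.

    At 100% only the maximum survives (all tied maxima when ties occur).
    """
    if not 0 <= t_pct <= 100:
        raise ValueError("threshold must be in [0, 100] percent")
    v = m.amplitudes
    cut = (t_pct / 100.0) * v.max()
    out = np.where(v >= cut, v, 0.0)
    return replace(m, amplitudes=out)


def dmin(m: SourceMap, focus: FocusRegion, mesh: CorticalMesh) -> float:
    """Distance (mm) from the map maximum vertex to the nearest focus vertex."""
    if np.all(m.amplitudes == 0):
        raise ValueError("dmin undefined for an all-zero map")
    d = distance_to_region(mesh, focus)
    return float(d[m.argmax()])


def dmin_reproducibility(dmins_by_group: dict) -> dict:
    """Within-group IQR (Q3 - Q1, linear-interpolation quantiles) of dmin.

    ``dmins_by_group`` maps a (patient, method) key to that group's dmin
    values.  Groups with fewer than two studies are excluded (reported under
    the returned dict's ``"excluded"`` key).
    """
    out: dict = {}
    excluded = []
    for key, vals in dmins_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            excluded.append(key)
            continue
        q1, q3 = np.percentile(vals, [25, 75], method="linear")
        out[key] = float(q3 - q1)
    if excluded:
        out["excluded"] = excluded
    return out


def inter_dmsi_distance(maxima_mm: dict) -> dict:
    """Mean distance from each method's maximum to the other methods' maxima.

    ``maxima_mm`` maps a method label to the (3,) coordinate of its map
    maximum (``None`` for a missing map: those pairs are skipped and the
    divisor adjusted).
    """
    present = {k: np.asarray(v, float) for k, v in maxima_mm.items() if v is not None}
    if len(present) < 2:
        raise ValueError("inter-method distance needs at least two methods")
    out = {}
    for k, x in present.items():
        d = [np.linalg.norm(x - y) for kk, y in present.items() if kk != k]
        out[k] = float(np.mean(d))
    return out


def spatial_dispersion(
    m: SourceMap, focus: FocusRegion, mesh: CorticalMesh, sd_squared: bool = False
) -> float:
    """Amplitude-weighted RMS distance (mm) of map energy from the focus.

    ``sd_squared=True`` returns the squared (mm^2) variant without the root.
    """
    v = m.amplitudes
    energy = v @ v
    if energy == 0:
        raise ValueError("spatial dispersion undefined for an all-zero map")
    d = distance_to_region(mesh, focus)
    val = float((d**2 * v**2).sum() / energy)
    return val if sd_squared else float(np.sqrt(val))


def map_size(m: SourceMap) -> int:
    """Number of active (nonzero) vertices of a (thresholded) map."""
    return int(np.count_nonzero(m.amplitudes))


def map_dmin(m: SourceMap, focus: FocusRegion, mesh: CorticalMesh) -> float:
    """Distance (mm) from the nearest active vertex to the focus; zero when
    the binarized map intersects the focus."""
    active = np.flatnonzero(m.amplitudes)
    if active.size == 0:
        raise ValueError("map_dmin undefined for an empty active set")
    d = distance_to_region(mesh, focus)
    return float(d[active].min())


def threshold_curves(
    m: SourceMap, focus: FocusRegion, mesh: CorticalMesh
) -> dict[str, ThresholdCurve]:
    """SD, MapSize and MapDmin on the 0..100% (step 10) threshold grid."""
    sd_vals, size_vals, mdmin_vals = [], [], []
    for t in THRESHOLD_GRID:
        tm = threshold_map(m, t)
        sd_vals.append(spatial_dispersion(tm, focus, mesh))
        size_vals.append(map_size(tm))
        mdmin_vals.append(map_dmin(tm, focus, mesh))
    kw = dict(thresholds=THRESHOLD_GRID, study_id=m.study_id, method_label=m.method_label)
    return {
        "SD": ThresholdCurve(metric_name="SD", values=np.array(sd_vals), **kw),
        "MapSize": ThresholdCurve(metric_name="MapSize", values=np.array(size_vals, float), **kw),
        "MapDmin": ThresholdCurve(metric_name="MapDmin", values=np.array(mdmin_vals), **kw),
    }


def metrics_for_study(
    maps: dict[str, SourceMap],
    focus: FocusRegion,
    mesh: CorticalMesh,
    patient_id: str = "",
    study_id: str = "",
) -> pd.DataFrame:
    """Full metric table for one study: one row per method x threshold.

    Columns: patient_id, study_id, method, threshold_pct, dmin_mm, sd_mm,
    size_vertices, map_dmin_mm.  ``dmin_mm`` is threshold independent and
    repeated across threshold rows.
    """
    rows = []
    for label, m in maps.items():
        d0 = dmin(m, focus, mesh)
        curves = threshold_curves(m, focus, mesh)
        for i, t in enumerate(THRESHOLD_GRID):
            rows.append(
                {
                    "patient_id": patient_id,
                    "study_id": study_id,
                    "method": label,
                    "threshold_pct": t,
                    "dmin_mm": d0,
                    "sd_mm": curves["SD"].values[i],
                    "size_vertices": int(curves["MapSize"].values[i]),
                    "map_dmin_mm": curves["MapDmin"].values[i],
                }
            )
    return pd.DataFrame(rows)


def save_map_csv(m: SourceMap, path) -> None:
    pd.DataFrame(
        {"vertex_id": np.arange(m.n_vertices), "value": m.amplitudes}
    ).to_csv(path, index=False)


def save_map_gifti(m: SourceMap, path) -> None:
    """Write a per-vertex functional map (.func.gii)."""
    import nibabel as nib

    arr = nib.gifti.GiftiDataArray(
        m.amplitudes.astype(np.float32), intent="NIFTI_INTENT_NONE"
    )
    img = nib.gifti.GiftiImage(darrays=[arr])
    img.meta["method"] = m.method_label
    nib.save(img, str(path))
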