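"""Narrow-peak cluster detection and localization-pattern classification.

The detection statistic: take the strongest pixel intensity in each axial
segment, normalize the resulting vector to the cell's maximum pixel, and call
the cell cluster-positive when strictly fewer than ``fraction_threshold``
(default 10%) of the entries lie strictly above ``intensity_threshold``
(default 0.75) — i.e. the cell has an intense and narrow fluorescence peak
rather than diffuse envelope signal.

Cluster locations are the intensity maxima of maximal runs of consecutive
supra-threshold segments; patterns: clusters at both poles = bipolar, one
pole = unipolar, otherwise mid-cell/none, with the mid-cell flag carried
independently of the polar pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ZeroSignalError
from .geometry import CellMesh, cell_length, segment_relative_positions
from .image import FluorFrame
from .params import DetectionParams

__all__ = [
    "CellCall",
    "segment_max_vector",
    "normalize_to_cell_max",
    "has_cluster",
    "cluster_positions",
    "classify_pattern",
    "call_cell",
    "summarize_population",
]


@dataclass
class CellCall:
    """Per-cell cluster verdict and pattern label."""

    cell_id: str
    frame: int
    length_um: float
    length_class: str  # short | long
    has_cluster: bool
    positions: list  # relative positions of detected clusters
    pattern: str  # unipolar | bipolar | midcell | none
    midcell: bool
    zero_signal: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.positions)


def segment_max_vector(mesh: CellMesh, frame: FluorFrame) -> np.ndarray:
    """Strongest pixel intensity in each segment, in segment order."""
    flat = frame.image.ravel()
    return np.array([flat[s].max() for s in mesh.segments], dtype=float)


def normalize_to_cell_max(vector) -> np.ndarray:
    """Divide by the maximum entry; values in [0, 1] with max exactly 1.

    Raises :class:`ZeroSignalError` when the maximum is 0 (zero-signal cell).
    """
    v = np.asarray(vector, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity vector")
    m = v.max()
    if m <= 0:
        raise ZeroSignalError("cell maximum intensity is 0")
    return v / m


def has_cluster(normalized, params: DetectionParams) -> bool:
    """Narrow-peak criterion on a normalized per-segment maximum vector.

    True iff (number of entries strictly above ``intensity_threshold``) /
    (number of entries) is strictly below ``fraction_threshold``. With
    ``denominator='nonzero'`` only entries > 0 count toward the denominator.
    """
    v = np.asarray(normalized, dtype=float)
    if v.size == 0:
        raise ValueError("empty normalized vector")
    n_above = int((v > params.intensity_threshold).sum())
    denom = int((v > 0).sum()) if params.denominator == "nonzero" else v.size
    if denom == 0:
        return False
    return n_above / denom < params.fraction_threshold


def cluster_positions(normalized, mesh: CellMesh, params: DetectionParams):
    """Relative positions of detected clusters.

    Each maximal run of consecutive segments strictly above
    ``intensity_threshold`` yields one cluster, located at the run's
    intensity-maximum segment midpoint. Only valid when :func:`has_cluster`
    is true.
    """
    v = np.asarray(normalized, dtype=float)
    if not has_cluster(v, params):
        raise ValueError("cluster_positions called on a cluster-negative cell")
    supra = v > params.intensity_threshold
    pos = segment_relative_positions(mesh)
    out = []
    i = 0
    n = v.size
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1]:
                j += 1
            k = i + int(np.argmax(v[i:j + 1]))
            out.append(float(pos[k]))
            i = j + 1
        else:
            i += 1
    return out


def classify_pattern(positions, params: DetectionParams):
    """(pattern, midcell flag) from cluster positions.

    Polar: position < ``polar_window`` or > 1 − ``polar_window``; clusters at
    both ends = bipolar, one end = unipolar. The mid-cell flag is independent:
    any position inside ``midcell_window``. Cells whose clusters are neither
    polar get pattern "midcell" when the flag is set; no clusters = "none".
    """
    positions = list(positions)
    w = params.polar_window
    lo, hi = params.midcell_window
    at0 = any(p < w for p in positions)
    at1 = any(p > 1.0 - w for p in positions)
    midcell = any(lo <= p <= hi for p in positions)
    if at0 and at1:
        pattern = "bipolar"
    elif at0 or at1:
        pattern = "unipolar"
    elif positions:
        pattern = "midcell" if midcell else "none"
    else:
        pattern = "none"
    return pattern, midcell


def call_cell(mesh: CellMesh, frame: FluorFrame, params: DetectionParams) -> CellCall:
    """Full per-cell verdict: detection, localization, pattern, length class."""
    length = cell_length(mesh)
    length_class = "short" if length < params.length_cutoff else "long"
    try:
        norm = normalize_to_cell_max(segment_max_vector(mesh, frame))
    except ZeroSignalError:
        return CellCall(mesh.cell_id, mesh.frame, length, length_class,
                        has_cluster=False, positions=[], pattern="none",
                        midcell=False, zero_signal=True)
    if not has_cluster(norm, params):
        return CellCall(mesh.cell_id, mesh.frame, length, length_class,
                        has_cluster=False, positions=[], pattern="none",
                        midcell=False)
    positions = cluster_positions(norm, mesh, params)
    pattern, midcell = classify_pattern(positions, params)
    return CellCall(mesh.cell_id, mesh.frame, length, length_class,
                    has_cluster=True, positions=positions, pattern=pattern,
                    midcell=midcell)


def _percentages(calls):
    n = len(calls)
    # polar categories sum to 100; pattern "midcell" counts as no polar cluster
    uni = sum(c.pattern == "unipolar" for c in calls)
    bi = sum(c.pattern == "bipolar" for c in calls)
    none = n - uni - bi
    mid = sum(c.midcell for c in calls)
    return {
        "n": n,
        "unipolar_pct": 100.0 * uni / n,
        "bipolar_pct": 100.0 * bi / n,
        "none_pct": 100.0 * none / n,
        "midcell_pct": 100.0 * mid / n,
        "zero_signal_n": sum(c.zero_signal for c in calls),
    }


def summarize_population(calls, params: DetectionParams | None = None) -> pd.DataFrame:
    """Percentage of cells per localization pattern, overall and by length class.

    Unipolar + bipolar + none sum to 100% (cells whose only cluster is at
    mid-cell count under "none" for the polar categories); the mid-cell
    percentage is reported separately. Length classes split at
    ``params.length_cutoff`` (< cutoff = short, >= cutoff = long).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("summarize_population requires at least one call")
    rows = [{"group": "all", **_percentages(calls)}]
    for cls in ("short", "long"):
        sub = [c for c in calls if c.length_class == cls]
        if sub:
            rows.append({"group": cls, **_percentages(sub)})
    return pd.DataFrame(rows)
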