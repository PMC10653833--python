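"""Cell meshes: ordered axial segments with pixel membership.

A :class:`CellMesh` subdivides one segmented cell into ordered axial segments
(pole0 → pole1), each owning a disjoint set of image pixels. Relative axial
coordinates run from 0 (pole0) to 1 (pole1); a segment's position is the
midpoint of its span of the cumulative axial extent, so unequal segments are
weighted by their physical length.

Meshes come from the synthetic generator, from the structured-text mesh
format, or from integer label images (straight cells only: pixels are sliced
along the principal axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MeshValidationError

__all__ = [
    "CellMesh",
    "cell_length",
    "segment_relative_position",
    "segment_relative_positions",
    "save_meshes",
    "load_meshes",
    "meshes_from_label_image",
    "label_image_from_meshes",
    "TARGET_SEGMENT_UM",
    "MIN_SEGMENTS",
]

#: target axial extent of one segment (µm); segment count = ceil(length / this).
#: One pixel at the default pixel size: the mesh step of the segmentation
#: tools this emulates, and fine enough that a narrow focus occupies a small
#: fraction of segments even in short cells.
TARGET_SEGMENT_UM = 0.065
MIN_SEGMENTS = 10


@dataclass
class CellMesh:
    """Ordered axial segmentation of one cell.

    Attributes
    ----------
    cell_id : str
    frame : int
    segments : list of 1D int arrays
        Flat row-major pixel indices into the image, ordered pole0 → pole1.
    axial_extents_px : 1D float array
        Axial extent of each segment in pixels.
    pole0, pole1 : (row, col) coordinates of the two poles.
    image_shape : (rows, cols) of the image the pixel indices refer to.
    pixel_size : µm per pixel.
    """

    cell_id: str
    frame: int
    segments: list
    axial_extents_px: np.ndarray
    pole0: tuple
    pole1: tuple
    image_shape: tuple
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.segments = [np.asarray(s, dtype=np.int64) for s in self.segments]
        self.axial_extents_px = np.asarray(self.axial_extents_px, dtype=float)

    # -- basic accessors -------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def pixel_indices(self) -> np.ndarray:
        """All pixel indices of the cell (union of segments)."""
        return np.concatenate(self.segments) if self.segments else np.empty(0, np.int64)

    def mask(self) -> np.ndarray:
        """Boolean mask of the cell in the full image."""
        m = np.zeros(self.image_shape, dtype=bool).ravel()
        m[self.pixel_indices()] = True
        return m.reshape(self.image_shape)

    def reversed(self) -> "CellMesh":
        """Mesh with segment order (and poles) flipped: pole1 becomes pole0."""
        return CellMesh(
            cell_id=self.cell_id,
            frame=self.frame,
            segments=list(reversed(self.segments)),
            axial_extents_px=self.axial_extents_px[::-1].copy(),
            pole0=self.pole1,
            pole1=self.pole0,
            image_shape=self.image_shape,
            pixel_size=self.pixel_size,
            meta=dict(self.meta),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        cid = self.cell_id
        if self.n_segments < 3:
            raise MeshValidationError(f"cell {cid}: fewer than 3 segments")
        if len(self.axial_extents_px) != self.n_segments:
            raise MeshValidationError(f"cell {cid}: extents/segments length mismatch")
        if np.any(self.axial_extents_px <= 0):
            raise MeshValidationError(f"cell {cid}: non-positive segment extent")
        npix = self.image_shape[0] * self.image_shape[1]
        seen = np.concatenate(self.segments) if self.segments else np.empty(0, np.int64)
        for i, seg in enumerate(self.segments):
            if seg.size == 0:
                raise MeshValidationError(f"cell {cid}: segment {i} is empty")
            if seg.min() < 0 or seg.max() >= npix:
                raise MeshValidationError(f"cell {cid}: segment {i} pixel out of bounds")
        if len(np.unique(seen)) != seen.size:
            raise MeshValidationError(f"cell {cid}: overlapping segments")
        if self.pixel_size <= 0:
            raise MeshValidationError(f"cell {cid}: non-positive pixel size")


# -- axial coordinates ---------------------------------------------------

def cell_length(mesh: CellMesh) -> float:
    """Physical cell length in µm: sum of segment axial extents × pixel size."""
    length = float(mesh.axial_extents_px.sum()) * mesh.pixel_size
    if length <= 0:
        raise MeshValidationError(f"cell {mesh.cell_id}: non-positive length")
    return length


def segment_relative_positions(mesh: CellMesh) -> np.ndarray:
    """Relative axial position (0=pole0, 1=pole1) of each segment midpoint.

    Positions are the midpoints of the cumulative axial extent, so for n
    equal segments position i is (i + 0.5) / n, and unequal segments are
    weighted by their axial length.
    """
    ext = mesh.axial_extents_px
    cum = np.cumsum(ext)
    return (cum - ext / 2.0) / cum[-1]


def segment_relative_position(mesh: CellMesh, segment_index: int) -> float:
    if not 0 <= segment_index < mesh.n_segments:
        raise IndexError(f"segment index {segment_index} out of range")
    return float(segment_relative_positions(mesh)[segment_index])


# -- structured-text mesh format ------------------------------------------

_HEADER = "# polarsig mesh v1"


def save_meshes(meshes, path) -> None:
    """Write meshes to the structured-text format.

    One ``cell`` line per cell per frame (id, frame, image shape, pixel size,
    pole coordinates), followed by one ``seg`` line per segment holding the
    axial extent (px) and the 0-based row-major pixel indices, in order
    pole0 → pole1.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for m in meshes:
            fh.write(
                "cell {} frame {} shape {} {} pixel_size {:.9g} "
                "pole0 {:.4f} {:.4f} pole1 {:.4f} {:.4f} nseg {}\n".format(
                    m.cell_id, m.frame, m.image_shape[0], m.image_shape[1],
                    m.pixel_size, m.pole0[0], m.pole0[1], m.pole1[0], m.pole1[1],
                    m.n_segments,
                )
            )
            for ext, seg in zip(m.axial_extents_px, m.segments):
                fh.write("seg {:.9g} ".format(ext) + " ".join(map(str, seg.tolist())) + "\n")


def load_meshes(path):
    """Read and validate meshes from the structured-text format.

    Malformed records raise :class:`MeshValidationError` naming the cell.
    """
    meshes = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    if lines and lines[0].startswith("#"):
        i = 1
    while i < len(lines):
        ln = lines[i]
        if not ln.strip():
            i += 1
            continue
        tok = ln.split()
        if tok[0] != "cell":
            raise MeshValidationError(f"line {i + 1}: expected 'cell' record, got {ln[:40]!r}")
        try:
            cid = tok[1]
            frame = int(tok[3])
            shape = (int(tok[5]), int(tok[6]))
            ps = float(tok[8])
            pole0 = (float(tok[10]), float(tok[11]))
            pole1 = (float(tok[13]), float(tok[14]))
            nseg = int(tok[16])
        except (IndexError, ValueError) as exc:
            raise MeshValidationError(f"line {i + 1}: malformed cell header: {exc}") from exc
        i += 1
        segments, extents = [], []
        for k in range(nseg):
            if i >= len(lines) or not lines[i].startswith("seg"):
                raise MeshValidationError(f"cell {cid}: missing segment {k}")
            parts = lines[i].split()
            extents.append(float(parts[1]))
            segments.append(np.array([int(x) for x in parts[2:]], dtype=np.int64))
            i += 1
        mesh = CellMesh(cid, frame, segments, np.array(extents), pole0, pole1, shape, ps)
        mesh.validate()
        meshes.append(mesh)
    return meshes


# -- label-image ingestion -------------------------------------------------

def meshes_from_label_image(labels, pixel_size: float, frame: int = 0):
    """Build meshes from an integer label image (straight cells only).

    For each label the pixels are projected onto the principal axis and cut
    into ``max(MIN_SEGMENTS, ceil(length_um / TARGET_SEGMENT_UM))`` equal
    axial slices. Slices left empty by discretization are absorbed by
    reducing the segment count.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise MeshValidationError("label image must be 2D")
    meshes = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        pts = np.stack([rows, cols], axis=1).astype(float)
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        # principal axis via covariance eigenvector
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        axis = v[:, np.argmax(w)]
        if axis[1] < 0 or (axis[1] == 0 and axis[0] < 0):
            axis = -axis  # deterministic orientation: pole0 at smaller col
        t = centered @ axis
        tmin, tmax = t.min(), t.max()
        length_px = (tmax - tmin) + 1.0
        length_um = length_px * pixel_size
        n = max(MIN_SEGMENTS, math.ceil(length_um / TARGET_SEGMENT_UM))
        flat = rows * labels.shape[1] + cols
        while n >= 3:
            edges = np.linspace(tmin - 0.5, tmax + 0.5, n + 1)
            which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n - 1)
            segs = [flat[which == k] for k in range(n)]
            if all(s.size for s in segs):
                break
            n -= 1
        else:
            raise MeshValidationError(f"cell {lab}: too few pixels for a mesh")
        ext = np.full(n, length_px / n)
        pole0 = tuple(centroid + axis * tmin)
        pole1 = tuple(centroid + axis * tmax)
        mesh = CellMesh(str(int(lab)), frame, segs, ext, pole0, pole1, labels.shape, pixel_size)
        mesh.validate()
        meshes.append(mesh)
    return meshes


def label_image_from_meshes(meshes, shape=None) -> np.ndarray:
    """Rasterize meshes into an integer label image (labels = 1..n in order)."""
    if shape is None:
        if not meshes:
            raise MeshValidationError("cannot infer shape from empty mesh list")
        shape = meshes[0].image_shape
    out = np.zeros(shape, dtype=np.int32).ravel()
    for i, m in enumerate(meshes, start=1):
        out[m.pixel_indices()] = i
    return out.reshape(shape)
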