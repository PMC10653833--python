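"""Synthetic fluorescence microscopy of rod-shaped cells with polar clusters.

Generates snapshot fields and time-lapse movies — images, meshes and ground
truth — with the statistical structure the downstream analysis assumes:

* cells are straight spherocylinders (rectangle + hemispherical caps) with
  envelope-weighted signal (membrane-proximal pixels are brightest);
* clusters are Gaussian spots added at configurable relative axial positions;
* noise is Poisson on the composited signal plus additive Gaussian read noise,
  applied once per field after compositing;
* movies grow cells exponentially, constrict them over the final 30 min of
  the cycle, and split them into two tracked daughters at one generation;
  each daughter's cluster appears at division + draw(appearance_offset_law)
  (negative draws place a mid-cell spot in the mother before division) and
  persists for draw(lifetime_law).

Cluster appearance and disappearance are realized on the imaging grid: the
recorded truth is the event time a camera sampling every ``frame_interval``
minutes would see, so recovery tests compare like with like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, PlacementError
from .geometry import MIN_SEGMENTS, TARGET_SEGMENT_UM, CellMesh
from .image import FluorFrame
from .params import PATTERNS, SimParams

__all__ = [
    "render_cell",
    "simulate_snapshot",
    "simulate_timelapse",
    "TimelapseTruth",
    "apply_noise",
    "polar_allocation_frame",
]

_PAD = 2  # px of empty border around each rendered cell patch
_GAP = 3  # px gap between sibling cells in a lane
_POLE_POS = 0.02  # relative position of a polar cluster
_SEPTUM_OFFSET = 0.02  # mid-cell spots sit just to each side of the septum
_CONSTRICTION_MIN = 30.0  # min over which the septum narrows before division
_CONSTRICTION_DEPTH = 0.6  # fractional radius reduction at completion
_SPOT_TANGENTIAL_PX = 2.0  # focus extent along the membrane tangent (px)


# ---------------------------------------------------------------------------
# single-cell rendering
# ---------------------------------------------------------------------------

def _render_signal(length_um, width_um, clusters, params: SimParams, constriction=None):
    """Noise-free, background-free signal patch plus mesh (patch coordinates).

    ``clusters`` is a list of (relative_position, amplitude); ``constriction``
    an optional (relative_position, depth) septum narrowing.
    """
    if length_um < 3.0 * width_um:
        raise DegenerateGeometryError(
            f"cell length {length_um:.3g} µm < 3x width {width_um:.3g} µm"
        )
    ps = params.pixel_size
    L = max(int(round(length_um / ps)), 3)
    r = width_um / (2.0 * ps)
    # odd height: integer centerline row, so cap tips fall on pixel centers
    H = 2 * int(math.ceil(r)) + 1 + 2 * _PAD
    W = L + 2 * _PAD
    cy = float(math.ceil(r) + _PAD)
    x_lo, x_hi = _PAD + r, _PAD + L - 1 - r  # centerline endpoints

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    # distance to the centerline segment
    xc = np.clip(xx, x_lo, x_hi)
    d = np.hypot(xx - xc, yy - cy)
    r_eff = np.full_like(d, r)
    if constriction is not None:
        cpos, depth = constriction
        cx = _PAD + cpos * (L - 1)
        r_eff = r * (1.0 - depth * np.exp(-((xx - cx) ** 2) / (2.0 * r ** 2)))
    mask = d <= r_eff + 1e-9

    # envelope weight: membrane-proximal pixels brightest
    w = np.exp(-(((r_eff - d) / (0.35 * r)) ** 2))
    signal = params.envelope_intensity * w * mask

    sigma_px = params.cluster_sigma / ps
    for pos, amp in clusters:
        if not 0.0 <= pos <= 1.0:
            raise ValueError(f"cluster position {pos} outside [0, 1]")
        sx = _PAD + pos * (L - 1)
        # clusters are membrane complexes: center the spot on the envelope at
        # this axial position (at the cap tip that is the centerline itself);
        # under constriction the local radius shrinks with the septum
        r_at = r
        if constriction is not None:
            cpos, depth = constriction
            cx = _PAD + cpos * (L - 1)
            r_at = r * (1.0 - depth * math.exp(-((sx - cx) ** 2) / (2.0 * r ** 2)))
        xc_s = min(max(sx, x_lo), x_hi)
        dy = math.sqrt(max((r_at - 0.5) ** 2 - (sx - xc_s) ** 2, 0.0))
        # spots are realized at pixel centers (sub-pixel optics not modeled);
        # if rounding lands outside the mask, take the nearest cell pixel
        sy = cy - dy
        sx_px, sy_px = round(sx), round(sy)
        if not mask[sy_px, sx_px]:
            my, mx = np.nonzero(mask)
            k = np.argmin((my - sy) ** 2 + (mx - sx) ** 2)
            sy_px, sx_px = int(my[k]), int(mx[k])
        # a focus is a short membrane arc seen in projection: narrow along the
        # cell axis, near-uniform (flat-top) along the membrane tangent
        spot = amp * np.exp(-((xx - sx_px) ** 2) / (2.0 * sigma_px ** 2)
                            - ((yy - sy_px) ** 4) / (2.0 * _SPOT_TANGENTIAL_PX ** 4))
        signal += spot * mask

    # equal-axial-extent segments covering the mask exactly
    n = max(MIN_SEGMENTS, math.ceil(length_um / TARGET_SEGMENT_UM))
    flat = np.flatnonzero(mask.ravel())
    cols = flat % W
    edges = np.linspace(_PAD - 0.5, _PAD + L - 0.5, n + 1)
    while n >= 3:
        edges = np.linspace(_PAD - 0.5, _PAD + L - 0.5, n + 1)
        which = np.clip(np.searchsorted(edges, cols, side="right") - 1, 0, n - 1)
        segs = [flat[which == k] for k in range(n)]
        if all(s.size for s in segs):
            break
        n -= 1
    ext = np.full(n, L / n)
    mesh = CellMesh(
        cell_id="0", frame=0, segments=segs, axial_extents_px=ext,
        pole0=(cy, float(_PAD)), pole1=(cy, float(_PAD + L - 1)),
        image_shape=(H, W), pixel_size=ps,
    )
    return signal, mesh


def apply_noise(image, params: SimParams, rng: np.random.Generator):
    """Poisson (on the composited signal) + Gaussian read noise, clipped at 0."""
    out = np.asarray(image, dtype=float)
    if params.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, out.shape)
    return np.clip(out, 0.0, None)


def render_cell(length_um, width_um, clusters, params: SimParams, rng=None, constriction=None):
    """Render one cell: (image patch, mesh, truth dict).

    The patch includes the diffuse background and, unless noise is disabled in
    ``params``, Poisson + read noise. Identical arguments and seed give
    bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    signal, mesh = _render_signal(length_um, width_um, clusters, params, constriction)
    img = apply_noise(signal + params.background_level, params, rng)
    truth = {
        "length_um": length_um,
        "width_um": width_um,
        "cluster_positions": [float(p) for p, _ in clusters],
        "cluster_amplitudes": [float(a) for _, a in clusters],
    }
    return img, mesh, truth


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def _draw_pattern_clusters(pattern, params: SimParams, rng):
    amp = params.cluster_amplitude
    jit = lambda: amp * rng.uniform(0.95, 1.05)  # noqa: E731
    lo = lambda: rng.uniform(0.0, 2 * _POLE_POS)  # noqa: E731
    hi = lambda: rng.uniform(1.0 - 2 * _POLE_POS, 1.0)  # noqa: E731
    if pattern == "bipolar":
        return [(lo(), jit()), (hi(), jit())]
    if pattern == "unipolar":
        return [(lo() if rng.random() < 0.5 else hi(), jit())]
    if pattern == "midcell":
        return [(rng.uniform(0.46, 0.54), jit())]
    return []


def _offset_mesh(mesh: CellMesh, r0, c0, field_shape, cell_id, frame):
    """Re-index a patch-coordinate mesh into field coordinates."""
    pw = mesh.image_shape[1]
    fw = field_shape[1]
    segs = []
    for s in mesh.segments:
        pr, pc = np.divmod(s, pw)
        segs.append((pr + r0) * fw + (pc + c0))
    return CellMesh(
        cell_id=str(cell_id), frame=frame, segments=segs,
        axial_extents_px=mesh.axial_extents_px.copy(),
        pole0=(mesh.pole0[0] + r0, mesh.pole0[1] + c0),
        pole1=(mesh.pole1[0] + r0, mesh.pole1[1] + c0),
        image_shape=field_shape, pixel_size=mesh.pixel_size,
    )


def simulate_snapshot(n_cells: int, params: SimParams):
    """Simulate one field of cells: (FluorFrame, meshes, truth DataFrame).

    Patterns are drawn i.i.d. from ``params.pattern_probs``; cells are shelf-
    packed without overlap. Raises :class:`PlacementError` when a fixed
    ``params.field_shape`` cannot hold all cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(params.seed)
    lo, hi = params.length_bounds
    lengths = np.clip(params.length_law.sample(rng, n_cells),
                      max(lo, 3.0 * params.cell_width), hi)
    probs = params.prob_vector()
    patterns = [PATTERNS[i] for i in rng.choice(len(PATTERNS), size=n_cells, p=probs)]

    patches, meshes_p, rows = [], [], []
    for i in range(n_cells):
        clusters = _draw_pattern_clusters(patterns[i], params, rng)
        signal, mesh = _render_signal(float(lengths[i]), params.cell_width, clusters, params)
        patches.append(signal)
        meshes_p.append(mesh)
        rows.append({
            "cell_id": str(i), "frame": 0, "pattern": patterns[i],
            "n_clusters": len(clusters),
            "cluster_positions": ";".join(f"{p:.4f}" for p, _ in clusters),
            "length_um": float(lengths[i]), "width_um": params.cell_width,
        })

    margin = 3
    sizes = [p.shape for p in patches]
    if params.field_shape is not None:
        field_shape = tuple(params.field_shape)
        wlim = field_shape[1]
    else:
        area = sum((h + margin) * (w + margin) for h, w in sizes)
        wlim = max(max(w for _, w in sizes) + 2 * margin,
                   int(math.ceil(math.sqrt(2.5 * area))))
        field_shape = None

    # shelf packing
    placements, x, y, shelf_h = [], margin, margin, 0
    for h, w in sizes:
        if w + 2 * margin > wlim:
            raise PlacementError(f"cell wider ({w}px) than the field ({wlim}px)")
        if x + w + margin > wlim:
            y += shelf_h + margin
            x, shelf_h = margin, 0
        placements.append((y, x))
        x += w + margin
        shelf_h = max(shelf_h, h)
    height = y + shelf_h + margin
    if field_shape is None:
        field_shape = (height, wlim)
    elif height > field_shape[0]:
        raise PlacementError(
            f"field {field_shape} too small for {n_cells} cells (needs {height} rows)"
        )

    field = np.zeros(field_shape, dtype=float)
    meshes = []
    for i, ((r0, c0), patch, mesh) in enumerate(zip(placements, patches, meshes_p)):
        field[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += patch
        meshes.append(_offset_mesh(mesh, r0, c0, field_shape, i, 0))
    img = apply_noise(field + params.background_level, params, rng)
    frame = FluorFrame(img, pixel_size=params.pixel_size, time_min=0.0)
    return frame, meshes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time-lapse
# ---------------------------------------------------------------------------

@dataclass
class TimelapseTruth:
    """Ground truth of a simulated movie.

    ``frames``: one row per cell per frame (presence, positions, geometry).
    ``cells``: one row per cell (lineage, division frame, cluster event times;
    ``offset_true_min`` and ``lifetime_true_min`` are the grid-realized event
    times of the daughter's cluster, NaN where not applicable).
    """

    frames: pd.DataFrame
    cells: pd.DataFrame


@dataclass
class _SimCell:
    cell_id: str
    parent_id: str | None
    lane: int
    birth_time: float
    birth_length: float  # µm
    old_pole_end: int  # 0 or 1; daughters' new pole is the other end
    division_time: float  # min; inf in cephalexin mode
    # own cluster events: (appear_min, vanish_min, rel_pos kind)
    events: list = dc_field(default_factory=list)
    # pre-division mid-cell events destined for daughters: (appear, vanish, side)
    pending: list = dc_field(default_factory=list)
    birth_frame: int = 0
    division_frame: int | None = None
    t0_min: float = math.nan  # parent's division time (daughters only)
    block_time: float = math.nan  # cephalexin: when division would have completed

    def length(self, t: float, generation: float) -> float:
        return self.birth_length * 2.0 ** ((t - self.birth_time) / generation)


def _snap(x: float, interval: float) -> float:
    return round(x / interval) * interval


def _draw_daughter_events(t_div, params: SimParams, rng):
    """Cluster (appear, vanish) for the two daughters of a division at t_div."""
    out = []
    for _ in range(2):
        off = float(np.atleast_1d(params.appearance_offset_law.sample(rng, 1))[0])
        life = float(np.atleast_1d(params.lifetime_law.sample(rng, 1))[0])
        if life <= 0:
            raise ValueError("lifetime_law produced a non-positive lifetime")
        appear = t_div + _snap(off, params.frame_interval)
        if params.stable_clusters:
            vanish = math.inf
        else:
            vanish = appear + max(round(life / params.frame_interval), 1) * params.frame_interval
        out.append((appear, vanish))
    return out


def simulate_timelapse(n_founders: int, n_frames: int, params: SimParams):
    """Simulate a movie: (list of FluorFrame, meshes per frame, TimelapseTruth).

    Founders start at a uniformly random cell-cycle phase with no cluster;
    clusters arise only from division events (or, in cephalexin mode, at the
    blocked septum). Each founder occupies one horizontal lane; cells in a
    lane are re-laid out every frame around the lane center, so masks never
    overlap while neighbours grow.
    """
    if n_founders < 1 or n_frames < 1:
        raise ValueError("n_founders and n_frames must be >= 1")
    span = n_frames * params.frame_interval
    if not params.cephalexin_mode and span < params.generation_time:
        raise ValueError(
            "movie must span at least one generation unless cephalexin_mode is set"
        )
    rng = np.random.default_rng(params.seed)
    ps = params.pixel_size
    G = params.generation_time
    interval = params.frame_interval
    t_end = (n_frames - 1) * interval

    lanes: list[list[_SimCell]] = []
    cell_meta: dict[str, _SimCell] = {}
    max_span_px = 0
    for i in range(n_founders):
        B = float(np.clip(params.length_law.sample(rng, 1)[0] / 1.6, 3.0, 5.5))
        age = rng.uniform(0.0, 0.9 * G)
        c = _SimCell(
            cell_id=f"c{i:04d}", parent_id=None, lane=i,
            birth_time=-age, birth_length=B, old_pole_end=0,
            division_time=math.inf if params.cephalexin_mode else G - age,
        )
        if params.cephalexin_mode:
            t_block = G - age  # when division would have completed
            off = float(np.atleast_1d(params.appearance_offset_law.sample(rng, 1))[0])
            life = float(np.atleast_1d(params.lifetime_law.sample(rng, 1))[0])
            if life <= 0:
                raise ValueError("lifetime_law produced a non-positive lifetime")
            appear = t_block + _snap(off, interval)
            vanish = math.inf if params.stable_clusters else (
                appear + max(round(life / interval), 1) * interval)
            c.events.append((appear, vanish, "midcell"))
            c.block_time = t_block
        else:
            c.pending = _draw_daughter_events(c.division_time, params, rng)
        lanes.append([c])
        cell_meta[c.cell_id] = c
        # lane capacity: total biomass doubles every generation regardless of splits
        mass_end = B / ps * 2.0 ** ((t_end - c.birth_time) / G)
        max_span_px = max(max_span_px, int(math.ceil(mass_end)) + 8 * _GAP)

    lane_h = int(math.ceil(params.cell_width / ps)) + 1 + 2 * _PAD + 4
    field_shape = (n_founders * lane_h + 2 * _PAD, max_span_px + 4 * _PAD)
    center_col = field_shape[1] / 2.0

    frames_out, meshes_out, frame_rows = [], [], []

    for f in range(n_frames):
        t = f * interval
        # divisions: replace a cell by two daughters at the first frame t >= t_div
        for lane in lanes:
            k = 0
            while k < len(lane):
                c = lane[k]
                if t >= c.division_time and c.division_frame is None:
                    c.division_frame = f
                    half = c.length(c.division_time, G) / 2.0
                    kids = []
                    for j, side in enumerate(("L", "R")):
                        d = _SimCell(
                            cell_id=c.cell_id + side, parent_id=c.cell_id,
                            lane=c.lane, birth_time=c.division_time,
                            birth_length=half,
                            old_pole_end=0 if side == "L" else 1,
                            division_time=(c.division_time + G),
                            birth_frame=f, t0_min=c.division_time,
                        )
                        appear, vanish = c.pending[j]
                        # the daughter's cluster sits at its new pole from division on
                        if vanish > c.division_time:
                            d.events.append((max(appear, c.division_time), vanish, "newpole"))
                        d.pending = _draw_daughter_events(d.division_time, params, rng)
                        kids.append(d)
                        cell_meta[d.cell_id] = d
                    lane[k:k + 1] = kids
                    k += 2
                else:
                    k += 1

        field = np.zeros(field_shape, dtype=float)
        frame_meshes = []
        for lane_idx, lane in enumerate(lanes):
            lens_px = [max(int(round(c.length(t, G) / ps)), 3) for c in lane]
            total = sum(lens_px) + _GAP * (len(lane) - 1) + 2 * _PAD * len(lane)
            x = int(round(center_col - total / 2.0))
            r0 = _PAD + lane_idx * lane_h
            for c, lpx in zip(lane, lens_px):
                length_um = lpx * ps
                clusters = []
                for appear, vanish, kind in c.events:
                    if appear <= t < vanish:
                        pos = _POLE_POS if kind != "newpole" else (
                            _POLE_POS if c.old_pole_end == 1 else 1.0 - _POLE_POS)
                        if kind == "midcell":
                            pos = 0.5
                        clusters.append((pos, params.cluster_amplitude))
                # mother carries pre-division mid-cell spots of her daughters
                if c.pending and t < c.division_time:
                    for j, (appear, vanish) in enumerate(c.pending):
                        if appear <= t < vanish:
                            pos = 0.5 + (-_SEPTUM_OFFSET if j == 0 else _SEPTUM_OFFSET)
                            clusters.append((pos, params.cluster_amplitude))
                constriction = None
                t_div = c.division_time if not params.cephalexin_mode else c.block_time
                if math.isfinite(t_div):
                    prog = (t - (t_div - _CONSTRICTION_MIN)) / _CONSTRICTION_MIN
                    prog = min(max(prog, 0.0), 1.0)
                    if prog > 0:
                        constriction = (0.5, _CONSTRICTION_DEPTH * math.sin(math.pi / 2 * prog))
                signal, mesh = _render_signal(
                    length_um, params.cell_width, clusters, params, constriction)
                field[r0:r0 + signal.shape[0], x:x + signal.shape[1]] += signal
                frame_meshes.append(
                    _offset_mesh(mesh, r0, x, field_shape, c.cell_id, f))
                frame_rows.append({
                    "cell_id": c.cell_id, "frame": f, "time_min": t,
                    "parent_id": c.parent_id if c.parent_id else "",
                    "length_um": length_um, "old_pole_end": c.old_pole_end,
                    "cluster_present": bool(clusters),
                    "cluster_positions": ";".join(f"{p:.4f}" for p, _ in clusters),
                })
                x += signal.shape[1] + _GAP
        img = apply_noise(field + params.background_level, params, rng)
        frames_out.append(FluorFrame(img, pixel_size=ps, time_min=t))
        meshes_out.append(frame_meshes)

    cell_rows = []
    for cid, c in cell_meta.items():
        appear = vanish = math.nan
        for a, v, kind in c.events:
            appear, vanish = a, v
            break
        row = {
            "cell_id": cid, "parent_id": c.parent_id if c.parent_id else "",
            "lane": c.lane, "birth_frame": c.birth_frame,
            "division_frame": c.division_frame if c.division_frame is not None else -1,
            "old_pole_end": c.old_pole_end,
            "appear_min": appear, "vanish_min": vanish,
            "t0_min": c.t0_min,
            "offset_true_min": appear - c.t0_min if not math.isnan(c.t0_min) else math.nan,
            "lifetime_true_min": (vanish - appear) if math.isfinite(vanish) else math.nan,
        }
        cell_rows.append(row)
    truth = TimelapseTruth(frames=pd.DataFrame(frame_rows), cells=pd.DataFrame(cell_rows))
    return frames_out, meshes_out, truth


# ---------------------------------------------------------------------------
# analytic test fixtures
# ---------------------------------------------------------------------------

def polar_allocation_frame(mesh: CellMesh, polar_fraction: float, window: float = 0.1,
                           base: float = 100.0) -> FluorFrame:
    """Noise-free frame allocating an exact fraction of total signal to the poles.

    Pixels of segments whose midpoint lies within ``window`` of either pole
    get a common intensity chosen so that the polar share of the summed cell
    signal equals ``polar_fraction`` exactly; remaining pixels get ``base``.
    """
    from .geometry import segment_relative_positions

    if not 0.0 < polar_fraction < 1.0:
        raise ValueError("polar_fraction must be in (0, 1)")
    pos = segment_relative_positions(mesh)
    polar = (pos < window) | (pos > 1.0 - window)
    n_polar = sum(int(mesh.segments[i].size) for i in np.flatnonzero(polar))
    n_body = sum(int(mesh.segments[i].size) for i in np.flatnonzero(~polar))
    if n_polar == 0 or n_body == 0:
        raise ValueError("mesh has no polar or no body segments at this window")
    a = polar_fraction * base * n_body / ((1.0 - polar_fraction) * n_polar)
    img = np.zeros(mesh.image_shape, dtype=float).ravel()
    for i, seg in enumerate(mesh.segments):
        img[seg] = a if polar[i] else base
    return FluorFrame(img.reshape(mesh.image_shape), pixel_size=mesh.pixel_size,
                      background_corrected=True)
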