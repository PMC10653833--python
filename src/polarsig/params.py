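"""Parameter containers: detection thresholds, simulation settings, sampling laws.

``DetectionParams`` holds every threshold of the analysis: the 0.75 normalized
intensity cut and the <10% fraction cut of the narrow-peak cluster criterion,
the polar and mid-cell windows on relative cell length, the 6.5 µm short/long
split, and the persistence requirement for time-lapse scoring.

``SimParams`` holds the synthetic-microscopy study conditions. Defaults model
slow-growing rod-shaped bacteria (generation time 330 min, i.e. 5–6 h) imaged
at 0.065 µm/px with an sCMOS-like noise model, and transient polar clusters
that become visible ~20 min after completion of cytokinesis and persist ~70 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Law", "DetectionParams", "SimParams"]


@dataclass(frozen=True)
class Law:
    """A one-dimensional sampling law.

    kinds
    -----
    point(v)            degenerate distribution at v
    normal(mu, sd)      Gaussian
    normal_pos(mu, sd)  Gaussian truncated to (0, inf) by resampling
    lognormal(mu, sd)   exp(Normal(mu, sd)); mu/sd on the log scale
    uniform(lo, hi)
    """

    kind: str
    args: tuple

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "point":
            (v,) = self.args
            return np.full(size, float(v)) if size is not None else float(v)
        if self.kind == "normal":
            mu, sd = self.args
            return rng.normal(mu, sd, size)
        if self.kind == "normal_pos":
            mu, sd = self.args
            out = np.atleast_1d(rng.normal(mu, sd, size if size is not None else 1))
            bad = out <= 0
            while bad.any():
                out[bad] = rng.normal(mu, sd, int(bad.sum()))
                bad = out <= 0
            return out if size is not None else float(out[0])
        if self.kind == "lognormal":
            mu, sd = self.args
            return rng.lognormal(mu, sd, size)
        if self.kind == "uniform":
            lo, hi = self.args
            return rng.uniform(lo, hi, size)
        raise ValueError(f"unknown law kind: {self.kind!r}")

    def validate(self) -> None:
        if self.kind not in {"point", "normal", "normal_pos", "lognormal", "uniform"}:
            raise ValueError(f"unknown law kind: {self.kind!r}")
        if self.kind in {"normal", "normal_pos", "lognormal"} and self.args[1] < 0:
            raise ValueError(f"{self.kind} law requires sd >= 0")
        if self.kind == "point" and self.args[0] is None:
            raise ValueError("point law requires a value")

    @staticmethod
    def from_spec(spec) -> "Law":
        """Build a Law from ``Law``, ``(kind, *args)`` tuple/list, or scalar (point)."""
        if isinstance(spec, Law):
            return spec
        if isinstance(spec, (int, float)):
            return Law("point", (float(spec),))
        if isinstance(spec, (tuple, list)) and spec:
            return Law(str(spec[0]), tuple(float(a) for a in spec[1:]))
        raise ValueError(f"cannot interpret law spec: {spec!r}")


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the cluster analysis.

    A cell is called cluster-positive when strictly fewer than
    ``fraction_threshold`` of its per-segment maximum intensities (normalized
    to the cell maximum) lie strictly above ``intensity_threshold`` — an
    intense and narrow fluorescence peak.
    """

    intensity_threshold: float = 0.75
    fraction_threshold: float = 0.10
    polar_window: float = 0.10
    midcell_window: tuple[float, float] = (0.40, 0.60)
    length_cutoff: float = 6.5  # µm; short < cutoff <= long
    min_consecutive_frames: int = 2
    denominator: str = "all"  # "all" segments or "nonzero" segments

    def __post_init__(self):
        if not 0.0 < self.intensity_threshold < 1.0:
            raise ValueError("intensity_threshold must be in (0, 1)")
        if not 0.0 < self.fraction_threshold < 1.0:
            raise ValueError("fraction_threshold must be in (0, 1)")
        lo, hi = self.midcell_window
        for v in (self.polar_window, lo, hi):
            if not 0.0 <= v <= 1.0:
                raise ValueError("windows must lie within [0, 1]")
        if lo >= hi:
            raise ValueError("midcell_window must be (lo, hi) with lo < hi")
        if self.length_cutoff <= 0:
            raise ValueError("length_cutoff must be positive")
        if self.min_consecutive_frames < 1:
            raise ValueError("min_consecutive_frames must be >= 1")
        if self.denominator not in {"all", "nonzero"}:
            raise ValueError("denominator must be 'all' or 'nonzero'")

    def replace(self, **kw) -> "DetectionParams":
        return replace(self, **kw)


#: default pattern mixture over snapshot cells
DEFAULT_PATTERN_PROBS = {"bipolar": 0.60, "unipolar": 0.25, "midcell": 0.0, "none": 0.15}

PATTERNS = ("bipolar", "unipolar", "midcell", "none")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic microscopy generator.

    Intensities are linear camera units (a.u.). Noise is Poisson on the
    composited signal plus additive Gaussian read noise. ``cluster_amplitude``
    defaults to roughly five times the per-pixel noise standard deviation on
    envelope signal — clusters are faint but resolvable by the narrow-peak
    criterion.
    """

    pixel_size: float = 0.065  # µm/px
    cell_width: float = 0.7  # µm
    length_law: Law = field(default_factory=lambda: Law("lognormal", (math.log(5.5), 0.28)))
    length_bounds: tuple[float, float] = (3.0, 12.0)  # µm, clip of length_law
    envelope_intensity: float = 100.0  # a.u. at the membrane
    cluster_amplitude: float = 122.0  # a.u. added at spot peak (5x noise sd)
    cluster_sigma: float = 0.1  # µm axial; a diffraction-limited focus
    background_level: float = 100.0  # a.u.
    poisson_noise: bool = True
    read_noise_sd: float = 20.0  # a.u., additive Gaussian
    pattern_probs: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_PROBS))
    frame_interval: float = 10.0  # min
    generation_time: float = 330.0  # min (5-6 h)
    appearance_offset_law: Law = field(default_factory=lambda: Law("normal", (20.0, 15.0)))
    lifetime_law: Law = field(default_factory=lambda: Law("normal_pos", (70.0, 20.0)))
    cephalexin_mode: bool = False  # division blocked, growth continues
    stable_clusters: bool = False  # clusters never disappear once present
    field_shape: tuple[int, int] | None = None  # (rows, cols); auto-sized if None
    seed: int = 0

    def __post_init__(self):
        for name in ("envelope_intensity", "cluster_amplitude", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size <= 0 or self.cell_width <= 0 or self.cluster_sigma <= 0:
            raise ValueError("pixel_size, cell_width, cluster_sigma must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        probs = self.pattern_probs
        if set(probs) - set(PATTERNS):
            raise ValueError(f"pattern_probs keys must be among {PATTERNS}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("pattern probabilities must be >= 0")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_probs must sum to 1")
        self.length_law.validate()
        self.appearance_offset_law.validate()
        self.lifetime_law.validate()

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)

    def prob_vector(self):
        return np.array([self.pattern_probs.get(p, 0.0) for p in PATTERNS])
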