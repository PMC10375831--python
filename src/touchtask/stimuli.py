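"""Parametric visual stimuli: drifting gratings, solid fields, images.

Stimuli are pure luminance generators: given a spec, a time and a target
region they return a ``StimulusFrame`` whose pixel values lie in [0, 1].
Protocols interact only with the :class:`Stimulus` lifecycle contract
(show / hide / update / next_trial / frame), never with concrete
generators, so user-defined stimuli plug in through the registry.

Orientation convention: 0 deg = vertical bars drifting horizontally,
which matches the left/right choice axis of the 2AFC task. Spatial
frequency is in cycles per degree of visual angle; since a freely moving
subject has no fixed viewing distance, the pixels-per-degree conversion
is an explicit, nominal config (default 10 px/deg).
"""

from __future__ import annotations

import math
from typing import Callable, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class StimulusSpec(BaseModel):
    """Parametric description of a visual stimulus.

    Only the fields relevant to ``kind`` are required:

    * ``grating``: contrast, spatial_freq (>0), drift_freq, orientation,
      mean_luminance, px_per_degree
    * ``solid``: mean_luminance (optionally color_rgb for display)
    * ``image``: image_path
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["grating", "solid", "image"]
    contrast: float = Field(default=1.0, ge=0.0, le=1.0)
    spatial_freq: float = Field(default=0.0, description="cycles per degree")
    drift_freq: float = Field(default=0.0, ge=0.0, description="Hz")
    orientation: float = Field(default=0.0, description="degrees")
    mean_luminance: float = Field(default=0.5, ge=0.0, le=1.0)
    color_rgb: Optional[tuple[int, int, int]] = None
    image_path: Optional[str] = None
    px_per_degree: float = Field(default=10.0, gt=0.0)

    @model_validator(mode="after")
    def _check_kind_fields(self) -> "StimulusSpec":
        if self.kind == "grating" and self.spatial_freq <= 0:
            raise ValueError("grating spec requires spatial_freq > 0")
        if self.kind == "image" and not self.image_path:
            raise ValueError("image spec requires image_path")
        if self.color_rgb is not None:
            if not all(0 <= c <= 255 for c in self.color_rgb):
                raise ValueError("color_rgb components must lie in [0, 255]")
        return self


class StimulusFrame(BaseModel):
    """A rendered luminance field (height x width) for one point in time."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    pixels: np.ndarray
    t: float

    @model_validator(mode="after")
    def _check_bounds(self) -> "StimulusFrame":
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame pixels must be a non-empty 2-D grid")
        if float(self.pixels.min()) < 0.0 or float(self.pixels.max()) > 1.0:
            raise ValueError("frame luminance values must lie in [0, 1]")
        return self


def _check_region(region: tuple[int, int]) -> tuple[int, int]:
    w, h = region
    if w <= 0 or h <= 0:
        raise ValueError(f"stimulus region must be non-empty, got {w}x{h}")
    return w, h


def grating_frame(spec: StimulusSpec, t: float, region: tuple[int, int]) -> StimulusFrame:
    """Render one frame of a drifting sinusoidal grating.

    luminance(x, y, t) = L * (1 + c * sin(2*pi*(f_s * x' - f_t * t)))
    clipped to [0, 1], where x' is the position along the orientation
    axis in degrees, f_s the spatial frequency (cyc/deg) and f_t the
    drift frequency (Hz). Deterministic in (spec, t).
    """
    if spec.kind != "grating":
        raise ValueError(f"grating_frame requires kind='grating', got {spec.kind!r}")
    w, h = _check_region(region)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    theta = math.radians(spec.orientation)
    # axis position in degrees of visual angle
    xprime = (math.cos(theta) * xx + math.sin(theta) * yy) / spec.px_per_degree
    phase = 2.0 * math.pi * (spec.spatial_freq * xprime - spec.drift_freq * t)
    lum = spec.mean_luminance * (1.0 + spec.contrast * np.sin(phase))
    return StimulusFrame(pixels=np.clip(lum, 0.0, 1.0), t=t)


def solid_frame(spec: StimulusSpec, region: tuple[int, int], t: float = 0.0) -> StimulusFrame:
    """Render a uniform field at the spec's mean luminance.

    The isoluminant-gray distractor preset simply shares the grating's
    mean luminance so that brightness alone cannot guide choice.
    """
    if spec.kind != "solid":
        raise ValueError(f"solid_frame requires kind='solid', got {spec.kind!r}")
    w, h = _check_region(region)
    return StimulusFrame(pixels=np.full((h, w), spec.mean_luminance, dtype=float), t=t)


def _image_luminance(spec: StimulusSpec, region: tuple[int, int]) -> np.ndarray:
    """Load a PNG once, normalize to [0,1] luminance and letterbox to region."""
    from PIL import Image

    w, h = _check_region(region)
    with Image.open(spec.image_path) as img:
        gray = np.asarray(img.convert("L"), dtype=float) / 255.0
    ih, iw = gray.shape
    scale = min(w / iw, h / ih)
    tw, th = max(1, int(iw * scale)), max(1, int(ih * scale))
    # nearest-neighbour resample; aspect preserved, letterboxed with black
    rows = (np.arange(th) / scale).astype(int).clip(0, ih - 1)
    cols = (np.arange(tw) / scale).astype(int).clip(0, iw - 1)
    scaled = gray[np.ix_(rows, cols)]
    out = np.zeros((h, w), dtype=float)
    y0, x0 = (h - th) // 2, (w - tw) // 2
    out[y0 : y0 + th, x0 : x0 + tw] = scaled
    return out


class MonotonicityError(RuntimeError):
    """Raised when a stimulus is updated with a time earlier than its last."""


class UnknownStimulusError(KeyError):
    """Raised for a spec kind with no registered generator."""


class Stimulus:
    """Lifecycle wrapper around a frame generator.

    Protocols call only this contract: ``show()``, ``hide()``,
    ``update(t)``, ``next_trial(params)`` and ``frame(t, region)``.
    While hidden, frame requests return the background (solid black).
    ``update`` enforces a monotone timeline.
    """

    def __init__(self, spec: StimulusSpec, renderer: Callable[[StimulusSpec, float, tuple[int, int]], StimulusFrame]):
        self.spec = spec
        self._renderer = renderer
        self.visible = False
        self._t = 0.0

    def show(self) -> None:
        self.visible = True

    def hide(self) -> None:
        self.visible = False

    def update(self, t: float) -> None:
        if t < self._t:
            raise MonotonicityError(
                f"stimulus time must be non-decreasing: {t} < {self._t}"
            )
        self._t = t

    def next_trial(self, params: Optional[dict] = None) -> None:
        """Apply between-trial spec modifications (e.g. a new contrast)."""
        if params:
            self.spec = self.spec.model_copy(update=params)
        self._t = 0.0

    def frame(self, t: float, region: tuple[int, int]) -> StimulusFrame:
        self.update(t)
        if not self.visible:
            w, h = _check_region(region)
            return StimulusFrame(pixels=np.zeros((h, w), dtype=float), t=t)
        return self._renderer(self.spec, t, region)


def _render_grating(spec: StimulusSpec, t: float, region: tuple[int, int]) -> StimulusFrame:
    return grating_frame(spec, t, region)


def _render_solid(spec: StimulusSpec, t: float, region: tuple[int, int]) -> StimulusFrame:
    return solid_frame(spec, region, t)


class _ImageRenderer:
    def __init__(self) -> None:
        self._cache: dict[tuple[str, tuple[int, int]], np.ndarray] = {}

    def __call__(self, spec: StimulusSpec, t: float, region: tuple[int, int]) -> StimulusFrame:
        key = (str(spec.image_path), tuple(region))
        if key not in self._cache:
            self._cache[key] = _image_luminance(spec, region)
        return StimulusFrame(pixels=self._cache[key], t=t)


_REGISTRY: dict[str, Callable] = {
    "grating": _render_grating,
    "solid": _render_solid,
    "image": _ImageRenderer(),
}


def registered_kinds() -> list[str]:
    return sorted(_REGISTRY)


def register_stimulus(kind: str, renderer: Callable) -> None:
    """Register a user-defined frame generator under a new kind name."""
    _REGISTRY[kind] = renderer


def create_stimulus(spec: StimulusSpec) -> Stimulus:
    """Construct a lifecycle stimulus instance from its spec (registry lookup)."""
    try:
        renderer = _REGISTRY[spec.kind]
    except KeyError:
        raise UnknownStimulusError(
            f"unknown stimulus kind {spec.kind!r}; available: {registered_kinds()}"
        ) from None
    return Stimulus(spec, renderer)


# Out-of-box specs used by the shipped protocols.

def grating_preset(**overrides) -> StimulusSpec:
    """Default target: full-contrast drifting grating, 1 Hz, 30 cyc/deg."""
    params = dict(
        kind="grating",
        contrast=1.0,
        spatial_freq=30.0,
        drift_freq=1.0,
        orientation=0.0,
        mean_luminance=0.5,
    )
    params.update(overrides)
    return StimulusSpec(**params)


def gray_preset(**overrides) -> StimulusSpec:
    """Isoluminant gray distractor: uniform field at the grating's mean."""
    params = dict(kind="solid", mean_luminance=0.5)
    params.update(overrides)
    return StimulusSpec(**params)


def black_preset() -> StimulusSpec:
    """Default background: solid black screen."""
    return StimulusSpec(kind="solid", mean_luminance=0.0)
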