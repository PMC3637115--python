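"""Synthetic fluorescence stills and time-lapse sequences with full ground truth.

The generator emulates the two ingredients the analysis assumes:

* **Still scenes** containing discrete cell-shaped fluorescent objects of two
  geometry classes on a noisy 8-bit background — rounded *signet* blobs
  (high circularity, rendered as superellipses) and elongated *spindle*
  bodies with tapering Y-like arms (low circularity). Default geometry is a
  764×560 pixel frame at 0.5 μm/pixel, so 30-90 μm cells span realistic
  pixel counts.
* **Time-lapse sequences** in which nucleus-like blobs execute a persistent
  random walk: per 12-hour segment, a step length is drawn from a normal law
  truncated symmetrically to [0, 2·step_mean] (so the population mean step is
  exactly ``step_mean``) and a direction correlated with the previous
  segment's; positions are interpolated linearly to the 10-minute frame
  cadence. Frames are rendered lazily so long sequences stay cheap.

Every stochastic output is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.stats import truncnorm
from skimage import draw

from . import morpho, segment
from .errors import OverlapError, ParameterError, ResolutionError
from .segment import CalibratedImage

__all__ = [
    "ShapeSpec",
    "SceneTruth",
    "MotilitySpec",
    "RealizedShape",
    "RenderedObject",
    "RenderedScene",
    "SyntheticTimelapse",
    "make_cell_mask",
    "render_scene",
    "make_timelapse",
    "sample_group_measurements",
    "random_shape_spec",
    "random_scene_truth",
]

#: boundary between the spindle and signet circularity regimes
CLASS_CIRCULARITY_SPLIT = 0.45
#: hours per motility segment; step statistics are parameterized per segment
SEGMENT_HOURS = 12.0
#: minimum rendered max-feret extent, in pixels
MIN_FERET_PX = 8.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """Target geometry of one synthetic fluorescent object.

    ``centre`` and ``target_feret`` are in μm; ``centre`` uses (x, y) axes
    where x runs along columns and y along rows. ``target_circularity`` is
    the intended orthogonal/feret ratio; spindle specs must lie below
    0.45 and signet specs at or above it, so the two classes stay separated.
    """

    geometry_class: str
    target_feret: float
    target_circularity: float
    centre: tuple[float, float]
    orientation: float = 0.0
    peak_intensity: int = 200

    def __post_init__(self) -> None:
        if self.geometry_class not in ("spindle", "signet"):
            raise ParameterError("geometry_class must be 'spindle' or 'signet'")
        if not (self.target_feret > 0):
            raise ParameterError("target_feret must be positive")
        if not (0 < self.target_circularity <= 1):
            raise ParameterError("target_circularity must be in (0, 1]")
        if self.geometry_class == "spindle" and self.target_circularity >= CLASS_CIRCULARITY_SPLIT:
            raise ParameterError("spindle specs require target_circularity < 0.45")
        if self.geometry_class == "signet" and self.target_circularity < CLASS_CIRCULARITY_SPLIT:
            raise ParameterError("signet specs require target_circularity >= 0.45")
        if not (1 <= int(self.peak_intensity) <= 255):
            raise ParameterError("peak_intensity must be an integer in [1, 255]")


@dataclass(frozen=True)
class SceneTruth:
    """Generating description of one synthetic still image."""

    shape_specs: tuple[ShapeSpec, ...]
    image_dims: tuple[int, int] = (764, 560)   # (rows, cols)
    pixel_size: float = 0.5                    # μm/pixel
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape_specs", tuple(self.shape_specs))
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if any(d < 8 for d in self.image_dims):
            raise ParameterError("image_dims too small")


@dataclass(frozen=True)
class MotilitySpec:
    """Population parameters of a synthetic time-lapse experiment.

    ``step_mean``/``step_sd`` parameterize the per-12-hour-segment step
    length (μm); ``persistence`` in [0, 1] sets the directional correlation
    between consecutive segments (0 = fresh uniform direction each segment,
    1 = straight-line motion).
    """

    n_cells: int
    duration: float = 72.0          # hours
    frame_interval: float = 10.0    # minutes
    step_mean: float = 30.0         # μm per 12-h segment
    step_sd: float = 10.0           # μm per 12-h segment
    persistence: float = 0.3
    nucleus_radius: float = 5.0     # μm

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ParameterError("duration and frame_interval must be positive")
        if self.step_mean <= 0 or self.step_sd < 0:
            raise ParameterError("step_mean must be > 0 and step_sd >= 0")
        if not (0 <= self.persistence <= 1):
            raise ParameterError("persistence must be in [0, 1]")
        if self.nucleus_radius <= 0:
            raise ParameterError("nucleus_radius must be positive")
        seg_min = SEGMENT_HOURS * 60.0
        if abs(round(seg_min / self.frame_interval) - seg_min / self.frame_interval) > 1e-9:
            raise ParameterError("frame_interval must divide the 12-h segment")
        n_seg = self.duration / SEGMENT_HOURS
        if abs(round(n_seg) - n_seg) > 1e-9:
            raise ParameterError("duration must be a whole number of 12-h segments")

    @property
    def n_segments(self) -> int:
        return int(round(self.duration / SEGMENT_HOURS))


# ---------------------------------------------------------------------------
# still scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RealizedShape:
    """Ground-truth indices of a rendered mask, measured by the morphometry
    module itself so that generator tolerances are stated in the same metric
    the analysis reports."""

    feret: float         # μm
    orthogonal: float    # μm
    circularity: float
    perimeter: float     # μm
    area: float          # μm²
    area_px: int


def _measure_mask(mask: np.ndarray, pixel_size: float) -> RealizedShape:
    rois = segment.detect_objects(mask, 1)
    if len(rois) != 1:
        raise AssertionError(f"rendered mask has {len(rois)} components, expected 1")
    roi = rois[0]
    feret, orth = morpho.feret_diameters(roi, pixel_size)
    per = morpho.perimeter(roi, pixel_size)
    ar = morpho.area(roi, pixel_size)
    return RealizedShape(
        feret=feret,
        orthogonal=orth,
        circularity=morpho.circularity_index(feret, orth),
        perimeter=per,
        area=ar,
        area_px=roi.area_px,
    )


def _signet_mask(canvas: int, feret_px: float, circ: float, theta: float) -> np.ndarray:
    """Rounded blob: superellipse with semi-axes feret/2 and circ·feret/2."""
    a = feret_px / 2.0
    b = circ * a
    # exponent 2 (ellipse): exponents > 2 bulge along the diagonals, which
    # shifts the max caliper off the major axis and breaks feret = 2a
    n = 2.0
    c = (canvas - 1) / 2.0
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(np.float64)
    x = xx - c
    y = yy - c
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    return (np.abs(u / a) ** n + np.abs(v / b) ** n) <= 1.0


def _tapered_limb(p0: np.ndarray, p1: np.ndarray, w0: float, n_pts: int = 24) -> np.ndarray:
    """Polygon of a limb whose half-width tapers from w0 at p0 to 0 at p1."""
    s = np.linspace(0.0, 1.0, n_pts)
    centre = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    d = p1 - p0
    norm = np.hypot(*d)
    perp = np.array([-d[1], d[0]]) / norm
    half = w0 * (1.0 - s) ** 0.6
    upper = centre + half[:, None] * perp[None, :]
    lower = centre - half[:, None] * perp[None, :]
    return np.vstack([upper, lower[::-1]])


def _spindle_mask(canvas: int, feret_px: float, circ: float, theta: float) -> np.ndarray:
    """Elongated Y-like body: a tapering tail plus two tapering arms.

    In body coordinates the tail tip sits at (-F/2, 0) and the two arm tips
    at (F/2, ±circ·F/2), so the max caliper runs tail→tip and the extent
    perpendicular to it is close to circ·F.
    """
    F = feret_px
    w0 = max(2.0, 0.055 * F)        # half-width of the body at the branch
    branch = np.array([0.10 * F, 0.0])
    tail_tip = np.array([-F / 2.0, 0.0])
    arm_tips = [np.array([F / 2.0, s * circ * F / 2.0]) for s in (+1.0, -1.0)]

    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    c = (canvas - 1) / 2.0
    mask = np.zeros((canvas, canvas), dtype=bool)
    for tip in [tail_tip, *arm_tips]:
        poly = _tapered_limb(branch, tip, w0)
        xy = poly @ rot.T  # body (u, v) -> image (x, y)
        rr, cc = draw.polygon(xy[:, 1] + c, xy[:, 0] + c, shape=mask.shape)
        mask[rr, cc] = True
    # small disk at the branch point guarantees 8-connectivity of the limbs
    bx, by = rot @ branch
    rr, cc = draw.disk((by + c, bx + c), w0, shape=mask.shape)
    mask[rr, cc] = True
    return mask


def make_cell_mask(spec: ShapeSpec, pixel_size: float) -> tuple[np.ndarray, RealizedShape]:
    """Rasterize one cell shape and measure its realized ground truth.

    Returns a square boolean mask (a single 8-connected component, shape
    centred) together with the realized morphometric indices measured by the
    same segmentation + morphometry code the analysis uses, so the generator
    tolerances (feret within 5 % of target, circularity within 0.1) are
    checked in the reported metric.

    Raises
    ------
    ResolutionError
        If the target feret spans fewer than 8 pixels at this pixel size.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    feret_px = spec.target_feret / pixel_size
    if feret_px < MIN_FERET_PX:
        raise ResolutionError(
            f"target feret spans {feret_px:.1f} px (< {MIN_FERET_PX:.0f}); "
            "increase the feret or reduce the pixel size"
        )
    canvas = 2 * math.ceil(feret_px / 2.0 + 3) + 1
    if spec.geometry_class == "signet":
        mask = _signet_mask(canvas, feret_px, spec.target_circularity, spec.orientation)
    else:
        mask = _spindle_mask(canvas, feret_px, spec.target_circularity, spec.orientation)
    return mask, _measure_mask(mask, pixel_size)


@dataclass(frozen=True)
class RenderedObject:
    """One object placed in a rendered scene: generating spec, realized
    ground-truth indices and the pixel footprint actually drawn."""

    spec: ShapeSpec
    realized: RealizedShape
    pixels: np.ndarray            # (n, 2) int (row, col) in scene coordinates

    @property
    def centroid_px(self) -> tuple[float, float]:
        return float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean())


@dataclass(frozen=True)
class RenderedScene:
    """A rendered synthetic still plus its per-object ground truth."""

    image: CalibratedImage
    objects: tuple[RenderedObject, ...]
    truth: SceneTruth


def render_scene(
    truth: SceneTruth,
    background_mean: float = 10.0,
    background_sd: float = 3.0,
    seed: int | None = None,
) -> RenderedScene:
    """Render a still image from a scene description.

    Background pixels are additive truncated-Gaussian noise (clipped to
    [0, 255]); object pixels are set to each spec's ``peak_intensity``
    (noise-free signal). Object footprints must be pairwise disjoint and lie
    fully inside the frame — each fluorescent object is a discrete ROI.

    ``seed`` defaults to ``truth.seed``; identical truth + seed give a
    bit-identical image.
    """
    if seed is None:
        seed = truth.seed
    if truth.shape_specs and background_mean >= min(s.peak_intensity for s in truth.shape_specs):
        raise ParameterError("background_mean must stay below every peak_intensity")
    if background_mean < 0 or background_sd < 0:
        raise ParameterError("background parameters must be nonnegative")

    rows, cols = truth.image_dims
    rng = np.random.default_rng(seed)
    bg = rng.normal(background_mean, background_sd, size=(rows, cols))
    canvas = np.clip(np.round(bg), 0, 255).astype(np.uint8)

    occupied = np.zeros((rows, cols), dtype=bool)
    placed: list[RenderedObject] = []
    for k, spec in enumerate(truth.shape_specs):
        mask, realized = make_cell_mask(spec, truth.pixel_size)
        size = mask.shape[0]
        cx, cy = spec.centre
        r0 = int(round(cy / truth.pixel_size - (size - 1) / 2.0))
        c0 = int(round(cx / truth.pixel_size - (size - 1) / 2.0))
        rr, cc = np.nonzero(mask)
        rr = rr + r0
        cc = cc + c0
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= rows or cc.max() >= cols:
            raise ParameterError(f"object {k} footprint extends outside the image bounds")
        if occupied[rr, cc].any():
            raise OverlapError(f"object {k} overlaps a previously placed object")
        occupied[rr, cc] = True
        canvas[rr, cc] = int(spec.peak_intensity)
        placed.append(
            RenderedObject(spec=spec, realized=realized,
                           pixels=np.column_stack([rr, cc]).astype(np.intp))
        )
    image = CalibratedImage(intensity=canvas, pixel_size=truth.pixel_size)
    return RenderedScene(image=image, objects=tuple(placed), truth=truth)


#: default per-class parameter ranges for randomly drawn specs:
#: (feret_lo, feret_hi) μm and (circularity_lo, circularity_hi)
SPINDLE_FERET_RANGE = (45.0, 75.0)
SPINDLE_CIRC_RANGE = (0.15, 0.40)
SIGNET_FERET_RANGE = (28.0, 42.0)
SIGNET_CIRC_RANGE = (0.55, 0.90)


def random_shape_spec(
    geometry_class: str,
    rng: np.random.Generator,
    centre: tuple[float, float] = (0.0, 0.0),
) -> ShapeSpec:
    """Draw one spec from the default parameter range of its class."""
    if geometry_class == "spindle":
        flo, fhi = SPINDLE_FERET_RANGE
        clo, chi = SPINDLE_CIRC_RANGE
    else:
        flo, fhi = SIGNET_FERET_RANGE
        clo, chi = SIGNET_CIRC_RANGE
    return ShapeSpec(
        geometry_class=geometry_class,
        target_feret=float(rng.uniform(flo, fhi)),
        target_circularity=float(rng.uniform(clo, chi)),
        centre=centre,
        orientation=float(rng.uniform(0.0, math.pi)),
        peak_intensity=int(rng.integers(150, 231)),
    )


def random_scene_truth(
    n_spindle: int,
    n_signet: int,
    image_dims: tuple[int, int] = (764, 560),
    pixel_size: float = 0.5,
    seed: int = 0,
) -> SceneTruth:
    """Non-overlapping random specs of both classes on a jittered grid.

    Cells are spaced by at least the largest possible rendering canvas, so
    footprints are guaranteed disjoint and fully in frame.
    """
    n = n_spindle + n_signet
    if n < 1:
        raise ParameterError("need at least one object")
    rng = np.random.default_rng(seed)
    rows, cols = image_dims
    width = cols * pixel_size
    height = rows * pixel_size
    max_feret = max(SPINDLE_FERET_RANGE[1], SIGNET_FERET_RANGE[1])
    canvas_um = max_feret + 8 * pixel_size        # rendering canvas edge
    margin = canvas_um / 2.0
    ncols = max(1, math.ceil(math.sqrt(n * width / height)))
    nrows = math.ceil(n / ncols)
    xs = np.linspace(margin, width - margin, ncols) if ncols > 1 else [width / 2]
    ys = np.linspace(margin, height - margin, nrows) if nrows > 1 else [height / 2]
    spacing = min(
        xs[1] - xs[0] if ncols > 1 else width,
        ys[1] - ys[0] if nrows > 1 else height,
    )
    if spacing < canvas_um:
        raise ParameterError(
            f"{n} objects do not fit without overlap in a "
            f"{width:.0f}×{height:.0f} μm frame"
        )
    sites = [(float(x), float(y)) for y in ys for x in xs][:n]
    jit = (spacing - canvas_um) / 2.0
    classes = ["spindle"] * n_spindle + ["signet"] * n_signet
    rng.shuffle(classes)
    specs = []
    for (x, y), cls in zip(sites, classes):
        dx, dy = rng.uniform(-jit, jit, size=2) if jit > 0 else (0.0, 0.0)
        cx = float(np.clip(x + dx, margin, width - margin))
        cy = float(np.clip(y + dy, margin, height - margin))
        specs.append(random_shape_spec(cls, rng, centre=(cx, cy)))
    return SceneTruth(shape_specs=tuple(specs), image_dims=image_dims,
                      pixel_size=pixel_size, seed=seed)


# ---------------------------------------------------------------------------
# time-lapse sequences
# ---------------------------------------------------------------------------

def _truncated_steps(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Step lengths ~ normal(mean, sd) truncated symmetrically to [0, 2·mean].

    The symmetric truncation keeps the population mean exactly ``mean``, so
    the expected 12-h-sampled path length over k segments is exactly k·mean.
    """
    if sd == 0:
        return np.full(size, mean, dtype=np.float64)
    a = (0.0 - mean) / sd
    b = (2.0 * mean - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


class SyntheticTimelapse:
    """Lazy synthetic time-lapse: full ground truth up front, frames rendered
    on demand (each frame is deterministic in ``(seed, frame_index)``, so any
    access order yields identical pixels).

    Attributes
    ----------
    positions_um : ndarray (n_frames, n_cells, 2)
        Ground-truth nucleus centres at every frame, (x, y) in μm.
    """

    def __init__(
        self,
        spec: MotilitySpec,
        dims: tuple[int, int],
        pixel_size: float,
        seed: int,
        positions_um: np.ndarray,
        nucleus_intensity: int = 220,
        background: tuple[float, float] = (10.0, 3.0),
    ) -> None:
        self.spec = spec
        self.dims = dims
        self.pixel_size = pixel_size
        self.seed = seed
        self.positions_um = positions_um
        self.nucleus_intensity = int(nucleus_intensity)
        self.background = background
        self.frame_interval_min = spec.frame_interval
        self.duration_h = spec.duration

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions_um.shape[1]

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, index: int) -> CalibratedImage:
        if not (0 <= index < self.n_frames):
            raise ParameterError(f"frame index {index} out of range")
        rows, cols = self.dims
        rng = np.random.default_rng([self.seed, 1_000_003 + index])
        bg = rng.normal(self.background[0], self.background[1], size=(rows, cols))
        canvas = np.clip(np.round(bg), 0, 255).astype(np.uint8)
        r_px = self.spec.nucleus_radius / self.pixel_size
        for x_um, y_um in self.positions_um[index]:
            rr, cc = draw.disk(
                (y_um / self.pixel_size, x_um / self.pixel_size), r_px,
                shape=(rows, cols),
            )
            canvas[rr, cc] = self.nucleus_intensity
        return CalibratedImage(intensity=canvas, pixel_size=self.pixel_size)

    def __getitem__(self, index: int) -> CalibratedImage:
        return self.frame(index)

    def __iter__(self) -> Iterator[CalibratedImage]:
        return (self.frame(i) for i in range(self.n_frames))

    def truth_positions(self, interval_h: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (times_h, positions) sampled every ``interval_h``
        hours (all frames when None)."""
        if interval_h is None:
            return self.times_h, self.positions_um
        stride_f = interval_h * 60.0 / self.frame_interval_min
        stride = int(round(stride_f))
        if abs(stride - stride_f) > 1e-9 or stride < 1:
            raise ParameterError("interval_h must be a multiple of the frame cadence")
        idx = np.arange(0, self.n_frames, stride)
        return self.times_h[idx], self.positions_um[idx]

    def true_path_lengths(self, interval_h: float = SEGMENT_HOURS) -> np.ndarray:
        """Per-cell path length (μm) over the positions sampled every
        ``interval_h`` hours."""
        _, pos = self.truth_positions(interval_h)
        steps = np.diff(pos, axis=0)
        return np.linalg.norm(steps, axis=2).sum(axis=0)


def _grid_starts(
    n_cells: int, width_um: float, height_um: float, margin_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered grid of start positions, keeping cells well separated."""
    ncols = max(1, math.ceil(math.sqrt(n_cells * width_um / height_um)))
    nrows = math.ceil(n_cells / ncols)
    xs = np.linspace(margin_um, width_um - margin_um, max(ncols, 2))[:ncols] \
        if ncols > 1 else np.array([width_um / 2.0])
    ys = np.linspace(margin_um, height_um - margin_um, max(nrows, 2))[:nrows] \
        if nrows > 1 else np.array([height_um / 2.0])
    spacing = min(
        xs[1] - xs[0] if ncols > 1 else width_um,
        ys[1] - ys[0] if nrows > 1 else height_um,
    )
    pts = [(x, y) for y in ys for x in xs][:n_cells]
    jitter = rng.uniform(-spacing / 10.0, spacing / 10.0, size=(n_cells, 2))
    starts = np.asarray(pts, dtype=np.float64) + jitter
    lo = np.array([margin_um, margin_um])
    hi = np.array([width_um - margin_um, height_um - margin_um])
    return np.clip(starts, lo, hi)


def make_timelapse(
    spec: MotilitySpec,
    dims: tuple[int, int] = (764, 560),
    pixel_size: float = 0.5,
    seed: int = 0,
    nucleus_intensity: int = 220,
    background: tuple[float, float] = (10.0, 3.0),
) -> SyntheticTimelapse:
    """Simulate a time-lapse of nucleus-like blobs on a persistent random walk.

    Each cell draws one step per 12-h segment (length from the symmetric
    truncated normal, direction correlated with the previous segment's by
    ``spec.persistence``); positions are interpolated linearly to the frame
    cadence, so the 12-h-sampled path length equals the sum of the drawn step
    lengths exactly. Proposed segment endpoints falling outside the frame
    margin are redrawn, which keeps every nucleus fully in frame for the
    whole recording.

    Raises
    ------
    ResolutionError
        If the nucleus radius spans fewer than 2 pixels.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    if spec.nucleus_radius / pixel_size < 2.0:
        raise ResolutionError("nucleus_radius must span at least 2 pixels")
    rows, cols = dims
    width_um = cols * pixel_size
    height_um = rows * pixel_size
    margin = 2.0 * spec.nucleus_radius + pixel_size
    if width_um <= 2 * margin or height_um <= 2 * margin:
        raise ParameterError("frame too small for the nucleus radius")

    rng = np.random.default_rng(seed)
    n = spec.n_cells
    n_seg = spec.n_segments
    starts = _grid_starts(n, width_um, height_um, margin, rng)

    lengths = _truncated_steps(rng, spec.step_mean, spec.step_sd, (n, n_seg))
    spread = math.pi * (1.0 - spec.persistence)
    waypoints = np.empty((n_seg + 1, n, 2), dtype=np.float64)
    waypoints[0] = starts
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    lo = np.array([margin, margin])
    hi = np.array([width_um - margin, height_um - margin])
    for k in range(n_seg):
        for i in range(n):
            th = theta[i] if k == 0 else theta[i] + rng.uniform(-spread, spread)
            for attempt in range(200):
                step = lengths[i, k] * np.array([math.cos(th), math.sin(th)])
                cand = waypoints[k, i] + step
                if np.all(cand >= lo) and np.all(cand <= hi):
                    break
                # near a border the persistent proposal may be infeasible;
                # fall back to a fresh uniform direction
                th = (theta[i] + rng.uniform(-spread, spread)) if attempt < 50 \
                    else rng.uniform(0.0, 2.0 * math.pi)
            else:
                raise ParameterError(
                    "could not place a segment endpoint inside the frame; "
                    "enlarge dims or reduce step_mean"
                )
            theta[i] = th
            waypoints[k + 1, i] = cand

    frames_per_seg = int(round(SEGMENT_HOURS * 60.0 / spec.frame_interval))
    n_frames = int(math.floor(spec.duration * 60.0 / spec.frame_interval)) + 1
    frac = np.arange(frames_per_seg) / frames_per_seg
    positions = np.empty((n_frames, n, 2), dtype=np.float64)
    for k in range(n_seg):
        seg = waypoints[k][None] + frac[:, None, None] * (waypoints[k + 1] - waypoints[k])[None]
        positions[k * frames_per_seg:(k + 1) * frames_per_seg] = seg
    positions[-1] = waypoints[-1]

    return SyntheticTimelapse(
        spec=spec, dims=dims, pixel_size=pixel_size, seed=seed,
        positions_um=positions, nucleus_intensity=nucleus_intensity,
        background=background,
    )


# ---------------------------------------------------------------------------
# group measurements
# ---------------------------------------------------------------------------

def sample_group_measurements(
    mean: float,
    sd: float,
    n: int,
    lower_bound: float = -np.inf,
    upper_bound: float = np.inf,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` values from a normal(mean, sd) truncated to
    [lower_bound, upper_bound].

    Used to simulate per-object group measurements (e.g. circularity indices
    in (0, 1], areas > 0) from a published mean ± SD. ``sd = 0`` yields ``n``
    copies of the mean.
    """
    if sd < 0:
        raise ParameterError("sd must be >= 0")
    if n < 2:
        raise ParameterError("n must be >= 2")
    if not (lower_bound < mean < upper_bound):
        raise ParameterError("bounds must contain the mean")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd == 0:
        return np.full(n, mean, dtype=np.float64)
    a = (lower_bound - mean) / sd
    b = (upper_bound - mean) / sd
    return np.asarray(truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng))
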