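"""Visual stimuli: test patterns, synthetic natural scenes, and scan sequences.

The simulated bee samples a stimulus by lateral scanning: five sequential
75x75-pixel patches are extracted from a larger image by shifting the sampling
window a fixed number of pixels between consecutive patches.  A 15-pixel shift
corresponds to a normal flight speed of 0.1 m/s; the shift therefore acts as a
speed proxy (0 px <-> stationary, 45 px <-> 0.3 m/s).

All images are 2-D arrays of green-channel intensity in [0, 1], row-major with
the origin at the top-left; the scan axis is the column axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import rescale, rotate

__all__ = [
    "M_PATCHES",
    "PATCH_SIZE",
    "DEFAULT_CANVAS",
    "SceneImage",
    "PatternImage",
    "ScanSequence",
    "make_pattern",
    "make_synthetic_scene",
    "shuffle_image",
    "make_scan",
    "make_moving_bar",
    "distal_view",
    "speed_to_shift",
]

#: number of patches per scan (temporal instances integrated by a lobula unit)
M_PATCHES = 5
#: side of one sampled patch, in pixels (the photoreceptor grid)
PATCH_SIZE = 75
#: default pattern canvas.  Must accommodate the longest traverse,
#: 75 + 4*45 = 255 px for a whole-pattern scan at the fast speed, and a
#: normal-speed traverse (135 px) inside a single quadrant (150 px).
DEFAULT_CANVAS = 300

PATTERN_KINDS = ("plus", "multiplication", "bar", "grating", "spiral", "two_bar_quadrant")
REGIONS = ("whole", "whole_fit", "lower_half", "lower_left", "custom")
DIRECTIONS = ("left_to_right", "right_to_left")


def speed_to_shift(speed_m_s: float) -> int:
    """Map a scanning speed in m/s to the pixel shift between patches.

    0.1 m/s corresponds to 15 px; the mapping is linear through the origin.
    """
    return int(round(150.0 * speed_m_s))


@dataclass
class SceneImage:
    """A grayscale scene used for non-associative training."""

    pixels: np.ndarray
    seed: int | None = None

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PatternImage:
    """A deterministic test pattern (plus, multiplication, bar, ...)."""

    pixels: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ScanSequence:
    """Five ordered 75x75 patches extracted by lateral window shifts."""

    patches: np.ndarray  # (5, 75, 75)
    shift_px: int
    region: str = "whole"
    direction: str = "left_to_right"

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.shape != (M_PATCHES, PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"scan must hold {M_PATCHES} patches of "
                f"{PATCH_SIZE}x{PATCH_SIZE}, got {self.patches.shape}"
            )
        if self.patches.min() < -1e-9 or self.patches.max() > 1 + 1e-9:
            raise ValueError("patch intensities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# pattern drawing
# ---------------------------------------------------------------------------

def _grid(canvas: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered pixel coordinates (x = columns, y = rows downward)."""
    c = (canvas - 1) / 2.0
    y, x = np.mgrid[0:canvas, 0:canvas].astype(float)
    return x - c, y - c


def _soft_bar(canvas: int, angle_deg: float, width: float, length: float,
              center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Anti-aliased bar mask in [0, 1] drawn from its signed distance field.

    ``angle_deg`` is the bar axis measured anticlockwise from horizontal
    (0 deg = horizontal bar, 90 deg = vertical bar).
    """
    x, y = _grid(canvas)
    x = x - center[0]
    y = y - center[1]
    th = np.deg2rad(angle_deg)
    # bar axis unit vector; image rows grow downward, so flip the sin term to
    # keep angles anticlockwise in conventional (x up-right) orientation
    ux, uy = np.cos(th), -np.sin(th)
    along = x * ux + y * uy
    across = -x * uy + y * ux
    # 1-px linear anti-alias ramp at both edges
    edge_w = np.clip(width / 2.0 + 0.5 - np.abs(across), 0.0, 1.0)
    edge_l = np.clip(length / 2.0 + 0.5 - np.abs(along), 0.0, 1.0)
    return edge_w * edge_l


def make_pattern(kind: str, params: dict | None = None, canvas: int = DEFAULT_CANVAS) -> PatternImage:
    """Draw one of the behavioural test patterns on a square canvas.

    Parameters
    ----------
    kind:
        One of ``plus``, ``multiplication``, ``bar``, ``grating``, ``spiral``
        or ``two_bar_quadrant``.
    params:
        Optional overrides: ``angle`` (degrees), ``contrast`` in [0, 1],
        ``stroke`` (bar width, px), ``frequency`` (grating cycles per 75-px
        patch), ``handedness`` (+1/-1, spirals), ``angles`` (pair, for
        ``two_bar_quadrant``), ``background`` intensity.
    """
    if kind not in PATTERN_KINDS:
        raise ValueError(f"unknown pattern kind {kind!r}; expected one of {PATTERN_KINDS}")
    if canvas < PATCH_SIZE + (M_PATCHES - 1) * 15:
        raise ValueError(f"canvas {canvas} too small for a 5-step scan")
    p = dict(params or {})
    contrast = float(p.get("contrast", 1.0))
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    background = float(p.get("background", 0.0))
    stroke = float(p.get("stroke", round(0.12 * canvas)))
    # confine strokes to the inscribed circle so a 45 deg rotation stays on-canvas
    length = float(p.get("length", 0.9 * canvas))
    angle = float(p.get("angle", 0.0))

    if kind == "plus":
        mask = np.maximum(
            _soft_bar(canvas, 0.0, stroke, length),
            _soft_bar(canvas, 90.0, stroke, length),
        )
    elif kind == "multiplication":
        mask = np.maximum(
            _soft_bar(canvas, 45.0, stroke, length),
            _soft_bar(canvas, 135.0, stroke, length),
        )
    elif kind == "bar":
        mask = _soft_bar(canvas, angle, stroke, length)
    elif kind == "grating":
        freq = float(p.get("frequency", 3.0))  # cycles per 75-px patch
        x, y = _grid(canvas)
        th = np.deg2rad(angle)
        # bars oriented along `angle`; modulation runs orthogonal to the bars
        phase = (-x * np.sin(th) - y * np.cos(th)) * 2 * np.pi * freq / PATCH_SIZE
        mask = 0.5 + 0.5 * np.sin(phase)
    elif kind == "spiral":
        hand = float(p.get("handedness", +1.0))
        turns = float(p.get("turns", 3.0))
        x, y = _grid(canvas)
        r = np.hypot(x, y)
        phi = np.arctan2(-y, x)  # anticlockwise in display orientation
        radius = 0.45 * canvas
        band = 0.5 + 0.5 * np.sin(hand * turns * 2 * np.pi * r / radius + phi)
        mask = np.where(r <= radius, band, 0.0)
    else:  # two_bar_quadrant
        a1, a2 = p.get("angles", (0.0, -45.0))
        q = canvas / 4.0
        mask = np.maximum(
            _soft_bar(canvas, float(a1), stroke * 0.6, 0.4 * canvas, center=(-q, q)),
            _soft_bar(canvas, float(a2), stroke * 0.6, 0.4 * canvas, center=(q, q)),
        )

    pixels = np.clip(background + contrast * mask * (1.0 - background), 0.0, 1.0)
    p.update(angle=angle, contrast=contrast, stroke=stroke, background=background)
    return PatternImage(pixels=pixels, kind=kind, params=p)


def distal_view(pattern: PatternImage, factor: float = 5.0) -> PatternImage:
    """Pattern as seen from a greater viewing distance.

    The pattern subtends ``1/factor`` of the visual angle: it is shrunk by
    ``factor`` (bilinear, anti-aliased) and pasted centrally onto a canvas of
    the original size filled with the background level.
    """
    small = rescale(pattern.pixels, 1.0 / factor, order=1, anti_aliasing=True)
    canvas = pattern.pixels.shape[0]
    background = float(pattern.params.get("background", 0.0))
    out = np.full_like(pattern.pixels, background)
    h, w = small.shape
    r0 = (canvas - h) // 2
    c0 = (canvas - w) // 2
    out[r0:r0 + h, c0:c0 + w] = small
    params = dict(pattern.params, distal_factor=factor)
    return PatternImage(pixels=np.clip(out, 0.0, 1.0), kind=pattern.kind, params=params)


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

def make_synthetic_scene(seed: int, size: tuple[int, int] = (DEFAULT_CANVAS, DEFAULT_CANVAS),
                         edge_density: int = 40, correlation_scale: float = 15.0) -> SceneImage:
    """Generate a synthetic naturalistic scene.

    Emulates the second-order statistics of flower/nature photographs: a
    1/f-like radial power spectrum with strong local spatial correlations,
    plus ``edge_density`` superposed oriented soft edges and blobs at random
    angles (the oriented structure that drives receptive-field formation).
    Reproducible bit-for-bit from ``seed``.
    """
    h, w = size
    if h < 200 or w < 200:
        raise ValueError("scene must be at least 200x200 px")
    rng = np.random.default_rng(seed)

    # correlated base: white noise shaped by a 1/(f + f0)^1.2 amplitude
    # spectrum (radially averaged power slope near -2, as in photographs of
    # natural scenes)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f0 = 1.0 / max(correlation_scale, 1.0)
    amp = np.power(f + f0, -1.2)
    amp[0, 0] = 0.0
    spectrum = np.fft.rfft2(rng.standard_normal(size)) * amp
    base = np.fft.irfft2(spectrum, s=size)
    base = (base - base.mean()) / (base.std() + 1e-12)

    # oriented edges and blobs
    edges = np.zeros(size)
    c = (min(h, w) - 1) / 2.0
    for _ in range(int(edge_density)):
        angle = rng.uniform(0.0, 180.0)
        bar_len = rng.uniform(0.15, 0.5) * min(h, w)
        bar_w = rng.uniform(3.0, 12.0)
        cy = rng.uniform(-c, c)
        cx = rng.uniform(-c, c)
        amp_e = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        edges += amp_e * _soft_bar(min(h, w), angle, bar_w, bar_len, center=(cx, cy))[:h, :w]
    if edges.std() > 0:
        edges = edges / edges.std()

    img = base + 0.8 * edges
    # optical point-spread smoothing; also lifts the lag-1 autocorrelation to
    # the >0.8 regime typical of green-channel nature photographs
    img = gaussian_filter(img, 0.8)
    lo, hi = img.min(), img.max()
    pixels = (img - lo) / (hi - lo + 1e-12)
    return SceneImage(pixels=pixels, seed=seed)


def shuffle_image(img: SceneImage, seed: int) -> SceneImage:
    """Randomly permute all pixels: identical intensity histogram, no spatial
    structure (the control training condition)."""
    rng = np.random.default_rng(seed)
    flat = img.pixels.ravel().copy()
    rng.shuffle(flat)
    return SceneImage(pixels=flat.reshape(img.pixels.shape), seed=seed)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _scan_window(shape: tuple[int, int], region: str, shift_px: int,
                 window_row: int | None) -> tuple[int, int, int]:
    """Resolve (row_start, col_lo, col_hi) of the permitted traverse band."""
    h, w = shape
    span = PATCH_SIZE + (M_PATCHES - 1) * shift_px
    if region == "whole":
        row = (h - PATCH_SIZE) // 2 if window_row is None else window_row
        col_lo, col_hi = 0, w
    elif region == "lower_half":
        row = h // 2 if window_row is None else window_row
        if row < h // 2:
            raise ValueError("lower_half window must start at or below the midline")
        col_lo, col_hi = 0, w
    elif region == "lower_left":
        row = h // 2 if window_row is None else window_row
        col_lo, col_hi = 0, w // 2
    elif region == "custom":
        if window_row is None:
            raise ValueError("custom region requires window_row")
        row = window_row
        col_lo, col_hi = 0, w
    else:
        raise ValueError(f"unknown region {region!r}")
    if row < 0 or row + PATCH_SIZE > h:
        raise ValueError("scan window exceeds image rows")
    if span > col_hi - col_lo:
        raise ValueError(
            f"traverse of {span} px does not fit in region {region!r} "
            f"({col_hi - col_lo} px wide)"
        )
    return row, col_lo, col_hi


def make_scan(img: SceneImage | PatternImage, region: str = "whole",
              shift_px: int = 15, direction: str = "left_to_right",
              window_row: int | None = None, col_start: int | None = None) -> ScanSequence:
    """Extract a 5-patch scan by shifting a 75x75 window along the columns.

    ``region`` selects where the window may sit: ``lower_half`` places it just
    below the pattern midline, ``lower_left`` additionally confines the whole
    traverse to the lower-left quadrant, and ``whole_fit`` surveys the entire
    pattern: the image is first rescaled so its full width fits inside the
    5-patch traverse (a bee sweeping across a whole pattern necessarily views
    it at a coarser angular resolution than when inspecting a sub-region
    close up; with shift 0 the rescale target is one 75-px window).  With
    ``shift_px == 0`` all five patches are identical (the no-scanning
    condition).  ``direction`` determines the temporal order in which the
    window positions are visited.
    """
    if shift_px < 0:
        raise ValueError("shift_px must be >= 0")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    pixels = img.pixels
    if region == "whole_fit":
        span = PATCH_SIZE + (M_PATCHES - 1) * shift_px
        scale = span / pixels.shape[1]
        if scale < 1.0:
            pixels = np.clip(rescale(pixels, scale, order=1, anti_aliasing=True), 0.0, 1.0)
        region = "whole"
    row, col_lo, col_hi = _scan_window(pixels.shape, region, shift_px, window_row)
    span = PATCH_SIZE + (M_PATCHES - 1) * shift_px
    if col_start is None:
        col_start = col_lo + (col_hi - col_lo - span) // 2
    elif col_start < col_lo or col_start + span > col_hi:
        raise ValueError("scan traverse exceeds region columns")

    order = range(M_PATCHES) if direction == "left_to_right" else range(M_PATCHES - 1, -1, -1)
    patches = np.stack([
        pixels[row:row + PATCH_SIZE, col_start + k * shift_px:
               col_start + k * shift_px + PATCH_SIZE]
        for k in order
    ])
    return ScanSequence(patches=patches, shift_px=shift_px, region=region, direction=direction)


def make_moving_bar(angle: float, shift_px: int = 15, contrast: float = 1.0,
                    bar_width: float = 15.0) -> ScanSequence:
    """Probe stimulus: a bar sweeping across the 75x75 field orthogonally to
    its own axis, rendered as a 5-frame sequence.

    ``angle`` is the bar orientation in degrees (0 = horizontal, 90 =
    vertical); the bar translates by ``shift_px`` per frame along the axis
    orthogonal to its orientation.  ``contrast`` scales the bar-background
    intensity difference.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    angle = float(angle) % 360.0
    th = np.deg2rad(angle)
    # motion direction orthogonal to the bar axis, in (x, y-down) coordinates
    nx, ny = np.sin(th), np.cos(th)
    frames = []
    for k in range(M_PATCHES):
        d = (k - (M_PATCHES - 1) / 2.0) * shift_px
        mask = _soft_bar(PATCH_SIZE, angle, bar_width, 3.0 * PATCH_SIZE,
                         center=(d * nx, d * ny))
        frames.append(np.clip(contrast * mask, 0.0, 1.0))
    return ScanSequence(patches=np.stack(frames), shift_px=shift_px)


def save_image_png(img: SceneImage | PatternImage, path) -> None:
    """Write an image as 8-bit grayscale PNG (linear map from [0, 1])."""
    from imageio.v3 import imwrite

    imwrite(path, (np.clip(img.pixels, 0, 1) * 255).astype(np.uint8))


def load_image_png(path) -> SceneImage:
    """Read an 8-bit grayscale PNG back into a [0, 1] intensity array."""
    from imageio.v3 import imread

    arr = np.asarray(imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return SceneImage(pixels=arr / 255.0)


def rotate_pattern(pattern: PatternImage, angle: float) -> PatternImage:
    """Rotate a pattern about the canvas centre (bilinear, clipped to [0, 1])."""
    out = rotate(pattern.pixels, -angle, order=1, mode="constant",
                 cval=float(pattern.params.get("background", 0.0)))
    params = dict(pattern.params, rotated_by=angle)
    return PatternImage(pixels=np.clip(out, 0.0, 1.0), kind=pattern.kind, params=params)
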