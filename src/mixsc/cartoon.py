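"""Parametric cartoon-face stimuli.

A face is drawn as the *sum* of 7 parts (outline, hair, eye pair, iris pair,
eyebrows, nose, mouth) on a 64x64 canvas, controlled by 19 integer feature
parameters, each on 11 levels from -5 to +5:

 1. face aspect ratio (round to long)      11. eye size (small to large)
 2. face direction (left to right)         12. iris size (small to large)
 3. feature assembly height (up to down)   13. gaze direction (11 x-y positions)
 4. hair length (short to long)            14. nose base (narrow to wide)
 5. hair thickness (thin to thick)         15. nose altitude (short to long)
 6. eyebrow slant (angry to worried)       16. mouth-nose distance (short to long)
 7. eyebrow width (short to long)          17. mouth size (narrow to wide)
 8. eyebrow height (up to down)            18. mouth top (smily to frowny)
 9. inter-eye distance (narrow to wide)    19. mouth bottom (closed to open)

Parameters 1-3 set the global face geometry (ellipse axes, lateral feature
shift, vertical feature shift) from which every part's layout is derived,
so they reach partial renders too; parameters 4-19 alter only their own
part.  Gaze direction indexes 11 positions on a raster path inside the eye
(left-to-right within each row, rows top to bottom: 4 upper, 3 middle, 4
lower positions).  Inversion is a vertical flip of the finished render.

Rendering is a deterministic function of the spec.  Strokes have value in
[0, 1] with a half-pixel linear anti-aliasing ramp; since the full face is
the plain sum of its parts, pixel values lie in [0, 7] before any
preprocessing.  The exact stroke geometry (ellipses, segments, quadratic
Bezier lips) is this package's own design, frozen by regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARTS",
    "PART_OF_FEATURE",
    "CartoonSpec",
    "CartoonImage",
    "spec_geometry",
    "render",
    "render_partial",
    "render_part",
    "part_bounds",
    "random_spec",
    "standard_spec",
]

PARTS = ("outline", "hair", "eye_pair", "iris_pair", "eyebrows", "nose", "mouth")

N_FEATURES = 19
LEVELS = tuple(range(-5, 6))

# owning part per feature (1-based feature ids); global features 1-3 are
# attributed to the outline for the partial-face protocol
PART_OF_FEATURE = {
    1: "outline", 2: "outline", 3: "outline",
    4: "hair", 5: "hair",
    6: "eyebrows", 7: "eyebrows", 8: "eyebrows",
    9: "eye_pair", 10: "eye_pair", 11: "eye_pair",
    12: "iris_pair", 13: "iris_pair",
    14: "nose", 15: "nose",
    16: "mouth", 17: "mouth", 18: "mouth", 19: "mouth",
}

SIZE = 64
_CX = _CY = (SIZE - 1) / 2.0

# gaze raster path: (dx, dy) in units of the available in-eye slack,
# left-to-right then top-to-bottom
GAZE_PATH = (
    (-0.9, -0.6), (-0.3, -0.6), (0.3, -0.6), (0.9, -0.6),
    (-0.9, 0.0), (0.0, 0.0), (0.9, 0.0),
    (-0.9, 0.6), (-0.3, 0.6), (0.3, 0.6), (0.9, 0.6),
)


@dataclass(frozen=True)
class CartoonSpec:
    params: tuple[int, ...] = (0,) * N_FEATURES
    visible_parts: frozenset[str] = frozenset(PARTS)
    inverted: bool = False

    def __post_init__(self):
        if len(self.params) != N_FEATURES:
            raise ValueError(f"need {N_FEATURES} parameters, got {len(self.params)}")
        if any(int(p) != p or p < -5 or p > 5 for p in self.params):
            raise ValueError("parameters must be integers in [-5, 5]")
        unknown = set(self.visible_parts) - set(PARTS)
        if unknown:
            raise ValueError(f"unknown parts: {sorted(unknown)}")

    def with_param(self, feature_id: int, level: int) -> "CartoonSpec":
        """Copy with 1-based feature ``feature_id`` set to ``level``."""
        p = list(self.params)
        p[feature_id - 1] = int(level)
        return CartoonSpec(tuple(p), self.visible_parts, self.inverted)


@dataclass(frozen=True)
class CartoonImage:
    pixels: np.ndarray
    provenance: CartoonSpec


def standard_spec() -> CartoonSpec:
    """The standard face: every feature at its central level 0."""
    return CartoonSpec()


def random_spec(rng: np.random.Generator) -> CartoonSpec:
    """All 19 parameters drawn independently and uniformly over the 11 levels."""
    return CartoonSpec(tuple(int(v) for v in rng.integers(-5, 6, size=N_FEATURES)))


def spec_geometry(spec: CartoonSpec) -> dict:
    """Layout quantities (pixel units) derived from the 19 parameters.

    Exposed so ordered parameters can be checked against actual geometry
    (e.g. inter-eye distance in pixels is non-decreasing in parameter 9).
    """
    t = np.asarray(spec.params, dtype=float) / 5.0  # each in [-1, 1]

    rx = 19.0 * (1.0 - 0.25 * t[0])  # round (-) to long (+)
    ry = 23.0 * (1.0 + 0.15 * t[0])
    dxf = 0.25 * rx * t[1]  # face direction: lateral feature shift
    dyf = 0.18 * ry * t[2]  # assembly height: vertical feature shift

    eye_y = _CY - 0.28 * ry + dyf
    eye_half = 0.37 * rx * (1.0 + 0.5 * t[8])
    eye_r = 0.16 * rx * (1.0 + 0.5 * t[10])
    ecc = 0.35 + 0.325 * (t[9] + 1.0)  # long (flat) to round
    eye_rx = eye_r
    eye_ry = eye_r * ecc
    eye_centers = (
        (_CX + dxf - eye_half, eye_y),
        (_CX + dxf + eye_half, eye_y),
    )

    iris_r = min(0.55 * (1.0 + 0.4 * t[11]), 0.95) * min(eye_rx, eye_ry)
    gx, gy = GAZE_PATH[int(spec.params[12]) + 5]
    gaze_off = (gx * max(eye_rx - iris_r, 0.0), gy * max(eye_ry - iris_r, 0.0))

    # eyebrows and mouth are anchored to the global face geometry only, so
    # eye- and nose-owned parameters never move other parts
    brow_x_half = 0.37 * rx
    brow_y = _CY - 0.44 * ry + dyf + 0.045 * ry * t[7]  # height: up (-) to down (+)
    brow_half = 0.18 * rx * (1.0 + 0.45 * t[6])
    brow_slant = 0.45 * t[5]  # radians; angry (-) to worried (+)

    nose_top = eye_y + 0.06 * ry
    nose_len = 0.22 * ry * (1.0 + 0.45 * t[14])
    nose_bottom = nose_top + nose_len
    nose_half = 0.12 * rx * (1.0 + 0.5 * t[13])

    mouth_y = _CY + dyf + ry * (0.26 + 0.06 * t[15])  # mouth-nose distance
    mouth_half = 0.30 * rx * (1.0 + 0.45 * t[16])
    mouth_top_bow = -0.11 * rx * t[17]  # smily (-): center sags down (+y)
    mouth_gap = 0.02 * ry + 0.10 * ry * (t[18] + 1.0) / 2.0

    hair_arc = np.pi * (0.35 + 0.30 * (t[3] + 1.0) / 2.0)  # from the top, per side
    hair_thick = 0.10 + 0.07 * t[4]

    return {
        "cx": _CX, "cy": _CY, "rx": rx, "ry": ry, "dxf": dxf, "dyf": dyf,
        "eye_centers": eye_centers, "inter_eye_distance": 2.0 * eye_half,
        "eye_rx": eye_rx, "eye_ry": eye_ry,
        "iris_r": iris_r, "gaze_off": gaze_off,
        "brow_x_half": brow_x_half, "brow_y": brow_y,
        "brow_half": brow_half, "brow_slant": brow_slant,
        "nose_top": nose_top, "nose_bottom": nose_bottom, "nose_half": nose_half,
        "mouth_y": mouth_y, "mouth_half": mouth_half,
        "mouth_top_bow": mouth_top_bow, "mouth_gap": mouth_gap,
        "hair_arc": hair_arc, "hair_thick": hair_thick,
    }


# ---------------------------------------------------------------- primitives

_YY, _XX = np.mgrid[0:SIZE, 0:SIZE].astype(float)


def _aa(dist: np.ndarray, thickness: float) -> np.ndarray:
    """Anti-aliased stroke value from a distance field (half-pixel ramp)."""
    return np.clip(thickness / 2.0 + 0.5 - dist, 0.0, 1.0)


def _stroke_ellipse(cx, cy, rx, ry, thickness=1.2) -> np.ndarray:
    f = np.hypot((_XX - cx) / rx, (_YY - cy) / ry)
    dist = np.abs(f - 1.0) * min(rx, ry)  # approximate pixel distance
    return _aa(dist, thickness)


def _fill_ellipse(cx, cy, rx, ry) -> np.ndarray:
    f = np.hypot((_XX - cx) / rx, (_YY - cy) / ry)
    return np.clip((1.0 - f) * min(rx, ry) + 0.5, 0.0, 1.0)


def _dist_segment(p0, p1) -> np.ndarray:
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    wx, wy = _XX - p0[0], _YY - p0[1]
    vv = vx * vx + vy * vy
    tproj = np.clip((wx * vx + wy * vy) / vv, 0.0, 1.0) if vv > 0 else 0.0
    return np.hypot(wx - tproj * vx, wy - tproj * vy)


def _stroke_polyline(points, thickness=1.2) -> np.ndarray:
    dist = np.full((SIZE, SIZE), np.inf)
    for p0, p1 in zip(points[:-1], points[1:]):
        dist = np.minimum(dist, _dist_segment(p0, p1))
    return _aa(dist, thickness)


def _bezier_points(p0, p1, bow, n=17):
    """Quadratic Bezier from p0 to p1 whose midpoint sags by ``bow`` in y."""
    c = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0 + 2.0 * bow)
    s = np.linspace(0.0, 1.0, n)
    x = (1 - s) ** 2 * p0[0] + 2 * (1 - s) * s * c[0] + s**2 * p1[0]
    y = (1 - s) ** 2 * p0[1] + 2 * (1 - s) * s * c[1] + s**2 * p1[1]
    return list(zip(x, y))


# ------------------------------------------------------------------- parts


def render_part(spec: CartoonSpec, part: str) -> np.ndarray:
    """Render a single part with the spec's full geometry applied."""
    g = spec_geometry(spec)
    if part == "outline":
        return _stroke_ellipse(g["cx"], g["cy"], g["rx"], g["ry"])
    if part == "hair":
        f = np.hypot((_XX - g["cx"]) / g["rx"], (_YY - g["cy"]) / g["ry"])
        band = (f >= 1.0 - g["hair_thick"]) & (f <= 1.0 + 0.02)
        # angle from the "up" direction (y negative), in [0, pi]
        ang = np.abs(np.arctan2(_XX - g["cx"], -(_YY - g["cy"])))
        return np.where(band & (ang <= g["hair_arc"]), 1.0, 0.0)
    if part == "eye_pair":
        img = np.zeros((SIZE, SIZE))
        for ex, ey in g["eye_centers"]:
            img = np.maximum(img, _stroke_ellipse(ex, ey, g["eye_rx"], g["eye_ry"], 1.0))
        return img
    if part == "iris_pair":
        img = np.zeros((SIZE, SIZE))
        ox, oy = g["gaze_off"]
        for ex, ey in g["eye_centers"]:
            img = np.maximum(img, _fill_ellipse(ex + ox, ey + oy, g["iris_r"], g["iris_r"]))
        return img
    if part == "eyebrows":
        img = np.zeros((SIZE, SIZE))
        for side in (-1.0, 1.0):
            ex = g["cx"] + g["dxf"] + side * g["brow_x_half"]
            a = side * g["brow_slant"]  # mirrored: angry lowers the inner ends
            dx, dy = g["brow_half"] * np.cos(a), g["brow_half"] * np.sin(a)
            seg = [(ex - dx, g["brow_y"] - dy), (ex + dx, g["brow_y"] + dy)]
            img = np.maximum(img, _stroke_polyline(seg, 1.2))
        return img
    if part == "nose":
        nx = g["cx"] + g["dxf"]
        ridge = _stroke_polyline([(nx, g["nose_top"]), (nx, g["nose_bottom"])], 1.0)
        base = _stroke_polyline(
            [(nx - g["nose_half"], g["nose_bottom"]), (nx + g["nose_half"], g["nose_bottom"])],
            1.0,
        )
        return np.maximum(ridge, base)
    if part == "mouth":
        mx = g["cx"] + g["dxf"]
        p0 = (mx - g["mouth_half"], g["mouth_y"])
        p1 = (mx + g["mouth_half"], g["mouth_y"])
        top = _stroke_polyline(_bezier_points(p0, p1, g["mouth_top_bow"]), 1.2)
        bot = _stroke_polyline(
            _bezier_points(p0, p1, g["mouth_top_bow"] + g["mouth_gap"]), 1.2
        )
        return np.maximum(top, bot)
    raise ValueError(f"unknown part: {part!r}")


def render(spec: CartoonSpec) -> CartoonImage:
    """Sum of the rendered visible parts; empty visible set gives a blank."""
    img = np.zeros((SIZE, SIZE))
    for part in PARTS:  # fixed order, though the sum is order-independent
        if part in spec.visible_parts:
            img = img + render_part(spec, part)
    if spec.inverted:
        img = np.flipud(img).copy()
    return CartoonImage(pixels=img, provenance=spec)


def render_partial(spec: CartoonSpec, part: str) -> CartoonImage:
    """Render with only one part present (geometry parameters still apply)."""
    if part not in PARTS:
        raise ValueError(f"unknown part: {part!r}")
    return render(CartoonSpec(spec.params, frozenset({part}), spec.inverted))


def part_bounds(spec: CartoonSpec, part: str, margin: float = 3.0) -> tuple[int, int, int, int]:
    """Generous axis-aligned bounds (x0, x1, y0, y1) containing ``part`` at
    every level of its local parameters, for the spec's global geometry.

    Varying only a parameter owned by ``part`` changes pixels inside these
    bounds only.  Bounds are inclusive-exclusive pixel indices, clipped to
    the canvas.
    """
    if part not in PARTS:
        raise ValueError(f"unknown part: {part!r}")
    # union of the part's support over its local-parameter extremes
    locals_of = [f for f, p in PART_OF_FEATURE.items() if p == part and f > 3]
    xs, ys = [], []
    for g in _extreme_geometries(spec, locals_of):
        x0, x1, y0, y1 = _part_box(g, part)
        xs += [x0, x1]
        ys += [y0, y1]
    lo = lambda v: int(np.clip(np.floor(min(v) - margin), 0, SIZE))  # noqa: E731
    hi = lambda v: int(np.clip(np.ceil(max(v) + margin) + 1, 0, SIZE))  # noqa: E731
    return lo(xs), hi(xs), lo(ys), hi(ys)


def _extreme_geometries(spec: CartoonSpec, feature_ids):
    if not feature_ids:
        yield spec_geometry(spec)
        return
    for combo in range(2 ** len(feature_ids)):
        s = spec
        for j, fid in enumerate(feature_ids):
            s = s.with_param(fid, -5 if (combo >> j) & 1 else 5)
        yield spec_geometry(s)


def _part_box(g: dict, part: str):
    cx, cy = g["cx"], g["cy"]
    if part in ("outline", "hair"):
        rx, ry = g["rx"] * 1.05, g["ry"] * 1.05
        return cx - rx, cx + rx, cy - ry, cy + ry
    (lx, ey), (rx_, _) = g["eye_centers"]
    if part == "eye_pair":
        return (lx - g["eye_rx"], rx_ + g["eye_rx"], ey - g["eye_ry"], ey + g["eye_ry"])
    if part == "iris_pair":
        r = g["iris_r"] + max(abs(g["gaze_off"][0]), abs(g["gaze_off"][1]))
        return lx - g["eye_rx"] - r, rx_ + g["eye_rx"] + r, ey - g["eye_ry"] - r, ey + g["eye_ry"] + r
    if part == "eyebrows":
        h = g["brow_half"]
        bx0 = cx + g["dxf"] - g["brow_x_half"]
        bx1 = cx + g["dxf"] + g["brow_x_half"]
        return bx0 - h, bx1 + h, g["brow_y"] - h, g["brow_y"] + h
    nx = cx + g["dxf"]
    if part == "nose":
        return nx - g["nose_half"], nx + g["nose_half"], g["nose_top"], g["nose_bottom"]
    if part == "mouth":
        h = g["mouth_half"]
        bow = abs(g["mouth_top_bow"]) * 2.0 + g["mouth_gap"] * 2.0
        return nx - h, nx + h, g["mouth_y"] - bow, g["mouth_y"] + bow
    raise ValueError(part)
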