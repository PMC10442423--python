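"""Knee phantom generator with exactly known joint-space geometry.

A phantom is an AP-view knee raster plus a label mask (0 background,
1 femur, 2 tibia, 3 fibula).  The femur–tibia separation is controlled
per column by a quadratic gap profile through three anchor values
(lateral / center / medial, in mm), so every emitted mask carries its
own ground-truth gap profile against which the measurement pipeline can
be validated to the pixel.

Geometry conventions: row index increases downward, the femur sits above
the tibia, the tibial plateau is flat (optionally tilted by a few
pixels), and the fibula is a lateral-side polygon strictly outside the
femur–tibia overlap so it can never contaminate a gap measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND, FEMUR, TIBIA, FIBULA = 0, 1, 2, 3

#: grayscale rendering intensities per label
_INTENSITY = {BACKGROUND: 25, FEMUR: 190, TIBIA: 175, FIBULA: 160}

#: default resolution set: pixel spacing (mm/px) -> (width, height) in px.
#: All sizes are at or below the 800x1000 standardization target.
RESOLUTION_SET = {
    0.20: (800, 1000),
    0.25: (720, 920),
    0.30: (640, 840),
}


@dataclass(frozen=True)
class BoneParams:
    """Polygon controls for the drawn bones (fractions of image size)."""

    overlap_frac: float = 0.55     # joint width as a fraction of image width
    shaft_frac: float = 0.42       # shaft width as a fraction of joint width
    condyle_height_frac: float = 0.22
    tibia_height_frac: float = 0.22
    plateau_row_frac: float = 0.52
    plateau_tilt_px: int = 4       # plateau row drift across the joint
    fibula_width_frac: float = 0.07
    fibula_drop_px: int = 18       # fibula head starts this far below the plateau
    margin_frac: float = 0.06


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom leg scan."""

    image_width: int
    image_height: int
    pixel_spacing: float
    side: str                       # "left" or "right"
    gap_mm: dict                    # {"lateral": mm, "center": mm, "medial": mm}
    bone_params: BoneParams = field(default_factory=BoneParams)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        missing = {"lateral", "center", "medial"} - set(self.gap_mm)
        if missing:
            raise ValueError(f"gap_mm missing keys: {sorted(missing)}")
        if any(g <= 0 for g in self.gap_mm.values()):
            raise ValueError("all gap_mm values must be positive")
        if min(self.gap_mm.values()) < self.pixel_spacing:
            raise ValueError(
                "unresolvable geometry: smallest gap "
                f"{min(self.gap_mm.values())} mm is below one pixel at "
                f"{self.pixel_spacing} mm/px"
            )
        if self.image_width < 60 or self.image_height < 60:
            raise ValueError("image too small to draw a knee phantom")


@dataclass
class LabeledScan:
    """A raster + label mask pair, the unit of image phenotyping.

    ``true_gap_profile`` (mm per overlap column) is ground truth carried
    by the generator; user-supplied scans will not have it.
    """

    image: np.ndarray               # (H, W) uint8
    mask: np.ndarray                # (H, W) uint8, labels {0,1,2,3}
    pixel_spacing: float
    side: str
    subject_id: str = ""
    gap_columns: np.ndarray | None = None     # x indices of the overlap region
    true_gap_profile: np.ndarray | None = None  # mm, aligned with gap_columns


def _quadratic_profile(x: np.ndarray, anchors_x: np.ndarray, anchors_y: np.ndarray) -> np.ndarray:
    """Lagrange quadratic through three (x, y) anchors, evaluated at x."""
    (x0, x1, x2), (y0, y1, y2) = anchors_x.astype(float), anchors_y.astype(float)
    t0 = y0 * (x - x1) * (x - x2) / ((x0 - x1) * (x0 - x2))
    t1 = y1 * (x - x0) * (x - x2) / ((x1 - x0) * (x1 - x2))
    t2 = y2 * (x - x0) * (x - x1) / ((x2 - x0) * (x2 - x1))
    return t0 + t1 + t2


def generate_knee_phantom(spec: PhantomSpec) -> LabeledScan:
    """Draw one phantom leg; deterministic given ``spec.seed``.

    The per-column femur–tibia gap (in px) equals
    ``round(gap_mm(x) / pixel_spacing)`` where ``gap_mm(x)`` interpolates
    the three anchor gaps quadratically from the lateral to the medial
    edge of the joint, so the mm ground truth is exact up to one pixel of
    discretization.
    """
    spec.validate()
    bp = spec.bone_params
    H, W = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)

    overlap_w = int(round(bp.overlap_frac * W))
    x0 = (W - overlap_w) // 2
    x1 = x0 + overlap_w                       # exclusive
    cols = np.arange(x0, x1)

    # lateral edge is the fibula side: image-right for a right knee (AP view
    # convention adopted here), image-left for a left knee.
    lateral_right = spec.side == "right"
    if lateral_right:
        anchors_x = np.array([x1 - 1, (x0 + x1 - 1) / 2.0, x0])
    else:
        anchors_x = np.array([x0, (x0 + x1 - 1) / 2.0, x1 - 1])
    anchors_y = np.array(
        [spec.gap_mm["lateral"], spec.gap_mm["center"], spec.gap_mm["medial"]]
    )
    gap_mm_profile = _quadratic_profile(cols.astype(float), anchors_x, anchors_y)
    gap_px = np.rint(gap_mm_profile / spec.pixel_spacing).astype(int)
    if np.any(gap_px < 1):
        raise ValueError("unresolvable geometry: interpolated gap below one pixel")

    margin = int(round(bp.margin_frac * H))
    plateau0 = int(round(bp.plateau_row_frac * H))
    frac = (cols - x0) / max(overlap_w - 1, 1)
    plateau = plateau0 + np.rint(bp.plateau_tilt_px * frac).astype(int)

    femur_bottom = plateau - gap_px - 1
    condyle_h = int(round(bp.condyle_height_frac * H))
    tibia_h = int(round(bp.tibia_height_frac * H))

    mask = np.zeros((H, W), dtype=np.uint8)
    rows = np.arange(H)[:, None]

    # femoral condyle: rounded upper outline (elliptical inset at the sides)
    inset = np.rint(
        0.35 * condyle_h * (1.0 - np.sqrt(np.clip(1.0 - (2 * frac - 1) ** 2, 0.0, 1.0)))
    ).astype(int)
    condyle_top = femur_bottom - condyle_h + inset
    in_femur = (rows >= condyle_top[None, :]) & (rows <= femur_bottom[None, :])
    mask[:, x0:x1][in_femur] = FEMUR

    # tibia: flat plateau down to a fixed depth
    in_tibia = (rows >= plateau[None, :]) & (rows < (plateau + tibia_h)[None, :])
    mask[:, x0:x1][in_tibia] = TIBIA

    # shafts above (femur) and below (tibia) over the central columns
    shaft_w = int(round(bp.shaft_frac * overlap_w))
    sx0 = x0 + (overlap_w - shaft_w) // 2
    sx1 = sx0 + shaft_w
    shaft_cols = slice(sx0, sx1)
    top_of_condyle = int(condyle_top.min())
    mask[margin:top_of_condyle, shaft_cols] = np.where(
        mask[margin:top_of_condyle, shaft_cols] == BACKGROUND,
        FEMUR,
        mask[margin:top_of_condyle, shaft_cols],
    )
    bottom_of_tibia = int(plateau.max()) + tibia_h
    mask[bottom_of_tibia : H - margin, shaft_cols] = TIBIA

    # fibula: lateral-side polygon strictly outside the overlap columns
    fib_w = max(int(round(bp.fibula_width_frac * W)), 4)
    if lateral_right:
        fx0 = min(x1 + 2, W - fib_w - 1)
        fx1 = fx0 + fib_w
    else:
        fx1 = max(x0 - 2, fib_w + 1)
        fx0 = fx1 - fib_w
    fib_top = int(plateau.max()) + bp.fibula_drop_px
    fib_bottom = min(fib_top + int(0.3 * H), H - margin)
    mask[fib_top:fib_bottom, fx0:fx1] = FIBULA

    image = np.empty((H, W), dtype=float)
    for label, val in _INTENSITY.items():
        image[mask == label] = val
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return LabeledScan(
        image=image,
        mask=mask,
        pixel_spacing=spec.pixel_spacing,
        side=spec.side,
        gap_columns=cols,
        true_gap_profile=gap_px * spec.pixel_spacing,
    )
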