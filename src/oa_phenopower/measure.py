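"""Minimum joint-space-width (mJSW) measurement from label masks.

Pipeline: standardize scan size (pad to 800x1000, reject resolution
outliers) -> per-column femur–tibia gap profile -> nine-point per-leg
average (three sampled columns in each of the lateral, center and
medial thirds of the joint) -> per-subject minimum over legs ->
height-regression normalization across image-resolution groups.

Gaps are measured vertically within a column: gap(x) = (topmost tibia
row) - (bottommost femur row) - 1, floored at zero so touching bones
read as zero. Fibula pixels are ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oa_phenopower.simulate.phantoms import FEMUR, TIBIA, LabeledScan

TARGET_SIZE = (800, 1000)  # (width, height)


class ScanRejected(Exception):
    """Scan failed quality control; ``reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def validate_and_pad(scan: LabeledScan, target: tuple = TARGET_SIZE) -> LabeledScan:
    """Pad image and mask to the target size with zeros, content centered.

    Ties in the centering split are broken toward the top-left. Scans
    larger than the target in either axis are resolution outliers and
    raise :class:`ScanRejected`.
    """
    tw, th = target
    h, w = scan.mask.shape
    if w > tw or h > th:
        raise ScanRejected("resolution outlier")
    top = (th - h) // 2
    left = (tw - w) // 2
    if (h, w) == (th, tw):
        return scan
    pad = ((top, th - h - top), (left, tw - w - left))
    return LabeledScan(
        image=np.pad(scan.image, pad),
        mask=np.pad(scan.mask, pad),
        pixel_spacing=scan.pixel_spacing,
        side=scan.side,
        subject_id=scan.subject_id,
        gap_columns=None if scan.gap_columns is None else scan.gap_columns + left,
        true_gap_profile=scan.true_gap_profile,
    )


@dataclass
class GapProfile:
    """Per-column femur–tibia gap over the overlap region."""

    columns: np.ndarray       # strictly increasing x indices
    gaps_px: np.ndarray       # vertical gap in px, >= 0
    pixel_spacing: float


def gap_profile(mask: np.ndarray, pixel_spacing: float = 1.0) -> GapProfile:
    """Exhaustive per-column gap scan of a label mask.

    Columns enter the profile when they contain both femur and tibia
    pixels; fibula pixels never contribute.
    """
    has_femur = (mask == FEMUR).any(axis=0)
    has_tibia = (mask == TIBIA).any(axis=0)
    if not has_femur.any() or not has_tibia.any():
        missing = "femur" if not has_femur.any() else "tibia"
        raise ScanRejected(f"incomplete segmentation: no {missing} pixels")
    both = has_femur & has_tibia
    if not both.any():
        raise ScanRejected("no measurable joint: femur and tibia never share a column")
    cols = np.flatnonzero(both)
    rows = np.arange(mask.shape[0])[:, None]
    sub = mask[:, cols]
    femur_bottom = np.max(np.where(sub == FEMUR, rows, -1), axis=0)
    tibia_top = np.min(np.where(sub == TIBIA, rows, mask.shape[0]), axis=0)
    gaps = np.maximum(tibia_top - femur_bottom - 1, 0)
    return GapProfile(columns=cols, gaps_px=gaps, pixel_spacing=pixel_spacing)


def _third_sample_indices(length: int) -> list:
    """Sampled offsets at the 25/50/75% positions of a third of size ``length``."""
    return [int(np.floor(q * (length - 1) + 0.5)) for q in (0.25, 0.5, 0.75)]


def nine_point_columns(columns: np.ndarray) -> np.ndarray:
    """The nine sampled column indices over an overlap region."""
    if len(columns) < 9:
        raise ScanRejected("joint too narrow to sample")
    sampled = []
    for third in np.array_split(columns, 3):
        for off in _third_sample_indices(len(third)):
            sampled.append(third[off])
    return np.asarray(sampled)


def nine_point_leg_jsw(profile: GapProfile) -> float:
    """Mean gap (px) over nine sampled columns: three per joint third.

    The overlap is split into three equal contiguous thirds (lateral,
    center, medial — identity depends on scan side but the average does
    not), and each third is sampled at the columns nearest its 25%, 50%
    and 75% positions.
    """
    cols = nine_point_columns(profile.columns)
    pos = np.searchsorted(profile.columns, cols)
    return float(profile.gaps_px[pos].mean())


def subject_mjsw(left_jsw: float | None, right_jsw: float | None) -> float:
    """Minimum over available per-leg averages; a single leg stands alone."""
    vals = [v for v in (left_jsw, right_jsw) if v is not None and not np.isnan(v)]
    if not vals:
        raise ValueError("no per-leg measurement available for subject")
    return float(min(vals))


@dataclass
class NormalizationModel:
    """Per-resolution-group height regression and scaling factors.

    factor_g = slope_reference / slope_g, so normalized values are
    raw_px * factor_g * reference pixel spacing (a mm-equivalent).
    The reference group's factor is 1 by construction.
    """

    reference_group: object
    reference_spacing: float
    slopes: dict = field(default_factory=dict)
    intercepts: dict = field(default_factory=dict)
    factors: dict = field(default_factory=dict)
    invalid_groups: list = field(default_factory=list)


def fit_normalization(
    records: pd.DataFrame,
    reference_group: object | None = None,
    group_spacing: dict | None = None,
) -> NormalizationModel:
    """OLS of raw mJSW (px) on height (cm), per resolution group.

    ``records`` needs columns raw_mjsw_px, height, resolution_group.
    With a single group the model is the identity normalization
    (factor 1). Groups whose fitted slope is non-positive cannot be
    scaled and are flagged invalid.
    """
    groups = list(pd.unique(records["resolution_group"]))
    if reference_group is None:
        reference_group = groups[0]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} absent from records")
    if group_spacing is None:
        if "pixel_spacing" in records.columns:
            group_spacing = (
                records.groupby("resolution_group")["pixel_spacing"].first().to_dict()
            )
        else:
            group_spacing = {g: 1.0 for g in groups}

    model = NormalizationModel(
        reference_group=reference_group,
        reference_spacing=float(group_spacing[reference_group]),
    )
    if len(groups) == 1:
        g = groups[0]
        model.slopes[g] = np.nan
        model.intercepts[g] = np.nan
        model.factors[g] = 1.0
        return model

    for g, sub in records.groupby("resolution_group"):
        h = sub["height"].to_numpy(dtype=float)
        v = sub["raw_mjsw_px"].to_numpy(dtype=float)
        if np.ptp(h) == 0:
            raise ValueError(f"singular fit in group {g!r}: constant height")
        slope, intercept = np.polyfit(h, v, 1)
        model.slopes[g] = float(slope)
        model.intercepts[g] = float(intercept)
    ref_slope = model.slopes[reference_group]
    if ref_slope <= 0:
        raise ValueError("reference group has non-positive height slope")
    for g in groups:
        s = model.slopes[g]
        if s <= 0:
            model.invalid_groups.append(g)
            model.factors[g] = np.nan
        else:
            model.factors[g] = ref_slope / s
    return model


def apply_normalization(model: NormalizationModel, raw_mjsw_px: float, group: object) -> float:
    """Normalized mm-equivalent mJSW for one record."""
    if group not in model.factors:
        raise KeyError(f"resolution group {group!r} not in normalization model")
    f = model.factors[group]
    if np.isnan(f):
        raise ValueError(f"group {group!r} was flagged invalid (non-positive slope)")
    return float(raw_mjsw_px * f * model.reference_spacing)


def measure_subjects(scans_by_subject: dict, heights: dict,
                     reference_group: object | None = None) -> pd.DataFrame:
    """End-to-end measurement for a batch of subjects.

    ``scans_by_subject`` maps subject_id -> {"left": LabeledScan | None,
    "right": ...}. Scans are padded/QC'd, profiled, nine-point averaged
    and reduced to one raw px value per subject; the resolution group is
    the pixel spacing. Returns the per-subject table with mjsw_norm
    filled in, plus a rejected-scan log in ``df.attrs["rejections"]``.
    """
    rows, rejections = [], []
    for sid, legs in scans_by_subject.items():
        per_leg = {"left": None, "right": None}
        spacing = None
        for side, scan in legs.items():
            if scan is None:
                continue
            try:
                padded = validate_and_pad(scan)
                prof = gap_profile(padded.mask, padded.pixel_spacing)
                per_leg[side] = nine_point_leg_jsw(prof)
                spacing = padded.pixel_spacing
            except ScanRejected as exc:
                rejections.append({"subject_id": sid, "side": side, "reason": exc.reason})
        if per_leg["left"] is None and per_leg["right"] is None:
            rejections.append({"subject_id": sid, "side": "both", "reason": "no usable scan"})
            continue
        rows.append(
            {
                "subject_id": sid,
                "left_jsw_px": per_leg["left"],
                "right_jsw_px": per_leg["right"],
                "raw_mjsw_px": subject_mjsw(per_leg["left"], per_leg["right"]),
                "resolution_group": spacing,
                "pixel_spacing": spacing,
                "height": heights[sid],
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        model = fit_normalization(df, reference_group=reference_group)
        df["mjsw_norm"] = [
            apply_normalization(model, r.raw_mjsw_px, r.resolution_group)
            for r in df.itertuples()
        ]
        df.attrs["normalization"] = model
    df.attrs["rejections"] = pd.DataFrame(rejections, columns=["subject_id", "side", "reason"])
    return df
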