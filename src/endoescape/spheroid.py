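"""Radial knockdown profiles of spheroid cryosection images.

The section image is scaled (nearest neighbor) so the spheroid mask has an
equivalent radius of 200 px; pixels below the background upper limit
(background mean + 3 s.d.) are excluded; the mean intensity is computed in
one-pixel-thick shells from the margin toward the center (shell membership
is binned on the Euclidean distance transform of the scaled mask, so
irregular margins are followed). Sample profiles are corrected for cell
background (wild-type spheroids) and normalized to control-treated
spheroids shell by shell, and the ratio profile can be exported as a
uint16 image via the transform round(1000 * log10(10000 * ratio)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import rescale

from .exceptions import InputValidationError

__all__ = ["ShellProfile", "TARGET_RADIUS_PX", "radial_profile",
           "normalize_profile", "export_profile_image", "profile_to_frame",
           "export_transform", "inverse_export_transform"]

TARGET_RADIUS_PX = 200
BACKGROUND_K = 3.0


@dataclass
class ShellProfile:
    """Mean intensity of one 1-px shell (shell 1 = outermost margin)."""

    shell_index: int
    shell_mean: float
    n_pixels_used: int
    excluded_pixels: int


def _equivalent_radius(mask: np.ndarray) -> float:
    area = int(np.count_nonzero(mask))
    if area == 0:
        raise InputValidationError("spheroid mask is empty")
    return float(np.sqrt(area / np.pi))


def radial_profile(image: np.ndarray, spheroid_mask: np.ndarray,
                   background_region: np.ndarray,
                   target_radius: int = TARGET_RADIUS_PX) -> list[ShellProfile]:
    """Per-shell mean intensities of a spheroid section, margin inward.

    ``background_region`` is a mask of image-background pixels used for the
    exclusion limit (mean + 3 s.d.); shell means over empty shells are NaN
    and carry ``n_pixels_used = 0``.
    """
    image = np.asarray(image, dtype=float)
    spheroid_mask = np.asarray(spheroid_mask, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if image.shape != spheroid_mask.shape:
        raise InputValidationError("image and spheroid mask must share geometry")
    if not background_region.any():
        raise InputValidationError("background region is empty")

    bg = image[background_region]
    limit = float(bg.mean() + BACKGROUND_K * bg.std())

    scale = target_radius / _equivalent_radius(spheroid_mask)
    scaled_img = rescale(image, scale, order=0, preserve_range=True,
                         anti_aliasing=False)
    scaled_mask = rescale(spheroid_mask.astype(float), scale, order=0,
                          preserve_range=True, anti_aliasing=False) > 0.5

    depth = ndimage.distance_transform_edt(scaled_mask)
    shells = np.ceil(depth).astype(int)          # shell i: depth in (i-1, i]
    n_shells = int(shells.max())
    keep = scaled_img >= limit

    profiles = []
    for i in range(1, n_shells + 1):
        in_shell = shells == i
        used = in_shell & keep
        n_used = int(used.sum())
        profiles.append(ShellProfile(
            shell_index=i,
            shell_mean=float(scaled_img[used].mean()) if n_used else float("nan"),
            n_pixels_used=n_used,
            excluded_pixels=int(in_shell.sum()) - n_used))
    return profiles


def normalize_profile(sample: list[ShellProfile], wildtype: list[ShellProfile],
                      control: list[ShellProfile]) -> np.ndarray:
    """Per-shell ratio profile (sample - wildtype) / (control - wildtype).

    Shells where the control does not exceed the wild-type background are
    undefined (NaN).
    """
    if not len(sample) == len(wildtype) == len(control):
        raise InputValidationError(
            f"profiles must have equal length, got {len(sample)}, "
            f"{len(wildtype)}, {len(control)}")
    s = np.array([p.shell_mean for p in sample])
    w = np.array([p.shell_mean for p in wildtype])
    c = np.array([p.shell_mean for p in control])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (s - w) / (c - w)
    ratio[~(c > w)] = np.nan
    return ratio


def export_transform(ratio) -> np.ndarray:
    """round(1000 * log10(10000 * ratio)), half away from zero, clipped to
    uint16 range; non-positive ratios map to 0."""
    ratio = np.asarray(ratio, dtype=float)
    out = np.zeros(ratio.shape, dtype=np.uint16)
    ok = np.isfinite(ratio) & (ratio > 0)
    vals = 1000.0 * np.log10(10000.0 * ratio[ok])
    # round half away from zero
    vals = np.sign(vals) * np.floor(np.abs(vals) + 0.5)
    out[ok] = np.clip(vals, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return out


def inverse_export_transform(stored) -> np.ndarray:
    """Recover the ratio from an exported pixel value (up to quantization)."""
    stored = np.asarray(stored, dtype=float)
    return 10.0 ** (stored / 1000.0) / 10000.0


def export_profile_image(ratio_profile,
                         target_radius: int = TARGET_RADIUS_PX) -> np.ndarray:
    """Map a per-shell ratio profile onto concentric shells of a
    ``target_radius``-px circle and export as uint16.

    Shell geometry matches :func:`radial_profile` on a perfect disk (EDT
    binning), so shell i of the profile lands on shell i of the circle.
    Undefined (NaN or non-positive) shells and the image outside the disk
    are stored as 0.
    """
    ratio_profile = np.asarray(ratio_profile, dtype=float)
    size = 2 * target_radius + 1
    c = target_radius
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.hypot(yy - c, xx - c) <= target_radius
    shells = np.ceil(ndimage.distance_transform_edt(mask)).astype(int)
    ratio_map = np.zeros((size, size))
    n = len(ratio_profile)
    inside = mask & (shells >= 1)
    idx = np.clip(shells[inside] - 1, 0, n - 1)
    ratio_map[inside] = ratio_profile[idx]
    return export_transform(ratio_map)


def profile_to_frame(profiles: list[ShellProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])
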