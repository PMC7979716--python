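"""Rigid/similarity registration of sequential stain rounds.

Consecutive rounds image the *same* physical section after destaining and
restaining, so they differ by a global similarity transform (stage placement,
slight rotation) — no local tissue deformation.  Registration therefore runs
on the repeated hematoxylin counterstain: a coarse rotation search with
phase correlation on a downsampled pyramid, refined locally, with the final
translation estimated at sub-pixel precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform, rescale, warp

from .stains import StainBasis, StainRoundImage, rgb_to_od, separate_stains


class RegistrationError(RuntimeError):
    """Raised when no transform reaches the minimum similarity score."""

    def __init__(self, message: str, best_score: float | None = None):
        super().__init__(message)
        self.best_score = best_score


@dataclass
class RoundTransform:
    """Similarity transform mapping a round into the reference frame.

    The map is ``p_ref = c + scale * R(rotation) @ (p - c) + (dx, dy)`` with
    ``c`` the image centre, ``p = (x, y)`` in pixel units (x = column).
    Applying the transform to the moving round (``apply_transform``) aligns it
    with the reference.
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 1.0
    score: float | None = None

    def __post_init__(self):
        if not (0.9 <= self.scale <= 1.1):
            raise ValueError(f"implausible scale {self.scale} (gate: [0.9, 1.1])")

    def inverse(self) -> "RoundTransform":
        th = math.radians(self.rotation_deg)
        s = 1.0 / self.scale
        # p = c + s R(-th) (p' - c) - s R(-th) t
        tx = -s * (math.cos(th) * self.dx_px + math.sin(th) * self.dy_px)
        ty = -s * (-math.sin(th) * self.dx_px + math.cos(th) * self.dy_px)
        return RoundTransform(tx, ty, -self.rotation_deg, s, score=self.score)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (abs(self.dx_px) < tol and abs(self.dy_px) < tol
                and abs(self.rotation_deg) < tol and abs(self.scale - 1) < tol)

    def as_skimage(self, shape: tuple) -> SimilarityTransform:
        """Forward map (moving -> reference) for an image of the given shape."""
        h, w = shape[:2]
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        return (SimilarityTransform(translation=-c)
                + SimilarityTransform(rotation=math.radians(self.rotation_deg),
                                      scale=self.scale)
                + SimilarityTransform(translation=c + [self.dx_px, self.dy_px]))

    def to_dict(self) -> dict:
        return {"dx_px": self.dx_px, "dy_px": self.dy_px,
                "rotation_deg": self.rotation_deg, "scale": self.scale,
                "score": self.score}

    @classmethod
    def from_dict(cls, d: dict) -> "RoundTransform":
        return cls(**{k: d.get(k, v) for k, v in
                      dict(dx_px=0.0, dy_px=0.0, rotation_deg=0.0,
                           scale=1.0, score=None).items()})


def apply_transform(image: np.ndarray, tform: RoundTransform, order: int = 1,
                    cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` into the reference frame under ``tform``.

    Bilinear by default (order=1); use order=0 for masks.
    """
    if tform.is_identity():
        return image.astype(float, copy=True)
    fwd = tform.as_skimage(image.shape)
    # warp() treats the given transform as the output->input (inverse) map.
    return warp(image.astype(float), fwd.inverse, order=order, cval=cval,
                preserve_range=True)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalised cross-correlation over a validity mask."""
    if mask.sum() < 16:
        return -1.0
    x = a[mask] - a[mask].mean()
    y = b[mask] - b[mask].mean()
    d = np.sqrt((x * x).sum() * (y * y).sum())
    if d == 0:
        return 0.0
    return float((x * y).sum() / d)


def _translation_for_rotation(ref: np.ndarray, mov: np.ndarray, theta: float,
                              upsample: int) -> tuple[float, float, float]:
    """Best translation and correlation score for a candidate rotation (deg).

    Uses plain (unnormalised) phase cross-correlation; rotation warps pad
    with the image median so the border contributes no spurious gradient.
    """
    if theta == 0.0:
        rot = mov
    else:
        rot = apply_transform(mov, RoundTransform(0.0, 0.0, theta),
                              cval=float(np.median(mov)))
    shift, error, _ = phase_cross_correlation(ref, rot, upsample_factor=upsample,
                                              normalization=None)
    return float(shift[1]), float(shift[0]), -float(error)


def register_pair(ref_od: np.ndarray, mov_od: np.ndarray,
                  max_rotation_deg: float = 4.0,
                  coarse_step_deg: float = 0.5,
                  fine_step_deg: float = 0.1,
                  min_score: float = 0.2) -> RoundTransform:
    """Estimate the similarity transform aligning ``mov_od`` to ``ref_od``.

    Coarse rotation grid on a downsampled pyramid level, local refinement at
    half resolution with parabolic sub-step interpolation, final sub-pixel
    translation at full resolution.  Scale is fixed at 1.0 (serial rounds of
    one section have no magnification change); the plausibility gate on scale
    lives in :class:`RoundTransform`.
    """
    ref_od = np.asarray(ref_od, dtype=float)
    mov_od = np.asarray(mov_od, dtype=float)
    if ref_od.shape != mov_od.shape:
        raise RegistrationError("round shapes differ beyond padding contract")

    longest = max(ref_od.shape)
    coarse_f = max(1, int(2 ** math.ceil(math.log2(max(longest / 256, 1)))))
    mid_f = max(1, coarse_f // 2)

    def level(img, f):
        return rescale(img, 1.0 / f, anti_aliasing=f > 1, preserve_range=True)

    ref_c, mov_c = level(ref_od, coarse_f), level(mov_od, coarse_f)
    thetas = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, coarse_step_deg)
    scores = [
        _translation_for_rotation(ref_c, mov_c, th, upsample=4)[2] for th in thetas
    ]
    best_theta = float(thetas[int(np.argmax(scores))])

    ref_m, mov_m = level(ref_od, mid_f), level(mov_od, mid_f)
    fine = np.arange(best_theta - coarse_step_deg, best_theta + coarse_step_deg + 1e-9,
                     fine_step_deg)
    fine_scores = np.array(
        [_translation_for_rotation(ref_m, mov_m, th, upsample=8)[2] for th in fine]
    )
    i = int(np.argmax(fine_scores))
    best_theta = float(fine[i])
    if 0 < i < len(fine) - 1:  # parabolic sub-step refinement on the score
        y0, y1, y2 = fine_scores[i - 1], fine_scores[i], fine_scores[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            best_theta += float(0.5 * (y0 - y2) / denom) * fine_step_deg

    dx, dy, _ = _translation_for_rotation(ref_od, mov_od, best_theta, upsample=50)
    result = RoundTransform(dx, dy, best_theta, 1.0)
    aligned = apply_transform(mov_od, result)
    foot = apply_transform(np.ones_like(mov_od), result) > 0.999
    score = _ncc(ref_od, aligned, foot)
    if score < min_score:
        raise RegistrationError(
            f"registration failed: best similarity score {score:.3f} < {min_score}",
            best_score=score,
        )
    result.score = score
    return result


def register_rounds(rounds: Sequence[StainRoundImage], basis: StainBasis,
                    reference_marker: str, **kwargs) -> list[RoundTransform]:
    """Register every round to the reference round on hematoxylin OD maps.

    Returns one :class:`RoundTransform` per input round, in input order; the
    reference round receives the identity (score 1).
    """
    if len(rounds) < 2:
        raise ValueError("need at least two rounds to register")
    names = [r.marker_name for r in rounds]
    if reference_marker not in names:
        raise ValueError(f"reference marker {reference_marker!r} not among rounds")
    ref_idx = names.index(reference_marker)

    hema = []
    for r in rounds:
        od = rgb_to_od(r.rgb_pixels)
        hema.append(separate_stains(od, basis).hematoxylin_od)

    out: list[RoundTransform] = []
    for i, r in enumerate(rounds):
        if i == ref_idx:
            out.append(RoundTransform(score=1.0))
        else:
            out.append(register_pair(hema[ref_idx], hema[i], **kwargs))
    return out
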