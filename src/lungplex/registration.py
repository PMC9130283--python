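"""Rigid inter-round registration and autofluorescence subtraction.

Cyclic staining re-mounts the slide for every imaging round, which
introduces a small rigid motion (translation plus rotation) between
rounds.  The nuclear DAPI image, re-acquired in every round, is the
registration landmark: each round's DAPI is aligned onto the reference
round's DAPI and the recovered transform is then applied to every
marker channel of that round.

Translation is estimated by phase correlation; rotation by a
coarse-to-fine 1-D search (coarse pass on a downsampled image pair)
minimizing the phase-correlation residual.  Endogenous tissue
autofluorescence, acquired in a dedicated blank round, is subtracted
pixel-wise from the FITC and TRITC channels after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation
from skimage.transform import downscale_local_mean

from .panel import AF_CHANNELS
from .stack import AF_ROUND, ImageStack, rigid_warp


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (deg, CCW about image center) followed by an (dx, dy) shift."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    reference_round: int = 1

    def apply(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        return rigid_warp(image, self.rotation, self.translation, order=order)

    def inverse(self) -> "RigidTransform":
        theta = np.deg2rad(self.rotation)
        cos, sin = np.cos(theta), np.sin(theta)
        dx, dy = self.translation
        # inverse of p' = R p + t is p = R^-1 p' - R^-1 t  (about the center)
        inv_dx = -(cos * dx + sin * dy)
        inv_dy = -(-sin * dx + cos * dy)
        return RigidTransform(-self.rotation, (inv_dx, inv_dy), self.reference_round)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then self."""
        theta = np.deg2rad(self.rotation)
        cos, sin = np.cos(theta), np.sin(theta)
        ox, oy = other.translation
        dx = cos * ox - sin * oy + self.translation[0]
        dy = sin * ox + cos * oy + self.translation[1]
        return RigidTransform(self.rotation + other.rotation, (dx, dy), self.reference_round)

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.rotation) < 1e-12
            and abs(self.translation[0]) < 1e-12
            and abs(self.translation[1]) < 1e-12
        )


def _pcc_error(ref: np.ndarray, mov: np.ndarray) -> float:
    # un-normalized cross-correlation residual: smooth in rotation, unlike the
    # phase-whitened variant which saturates under broadband noise
    _, error, _ = phase_cross_correlation(ref, mov, normalization=None)
    return float(error)


def estimate_rigid(
    dapi_ref: np.ndarray,
    dapi_mov: np.ndarray,
    max_rotation: float = 3.0,
    coarse_step: float = 0.25,
    fine_step: float = 0.05,
    upsample: int = 20,
    reference_round: int = 1,
) -> RigidTransform:
    """Estimate the corrective rigid transform aligning `dapi_mov` onto `dapi_ref`.

    Convention: the returned transform, applied to the moving image,
    reproduces the reference.  For a moving image that is the reference
    shifted by (+5, -3) px the recovered translation is therefore
    (-5, +3), and for a +2 deg rotation it is -2 deg.
    """
    if dapi_ref.shape != dapi_mov.shape:
        raise RegistrationError("reference and moving image shapes differ")
    if dapi_ref.max() == dapi_ref.min() or dapi_mov.max() == dapi_mov.min():
        raise RegistrationError("no registration signal (blank image)")

    # band-limit before resampling: keeps the rotation score comparable
    # between the un-warped (theta = 0) and interpolated candidates
    ref = ndi.gaussian_filter(dapi_ref.astype(np.float64), 1.0)
    mov = ndi.gaussian_filter(dapi_mov.astype(np.float64), 1.0)

    # coarse rotation search on a 4x downsampled pair
    factor = 4 if min(ref.shape) >= 256 else 1
    ref_s = downscale_local_mean(ref, (factor, factor))
    mov_s = downscale_local_mean(mov, (factor, factor))
    coarse = np.arange(-max_rotation, max_rotation + 1e-9, coarse_step)
    errs = [_pcc_error(ref_s, rigid_warp(mov_s, th, (0.0, 0.0))) for th in coarse]
    best = coarse[int(np.argmin(errs))]

    # fine search on a 2x downsampled pair around the coarse optimum
    f2 = 2 if min(ref.shape) >= 256 else 1
    ref_f = downscale_local_mean(ref, (f2, f2))
    mov_f = downscale_local_mean(mov, (f2, f2))
    fine = np.arange(best - coarse_step, best + coarse_step + 1e-9, fine_step)
    errs = np.array([_pcc_error(ref_f, rigid_warp(mov_f, th, (0.0, 0.0))) for th in fine])
    i = int(np.argmin(errs))
    rotation = float(fine[i])
    if 0 < i < len(fine) - 1:  # parabolic sub-step refinement
        denom = errs[i - 1] - 2 * errs[i] + errs[i + 1]
        if denom > 1e-12:
            rotation += 0.5 * fine_step * float((errs[i - 1] - errs[i + 1]) / denom)

    rotated = rigid_warp(mov, rotation, (0.0, 0.0))
    shift, _, _ = phase_cross_correlation(
        ref, rotated, upsample_factor=upsample, normalization="phase"
    )
    # phase correlation reports the (row, col) offset of mov relative to ref
    dy, dx = (float(s) for s in shift)
    return RigidTransform(rotation, (dx, dy), reference_round)


def apply_transform(stack: ImageStack, transforms: dict[int, RigidTransform]) -> ImageStack:
    """Resample every channel of each round by that round's transform."""
    missing = [r for r in stack.rounds if r not in transforms]
    if missing:
        raise RegistrationError(f"no transform supplied for round(s) {missing}")
    images = {}
    for (rnd, ch), img in stack.images.items():
        t = transforms[rnd]
        images[(rnd, ch)] = img.copy() if t.is_identity else t.apply(img)
    out = ImageStack(images, stack.microns_per_pixel, dict(stack.metadata))
    out.metadata["transforms"] = {
        str(r): {"rotation": t.rotation, "translation": list(t.translation)}
        for r, t in transforms.items()
    }
    return out


def subtract_autofluorescence(marker_img: np.ndarray, af_img: np.ndarray) -> np.ndarray:
    """Pixel-wise max(marker - af, 0) on 8-bit images (no wraparound)."""
    if marker_img.shape != af_img.shape:
        raise ValueError("marker and autofluorescence image shapes differ")
    diff = marker_img.astype(np.int16) - af_img.astype(np.int16)
    return np.clip(diff, 0, 255).astype(np.uint8)


def register_stack(
    stack: ImageStack,
    reference_round: int = 1,
    max_rotation: float = 3.0,
    subtract_af: bool = True,
    transforms: dict[int, RigidTransform] | None = None,
) -> tuple[ImageStack, dict[int, RigidTransform]]:
    """Full inter-round alignment driven by the per-round DAPI images.

    Returns the aligned (and, when a blank AF round is present,
    AF-subtracted) stack together with the per-round transforms.
    Supplying `transforms` skips estimation and applies them as given
    (used to replay known ground-truth motion).
    """
    if transforms is None:
        ref = stack.get(reference_round, "DAPI")
        transforms = {}
        for rnd in stack.rounds:
            if rnd == reference_round:
                transforms[rnd] = RigidTransform(reference_round=reference_round)
            else:
                transforms[rnd] = estimate_rigid(
                    ref, stack.get(rnd, "DAPI"), max_rotation=max_rotation,
                    reference_round=reference_round,
                )
    aligned = apply_transform(stack, transforms)
    if subtract_af and AF_ROUND in stack.rounds:
        for (rnd, ch) in list(aligned.images):
            if rnd == AF_ROUND or ch not in AF_CHANNELS:
                continue
            af = aligned.images.get((AF_ROUND, ch))
            if af is not None:
                aligned.images[(rnd, ch)] = subtract_autofluorescence(
                    aligned.images[(rnd, ch)], af
                )
    return aligned, transforms
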