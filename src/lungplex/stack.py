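"""Multi-round, multi-channel 8-bit image stack.

Images are indexed by ``(round, channel)`` where channel is one of
FITC / TRITC / FARRED / DAPI.  Round numbers follow the staining design
(1..n_rounds); round 0 is reserved for the blank autofluorescence
reference acquisition.  All images share one shape and the pixel scale
is carried as microns per pixel.

Coordinate convention (used throughout the package): row-major arrays,
origin at the top-left corner, ``(x, y) = (column, row)``, 0-based;
rotation angles are in degrees, counter-clockwise positive, about the
image center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
import tifffile

AF_ROUND = 0


def rigid_warp(
    image: np.ndarray,
    rotation_deg: float,
    translation: tuple[float, float],
    order: int = 1,
) -> np.ndarray:
    """Rotate about the image center, then translate by (dx, dy) pixels.

    Bilinear interpolation by default; pixels sampled from outside the
    frame are filled with 0.  Input dtype is preserved (8-bit results
    are rounded half-up).
    """
    theta = np.deg2rad(rotation_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    # rotation matrix acting on (row, col) for a CCW-positive angle in (x, y)
    rot = np.array([[cos, sin], [-sin, cos]])
    center = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
    shift_rc = np.array([translation[1], translation[0]], dtype=float)
    # output -> input mapping: p_in = R^-1 (p_out - c - t) + c
    inv = rot.T
    offset = center - inv @ (center + shift_rc)
    out = ndi.affine_transform(
        image.astype(np.float64), inv, offset=offset, order=order, mode="constant", cval=0.0
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.floor(out + 0.5), info.min, info.max).astype(image.dtype)
    return out


@dataclass
class ImageStack:
    """Registered or raw multi-round image set with a common pixel scale."""

    images: dict[tuple[int, str], np.ndarray]
    microns_per_pixel: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.images:
            return
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) > 1:
            raise ValueError(f"images do not share one shape: {sorted(shapes)}")
        for key, img in self.images.items():
            if img.dtype != np.uint8:
                raise ValueError(f"image {key} is {img.dtype}, expected uint8")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def rounds(self) -> list[int]:
        return sorted({r for r, _ in self.images})

    @property
    def staining_rounds(self) -> list[int]:
        return [r for r in self.rounds if r != AF_ROUND]

    def channels_of_round(self, rnd: int) -> list[str]:
        return sorted(ch for r, ch in self.images if r == rnd)

    def get(self, rnd: int, channel: str) -> np.ndarray:
        return self.images[(rnd, channel)]

    def marker_image(self, panel, short_name: str) -> np.ndarray:
        rnd, ch = panel.round_channel(short_name)
        try:
            return self.images[(rnd, ch)]
        except KeyError:
            raise KeyError(
                f"no image for marker {short_name!r} at round {rnd}, channel {ch}"
            ) from None

    def copy(self) -> "ImageStack":
        return ImageStack(
            {k: v.copy() for k, v in self.images.items()},
            self.microns_per_pixel,
            dict(self.metadata),
        )

    # -- TIFF round trip ----------------------------------------------
    def write_tiff(self, path: str | Path) -> None:
        keys = sorted(self.images)
        pages = np.stack([self.images[k] for k in keys])
        meta = {
            "axes": "QYX",
            "lungplex_keys": json.dumps([[r, ch] for r, ch in keys]),
            "lungplex_mpp": self.microns_per_pixel,
            "lungplex_meta": json.dumps(self.metadata),
        }
        tifffile.imwrite(path, pages, metadata=meta)

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            meta = tif.shaped_metadata[0]
        keys = [(int(r), str(ch)) for r, ch in json.loads(meta["lungplex_keys"])]
        images = {k: pages[i] for i, k in enumerate(keys)}
        return cls(
            images,
            float(meta["lungplex_mpp"]),
            json.loads(meta.get("lungplex_meta", "{}")),
        )
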