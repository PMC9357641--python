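"""Image preparation: z-calibration, standardization, tiling, data splits.

Each acquisition stack is calibrated so z = 0 is the first plane where
fluorescent signal covers almost the entire field; planes down to 30 um are
retained and treated as independent image files.  Every image is
standardized to zero mean and unit standard deviation per channel and
cropped into an 8 x 8 grid of 128-pixel (64 um) image tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DegenerateChannelError, GeometryError, InvalidConfigError
from .phantom import MPMStack

__all__ = [
    "TileGrid",
    "Tile",
    "calibrate_z",
    "standardize",
    "crop_tiles",
    "split_train_validation",
]


@dataclass(frozen=True)
class TileGrid:
    """The cropping grid: 64 tiles of 128 px (64 um at 0.50 um/px)."""

    tile_side_px: int = 128
    tiles_per_side: int = 8
    pixel_size_um: float = 0.50

    @property
    def tiles_per_image(self) -> int:
        return self.tiles_per_side**2

    @property
    def tile_side_um(self) -> float:
        return self.tile_side_px * self.pixel_size_um


@dataclass
class Tile:
    """One tile crop with its grid position, blank flag and classifier score.

    ``pixels`` holds the standardized values fed to the classifier;
    ``raw_pixels`` (optional) the original gray levels used by the blank
    rule.  Blank tiles never carry a classifier score.
    """

    pixels: np.ndarray  # [channel][side][side]
    grid_row: int
    grid_col: int
    image_id: str = ""
    is_blank: bool = False
    truth_label: str | None = None  # "cancer" | "no_cancer"
    score: float | None = None
    raw_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise GeometryError("tile pixels must be [channel][y][x]")
        if not (0 <= self.grid_row and 0 <= self.grid_col):
            raise GeometryError("grid coordinates must be non-negative")
        if self.is_blank and self.score is not None:
            raise InvalidConfigError("blank tiles never carry a classifier score")


def calibrate_z(
    stack: MPMStack,
    coverage_threshold: float = 0.90,
    noise_floor: float | None = None,
) -> list[int]:
    """Find z = 0 and return the retained plane indices (depth <= 30 um).

    z = 0 is the first plane where the fraction of pixels whose
    across-channel maximum exceeds a noise floor reaches
    ``coverage_threshold`` ("signal in almost the entire image area").
    The floor defaults to background + 2 sd, both estimated robustly
    (median / MAD) from the dimmest plane of the stack.
    """
    if not 0 < coverage_threshold <= 1:
        raise InvalidConfigError("coverage_threshold must be in (0, 1]")
    planes = stack.voxels.max(axis=1).astype(float)  # [z][y][x] channel max
    if noise_floor is None:
        dimmest = planes[np.argmin(planes.mean(axis=(1, 2)))]
        bg = float(np.median(dimmest))
        sd = 1.4826 * float(np.median(np.abs(dimmest - bg)))
        noise_floor = bg + 2.0 * sd
    coverage = (planes > noise_floor).mean(axis=(1, 2))
    above = np.nonzero(coverage >= coverage_threshold)[0]
    if len(above) == 0:
        raise CalibrationError(
            f"no plane reaches coverage {coverage_threshold:.2f} "
            f"(max observed {coverage.max():.3f})"
        )
    z0 = int(above[0])
    g = stack.geometry
    max_extra = int(g.max_depth_um // g.z_step_um)
    last = min(stack.voxels.shape[0] - 1, z0 + max_extra)
    return list(range(z0, last + 1))


def standardize(image: np.ndarray, per_channel: bool = True) -> np.ndarray:
    """Normalize an image to mean 0, standard deviation 1 (per channel).

    Raises :class:`DegenerateChannelError` on a constant channel so the
    caller can route the image to blank handling.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    if per_channel:
        mean = img.mean(axis=(-2, -1), keepdims=True)
        sd = img.std(axis=(-2, -1), keepdims=True)
    else:
        mean = img.mean()
        sd = img.std()
    if np.any(sd < 1e-12):
        raise DegenerateChannelError("constant channel cannot be standardized")
    out = (img - mean) / sd
    return out if image.ndim != 2 else out[0]


def crop_tiles(
    image: np.ndarray,
    grid: TileGrid | None = None,
    image_id: str = "",
    raw_image: np.ndarray | None = None,
) -> list[Tile]:
    """Partition an image into non-overlapping tiles in row-major order."""
    grid = grid or TileGrid()
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[None]
    _, h, w = img.shape
    side = grid.tile_side_px
    if h % side or w % side:
        raise GeometryError(f"image sides {h}x{w} not divisible by tile side {side}")
    tiles = []
    for r in range(h // side):
        for c in range(w // side):
            sl = (slice(None), slice(r * side, (r + 1) * side), slice(c * side, (c + 1) * side))
            tiles.append(
                Tile(
                    pixels=img[sl],
                    grid_row=r,
                    grid_col=c,
                    image_id=image_id,
                    raw_pixels=None if raw_image is None else np.asarray(raw_image)[sl],
                )
            )
    return tiles


def split_train_validation(
    items: list | np.ndarray,
    fraction: float = 0.20,
    seed: int = 0,
) -> tuple[list, list]:
    """Random tile-level split into (training, validation) sets.

    The validation set holds ``round(fraction * total)`` items; the split is
    disjoint, exhaustive, and deterministic for a given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidConfigError("fraction must be in (0, 1)")
    items = list(items)
    n_val = int(round(fraction * len(items)))
    order = np.random.default_rng(seed).permutation(len(items))
    val_idx = set(order[:n_val].tolist())
    train = [items[i] for i in range(len(items)) if i not in val_idx]
    val = [items[i] for i in sorted(val_idx)]
    return train, val
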