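"""ROI definition from statistic maps and mirror flipping across hemispheres.

The contralateral sensorimotor ROI is defined as the 70 highest-statistic
voxels around the suprathreshold peak nearest a hand-knob landmark on a
10 mm-smoothed group map; its ipsilateral counterpart is the mirror image
obtained by reversing the sign of the world x coordinate.  Smoothing is
used for ROI *definition* only -- all downstream analyses read unsmoothed
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

__all__ = ["ROIMask", "smooth_map", "select_roi", "mirror_roi", "roi_mean"]

#: FWHM of the ROI-definition smoothing kernel, mm
DEFAULT_SMOOTHING_FWHM = 10.0

#: default ROI size, voxels
DEFAULT_ROI_SIZE = 70


@dataclass
class ROIMask:
    """Set of voxel grid coordinates with an affine into world mm."""

    coords: NDArray[np.intp]  # k x 3 integer grid coordinates
    affine: NDArray[np.floating]  # 4 x 4 grid -> world mm
    shape: tuple[int, int, int]
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        self.affine = np.asarray(self.affine, dtype=float)
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("ROI coordinates must be unique")
        for ax in range(3):
            if np.any(self.coords[:, ax] < 0) or np.any(
                self.coords[:, ax] >= self.shape[ax]
            ):
                raise ValueError("ROI coordinates fall outside the image grid")

    @property
    def k(self) -> int:
        return len(self.coords)

    def world_coords(self) -> NDArray[np.floating]:
        homo = np.column_stack(
            [self.coords, np.ones(len(self.coords))]
        ).astype(float)
        return (self.affine @ homo.T).T[:, :3]

    def to_mask_array(self) -> NDArray[np.bool_]:
        arr = np.zeros(self.shape, dtype=bool)
        arr[tuple(self.coords.T)] = True
        return arr


def _voxel_sizes(affine: NDArray[np.floating]) -> NDArray[np.floating]:
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


def smooth_map(
    stat_map: NDArray[np.floating],
    affine: NDArray[np.floating],
    fwhm_mm: float = DEFAULT_SMOOTHING_FWHM,
) -> NDArray[np.floating]:
    """Gaussian-smooth a 3-D statistic map at the given FWHM (mm)."""
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / _voxel_sizes(affine)
    return ndimage.gaussian_filter(
        np.asarray(stat_map, dtype=float), sigma=sigma_vox
    )


def _local_peaks(
    stat_map: NDArray[np.floating], threshold: float
) -> NDArray[np.intp]:
    """Grid coordinates of suprathreshold 26-connectivity local maxima."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = stat_map == ndimage.maximum_filter(
        stat_map, footprint=footprint, mode="nearest"
    )
    peaks = np.argwhere(local_max & (stat_map > threshold))
    return peaks


def select_roi(
    stat_map: NDArray[np.floating],
    affine: NDArray[np.floating],
    landmark_mm: NDArray[np.floating],
    k: int = DEFAULT_ROI_SIZE,
    threshold: float | None = None,
    hemisphere: str = "left",
) -> ROIMask:
    """Select the k top-statistic voxels around the peak nearest a landmark.

    The suprathreshold local maximum closest to ``landmark_mm`` (world
    coordinates) seeds a 26-connectivity region grown by admitting
    neighbouring voxels in descending statistic order until ``k`` voxels
    are collected.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if threshold is None:
        finite = stat_map[np.isfinite(stat_map)]
        threshold = float(np.percentile(finite, 95.0))
    n_candidates = int(np.sum(stat_map > threshold))
    if n_candidates < k:
        raise ValueError(
            f"only {n_candidates} suprathreshold voxels available, need {k}"
        )
    peaks = _local_peaks(stat_map, threshold)
    if len(peaks) == 0:
        raise ValueError("no suprathreshold peaks in the statistic map")
    homo = np.column_stack([peaks, np.ones(len(peaks))]).astype(float)
    peaks_mm = (np.asarray(affine) @ homo.T).T[:, :3]
    dist = np.linalg.norm(peaks_mm - np.asarray(landmark_mm), axis=1)
    seed = tuple(peaks[int(np.argmin(dist))])

    # region growing: frontier of 26-neighbours, highest statistic first
    import heapq

    selected: set[tuple[int, int, int]] = set()
    heap: list[tuple[float, tuple[int, int, int]]] = [(-stat_map[seed], seed)]
    seen = {seed}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    shape = stat_map.shape
    while heap and len(selected) < k:
        negval, vox = heapq.heappop(heap)
        if not np.isfinite(negval):
            continue
        selected.add(vox)
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if nb in seen:
                continue
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue
            seen.add(nb)
            heapq.heappush(heap, (-stat_map[nb], nb))
    if len(selected) < k:
        raise ValueError(
            f"connected neighbourhood exhausted at {len(selected)} voxels, "
            f"need {k}"
        )
    coords = np.array(sorted(selected), dtype=np.intp)
    return ROIMask(
        coords=coords,
        affine=np.asarray(affine, dtype=float),
        shape=shape,
        hemisphere=hemisphere,
    )


def mirror_roi(mask: ROIMask) -> ROIMask:
    """Mirror a mask across the midsagittal plane (world x -> -x)."""
    world = mask.world_coords()
    world[:, 0] *= -1.0
    inv = np.linalg.inv(mask.affine)
    homo = np.column_stack([world, np.ones(len(world))])
    grid = (inv @ homo.T).T[:, :3]
    coords = np.round(grid).astype(np.intp)
    if np.max(np.abs(grid - coords)) > 1e-6:
        raise ValueError(
            "mirrored voxels do not land on the grid; affine is not "
            "symmetric about x=0"
        )
    for ax in range(3):
        if np.any(coords[:, ax] < 0) or np.any(
            coords[:, ax] >= mask.shape[ax]
        ):
            raise ValueError("mirrored voxel falls outside the image grid")
    flipped = {"left": "right", "right": "left"}[mask.hemisphere]
    return ROIMask(
        coords=coords,
        affine=mask.affine.copy(),
        shape=mask.shape,
        hemisphere=flipped,
    )


def roi_mean(
    beta_map: NDArray[np.floating], mask: ROIMask
) -> float:
    """Unweighted mean of a (3-D) coefficient map over the mask voxels."""
    beta_map = np.asarray(beta_map, dtype=float)
    if beta_map.shape != mask.shape:
        raise ValueError("beta map shape does not match mask grid")
    if mask.k == 0:
        raise ValueError("empty ROI")
    return float(beta_map[tuple(mask.coords.T)].mean())
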