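"""File-format helpers: NIfTI volumes, BIDS-style TSV events, YAML configs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .cohort import EventSchedule
from .roi import ROIMask

__all__ = [
    "save_mask",
    "load_mask",
    "save_bold",
    "load_bold",
    "save_events",
    "load_events",
    "save_design",
]


def save_mask(mask: ROIMask, path: str | Path) -> None:
    """Write an ROI as a binary NIfTI volume."""
    img = nib.Nifti1Image(
        mask.to_mask_array().astype(np.uint8), mask.affine
    )
    nib.save(img, str(path))


def load_mask(path: str | Path, hemisphere: str = "left") -> ROIMask:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    coords = np.argwhere(arr > 0)
    return ROIMask(
        coords=coords, affine=img.affine, shape=arr.shape[:3],
        hemisphere=hemisphere,
    )


def save_bold(
    data: NDArray[np.floating],
    path: str | Path,
    affine: NDArray[np.floating] | None = None,
) -> None:
    """Write a scans x voxels array as a 4-D NIfTI (voxels along x)."""
    data = np.asarray(data, dtype=np.float32)
    vol = data.T[:, None, None, :]  # x=voxels, y=z=1, t=scans
    img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def load_bold(path: str | Path) -> NDArray[np.floating]:
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    return vol.reshape(-1, vol.shape[-1]).T.astype(float)


def save_events(schedule: EventSchedule, path: str | Path) -> None:
    """Write BIDS-flavoured events TSV (onset, duration, trial_type)."""
    schedule.to_events_frame().to_csv(path, sep="\t", index=False)


def load_events(
    path: str | Path, run_length: int, tr: float, design: str
) -> EventSchedule:
    df = pd.read_csv(path, sep="\t")
    return EventSchedule(
        onsets=df["onset"].to_numpy(dtype=float),
        conditions=[str(v) for v in df["trial_type"]],
        run_length=run_length,
        tr=tr,
        design=design,
    )


def save_design(design, path: str | Path) -> None:
    """Export a design matrix as TSV for audit."""
    pd.DataFrame(design.matrix, columns=design.names).to_csv(
        path, sep="\t", index=False
    )
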