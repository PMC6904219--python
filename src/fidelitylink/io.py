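"""Reading and writing the pipeline's tabular and volumetric artefacts.

Trial tables travel as tab-separated events files (BIDS-events-style
columns); pattern matrices and information maps as NIfTI volumes on the
acquisition grid (3 x 3 x 4 mm by default); searchlight maps as JSON; and
per-trial information as TSV keyed by trial id so it merges with power
tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .rsa import SearchlightMap

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_info_map_nifti",
    "read_info_map_nifti",
    "write_searchlights_json",
    "read_searchlights_json",
]

_EVENT_COLUMNS = [
    "onset_s", "duration_s", "trial_id", "stimulus", "phase", "block",
    "modality", "confidence", "correct", "remembered",
]


def write_trial_table(table: pd.DataFrame, path) -> Path:
    """Write a trial table as a tab-separated events file."""
    path = Path(path)
    cols = [c for c in _EVENT_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("correct", "remembered"):
        if col in table.columns:
            table[col] = table[col].astype(bool)
    return table


def _affine(spacing_mm=(3.0, 3.0, 4.0)) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def write_info_map_nifti(values: np.ndarray, mask: np.ndarray, path,
                         spacing_mm=(3.0, 3.0, 4.0)) -> Path:
    """Place per-voxel values into the mask grid and save as NIfTI."""
    mask = np.asarray(mask, dtype=bool)
    vol = np.full(mask.shape, np.nan, dtype=float)
    vol[mask] = np.asarray(values, dtype=float)
    img = nib.Nifti1Image(vol, _affine(spacing_mm))
    path = Path(path)
    nib.save(img, path)
    return path


def read_info_map_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (values over mask voxels, mask) from a saved information map."""
    vol = np.asarray(nib.load(path).dataobj, dtype=float)
    mask = np.isfinite(vol)
    return vol[mask], mask


def write_searchlights_json(searchlights: SearchlightMap, path) -> Path:
    payload = dict(
        radius_mm=searchlights.radius_mm,
        min_fraction=searchlights.min_fraction,
        full_count=searchlights.full_count,
        grid_spacing_mm=list(searchlights.grid_spacing_mm),
        mask_shape=list(searchlights.mask_shape) if searchlights.mask_shape else None,
        members={int(c): [int(v) for v in mem]
                 for c, mem in zip(searchlights.centres, searchlights.members)},
    )
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def read_searchlights_json(path) -> SearchlightMap:
    payload = json.loads(Path(path).read_text())
    centres = np.array(sorted(int(k) for k in payload["members"]), dtype=int)
    members = [np.array(payload["members"][str(c)], dtype=int) for c in centres]
    return SearchlightMap(
        centres=centres,
        members=members,
        radius_mm=payload["radius_mm"],
        min_fraction=payload["min_fraction"],
        full_count=payload["full_count"],
        grid_spacing_mm=tuple(payload["grid_spacing_mm"]),
        mask_shape=tuple(payload["mask_shape"]) if payload["mask_shape"] else None,
    )
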