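"""Recompute volumes, COGs and Dice from deposited group maps.

The published group-level maps (binary 50%-thresholded MPMs in template
space) can be checked against the reported tables by recomputing each
map's volume and center of gravity and the Dice coefficient between
functionally homologous maps from different pathways. This harness takes
any directory (or explicit name -> path mapping) of binary NIfTI masks; it
makes no assumption about provenance, so it works equally on downloaded
deposits and on locally generated stand-ins.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .group_maps import MPMask, center_of_gravity, mask_volume_mm3
from .similarity_metrics import dice


def load_binary_mask(path: Path | str, name: str | None = None) -> MPMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    return MPMask(
        mask=data,
        label_name=name or Path(str(path)).stem.split(".")[0],
        threshold_fraction=0.5,
        affine=img.affine,
    )


def deposited_map_report(
    maps: dict[str, Path | str] | Path | str,
    dice_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volumes/COGs per map and Dice per requested map pair.

    ``maps`` is either a name -> NIfTI path mapping or a directory to scan
    for ``*.nii[.gz]`` files. Returns ``(volume_table, dice_table)``; with
    ``dice_pairs`` omitted, Dice is computed for every unordered pair of
    maps sharing a grid.
    """
    if not isinstance(maps, dict):
        directory = Path(maps)
        maps = {
            p.name.split(".")[0]: p
            for p in sorted(directory.iterdir())
            if p.name.endswith((".nii", ".nii.gz"))
        }
    loaded = {name: load_binary_mask(path, name) for name, path in maps.items()}

    vol_rows = []
    for name, m in loaded.items():
        row = {"map": name, "volume_mm3": mask_volume_mm3(m)}
        if m.mask.any():
            cog = center_of_gravity(m)
            row.update(cog_x=cog[0], cog_y=cog[1], cog_z=cog[2])
        vol_rows.append(row)

    if dice_pairs is None:
        names = list(loaded)
        dice_pairs = [
            (a, b)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if loaded[a].mask.shape == loaded[b].mask.shape
        ]
    dice_rows = [
        {"map_a": a, "map_b": b, "dice": dice(loaded[a].mask, loaded[b].mask)}
        for a, b in dice_pairs
    ]
    return pd.DataFrame(vol_rows), pd.DataFrame(dice_rows)
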