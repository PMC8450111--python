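"""Readers and writers for the package's tabular and image formats.

Focus tables are TSV with header ``strain nucleus_id chromosome_id
axis_length_um focus_pos_um``, one row per focus; a chromosome without foci
appears once with an empty ``focus_pos_um``. Tetrad tables are TSV
``tetrad_id c1 c2 c3 c4`` with values Y|R|N. Images are single-channel
16-bit TIFF with a same-shape 8-bit mask TIFF.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import FocusChromosome, SimulationConfig, TetradPattern

FOCUS_COLUMNS = ["strain", "nucleus_id", "chromosome_id", "axis_length_um", "focus_pos_um"]
TETRAD_COLUMNS = ["tetrad_id", "c1", "c2", "c3", "c4"]

__all__ = [
    "FOCUS_COLUMNS",
    "TETRAD_COLUMNS",
    "write_focus_table",
    "read_focus_table",
    "write_tetrad_table",
    "read_tetrad_table",
    "write_config",
    "read_config",
    "write_image",
    "read_image",
    "read_mask",
    "read_lines",
]


def write_focus_table(chroms: list[FocusChromosome], path) -> None:
    rows = []
    for ch in chroms:
        base = (ch.strain, ch.nucleus_id, ch.chromosome_id, ch.axis_length)
        if ch.n_foci == 0:
            rows.append((*base, ""))
        else:
            rows.extend((*base, float(p)) for p in ch.focus_positions)
    pd.DataFrame(rows, columns=FOCUS_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_focus_table(path) -> list[FocusChromosome]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"strain": str, "nucleus_id": str, "chromosome_id": str},
    )
    missing = set(FOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    keys = ["strain", "nucleus_id", "chromosome_id"]
    for (strain, nid, cid), grp in df.groupby(keys, sort=False):
        lengths = grp["axis_length_um"].unique()
        if lengths.size != 1:
            raise ValueError(
                f"{path}: inconsistent axis_length_um for {strain}/{nid}/{cid}"
            )
        pos = grp["focus_pos_um"].dropna().to_numpy(dtype=float)
        out.append(
            FocusChromosome(
                strain=strain,
                nucleus_id=nid,
                chromosome_id=cid,
                axis_length=float(lengths[0]),
                focus_positions=np.sort(pos),
            )
        )
    return out


def write_tetrad_table(tetrads: list[TetradPattern], path) -> None:
    rows = [(t.tetrad_id, *t.spore_colors) for t in tetrads]
    pd.DataFrame(rows, columns=TETRAD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tetrad_table(path) -> list[TetradPattern]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TETRAD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TetradPattern(tetrad_id=row.tetrad_id, spore_colors=(row.c1, row.c2, row.c3, row.c4))
        for row in df.itertuples()
    ]


def write_config(config: SimulationConfig, path) -> None:
    """Flat key-value file whose keys are the SimulationConfig field names."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimulationConfig(**data)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.clip(image, 0, 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_lines(path) -> list[tuple[float, float, float, float]]:
    """Line-endpoints TSV ``x1 y1 x2 y2`` (one row per profile line)."""
    df = pd.read_csv(path, sep="\t")
    needed = ["x1", "y1", "x2", "y2"]
    missing = set(needed) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [tuple(float(row[c]) for c in needed) for _, row in df.iterrows()]


__all__.append("write_mask")
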