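"""File formats: cohort CSVs, square matrix text files, BrainNet node files.

Weight matrices and binary adjacencies are stored as whitespace-delimited
square text matrices (compatible with BrainNet Viewer ``.edge`` files).
Node files carry 6 whitespace-separated columns per region: x, y, z,
color, size, label.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition
from .preprocess import META_COLUMNS, region_columns


def write_matrix(path: str | Path, M: np.ndarray) -> None:
    """Square matrix as whitespace-delimited text (.edge-compatible)."""
    np.savetxt(path, np.asarray(M, dtype=float), fmt="%.10g")


def read_matrix(path: str | Path) -> np.ndarray:
    M = np.loadtxt(path)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: not a square matrix")
    return M


def write_node_file(
    path: str | Path,
    atlas: AtlasDefinition,
    size: np.ndarray | None = None,
    color: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> None:
    """BrainNet Viewer .node export: x y z color size label per region.

    ``size`` typically carries |Hedges' g| so node size is proportional to
    the effect size; ``mask`` restricts the file to selected regions.
    """
    n = len(atlas)
    size = np.ones(n) if size is None else np.asarray(size, dtype=float)
    color = np.ones(n) if color is None else np.asarray(color, dtype=float)
    mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    lines = []
    for i, r in enumerate(atlas):
        if not mask[i]:
            continue
        x, y, z = r.centroid
        lines.append(f"{x:g}\t{y:g}\t{z:g}\t{color[i]:g}\t{size[i]:.6g}\t{r.name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_morphometry_csv(path: str | Path, atlas: AtlasDefinition) -> pd.DataFrame:
    """Load a morphometry table and validate it against the atlas."""
    table = pd.read_csv(path)
    missing_meta = set(META_COLUMNS) - set(table.columns)
    if missing_meta:
        raise ValueError(f"{path}: missing columns {sorted(missing_meta)}")
    missing = [name for name in atlas.names if name not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing atlas region column(s): {missing}")
    ordered = list(META_COLUMNS) + atlas.names
    return table[ordered]


def write_morphometry_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def validate_region_order(table: pd.DataFrame, atlas: AtlasDefinition) -> None:
    regs = region_columns(table)
    if regs != atlas.names:
        missing = [n for n in atlas.names if n not in regs]
        if missing:
            raise ValueError(f"table is missing atlas region(s): {missing}")
        raise ValueError("table region columns are not in atlas order")
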