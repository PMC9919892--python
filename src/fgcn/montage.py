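"""Electrode montages: channel identities and planar coordinates.

A montage carries the 2-D projected position of every EEG electrode. It is
the sole geometric input to the topological (distance-based) channel graph:
the RBF kernel of the pairwise Euclidean distances. A packaged 62-channel
10-20-style table (``montage62.csv``) matches the layout of the SEED
recording cap, with an optional 8x9 grid index per channel for image-style
(grid) convolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError

GRID_SHAPE = (8, 9)


@dataclass(frozen=True)
class Montage:
    """An ordered set of named electrodes with planar coordinates.

    Parameters
    ----------
    channel_names
        Unique channel identifiers, in recording order.
    coords
        ``(n_channels, 2)`` array of planar positions in an arbitrary but
        consistent length unit.
    grid_index
        Optional ``(n_channels, 2)`` integer array of (row, col) positions
        in an 8x9 grid, for depthwise convolution on the electrode image.
    """

    channel_names: tuple[str, ...]
    coords: np.ndarray
    grid_index: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        n = len(self.channel_names)
        if len(set(self.channel_names)) != n:
            raise ParameterError("montage channel names must be unique")
        if coords.shape != (n, 2):
            raise ParameterError(
                f"coords must have shape ({n}, 2), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ParameterError("montage coordinates must be finite")
        d = self.distances()
        off = d[~np.eye(n, dtype=bool)]
        if off.size and np.any(off == 0.0):
            warnings.warn(
                "montage contains distinct channels at identical coordinates",
                stacklevel=2,
            )
        if self.grid_index is not None:
            gi = np.asarray(self.grid_index, dtype=int)
            object.__setattr__(self, "grid_index", gi)
            if gi.shape != (n, 2):
                raise ParameterError(f"grid_index must have shape ({n}, 2)")
            if np.any(gi < 0) or np.any(gi >= np.array(GRID_SHAPE)):
                raise ParameterError(f"grid_index entries must lie in {GRID_SHAPE}")
            if len({tuple(rc) for rc in gi}) != n:
                raise ParameterError("grid_index entries must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix, shape ``(n, n)``."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def median_distance(self) -> float:
        """Median off-diagonal pairwise distance (default RBF width)."""
        d = self.distances()
        n = self.n_channels
        return float(np.median(d[~np.eye(n, dtype=bool)]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Montage":
        """Load a montage from a CSV with columns name, x, y
        (and optionally grid_row, grid_col)."""
        df = pd.read_csv(path)
        required = {"name", "x", "y"}
        if not required.issubset(df.columns):
            raise ParameterError(
                f"montage CSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        grid = None
        if {"grid_row", "grid_col"}.issubset(df.columns):
            grid = df[["grid_row", "grid_col"]].to_numpy(dtype=int)
        return cls(
            channel_names=tuple(df["name"].astype(str)),
            coords=df[["x", "y"]].to_numpy(dtype=float),
            grid_index=grid,
        )

    def to_csv(self, path: str | Path) -> None:
        data = {
            "name": list(self.channel_names),
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
        }
        if self.grid_index is not None:
            data["grid_row"] = self.grid_index[:, 0]
            data["grid_col"] = self.grid_index[:, 1]
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def default_62(cls) -> "Montage":
        """The packaged 62-channel 10-20-style montage with 8x9 grid index."""
        with resources.as_file(
            resources.files("fgcn.data").joinpath("montage62.csv")
        ) as p:
            return cls.from_csv(p)

    @classmethod
    def synthetic(cls, n_channels: int, n_cols: int = 9) -> "Montage":
        """A regular-grid montage for arbitrary channel counts.

        Used for synthetic datasets whose channel count differs from the
        packaged 62-channel cap. Unit spacing; names ``ch00, ch01, ...``.
        """
        if n_channels < 2:
            raise ParameterError("a montage needs at least 2 channels")
        rows, cols = np.divmod(np.arange(n_channels), n_cols)
        coords = np.column_stack([cols.astype(float), -rows.astype(float)])
        names = tuple(f"ch{i:02d}" for i in range(n_channels))
        grid = None
        if rows.max() < GRID_SHAPE[0] and n_cols <= GRID_SHAPE[1]:
            grid = np.column_stack([rows, cols])
        return cls(channel_names=names, coords=coords, grid_index=grid)


def default_montage(n_channels: int) -> Montage:
    """The packaged 62-channel montage when it fits, else a regular grid."""
    if n_channels == 62:
        return Montage.default_62()
    return Montage.synthetic(n_channels)
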