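"""Electrode montages: channel names plus 3D scalp positions.

The bundled montage covers the 32 EEG channels of the DEAP recording layout
(international 10-20 system, Fp1 ... O2) with positions on a unit-mean-radius
spherical head model. Inter-electrode Euclidean distances computed from these
positions drive the distance-based adjacency matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["Montage", "load_montage", "deap32_montage"]

_BUNDLED = "montage_10_20_32.csv"


@dataclass(frozen=True)
class Montage:
    """A set of named EEG channels with 3D coordinates.

    Parameters
    ----------
    names : tuple of str
        Channel labels (10-20 system), unique.
    positions : ndarray, shape (n_channels, 3)
        Cartesian coordinates in unit head-radius scale.
    """

    names: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {pos.shape}")
        if len(self.names) != pos.shape[0]:
            raise ValueError("number of names must match number of positions")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        d = self.pairwise_distances()
        off = d[~np.eye(len(self.names), dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("distinct channels must have distinct positions")

    def __len__(self) -> int:
        return len(self.names)

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean distance matrix, shape (n, n)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z"])
            for name, (x, y, z) in zip(self.names, self.positions):
                writer.writerow([name, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])


def load_montage(path: str | Path) -> Montage:
    """Read a montage from a CSV file with columns name, x, y, z."""
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"name", "x", "y", "z"} - set(
            reader.fieldnames
        ):
            raise ValueError("montage file needs columns: name, x, y, z")
        for rec in reader:
            names.append(rec["name"])
            rows.append([float(rec["x"]), float(rec["y"]), float(rec["z"])])
    return Montage(tuple(names), np.array(rows))


def deap32_montage() -> Montage:
    """The bundled 32-channel 10-20 montage in DEAP channel order."""
    ref = resources.files("crgcn.data").joinpath(_BUNDLED)
    with resources.as_file(ref) as path:
        return load_montage(path)
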