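"""In-memory containers and HDF5 I/O for the pipeline.

Two containers travel between stages: :class:`EpochedData` (trials x
channels x samples sensor or source epochs) and :class:`SourceModel`
(leadfield, voxel grid, atlas labels).  Both round-trip losslessly
through a plain HDF5 layout so that every stage can be run from files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochedData", "SourceModel", "seed_streams"]


def seed_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one integer seed into ``n`` independent substreams.

    Uses numpy's SeedSequence spawning (counter-based keys), so streams
    are reproducible regardless of the order in which they are consumed.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class EpochedData:
    """Epoched multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    srate : float
        Sampling rate in Hz.
    ch_names : list of str
    ch_pos : ndarray, shape (n_channels, 2 or 3)
        Channel positions; units are whatever the montage uses, and the
        sensor-adjacency neighbour distance must match them.
    tmin : float
        Time of the first sample relative to stimulus onset, seconds.
    condition : ndarray of str, shape (n_trials,)
        Per-trial condition tags.
    """

    data: np.ndarray
    srate: float
    ch_names: list[str]
    ch_pos: np.ndarray
    tmin: float = 0.0
    condition: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if not np.isfinite(self.srate) or self.srate <= 0:
            raise ValueError(f"invalid sampling rate: {self.srate}")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length does not match channel axis")
        self.ch_pos = np.asarray(self.ch_pos, dtype=float)
        if self.condition is None:
            self.condition = np.array([""] * self.data.shape[0])
        else:
            self.condition = np.asarray(self.condition)
            if self.condition.shape[0] != self.data.shape[0]:
                raise ValueError("condition length does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.tmin + np.arange(self.n_samples) / self.srate

    def select_condition(self, tag: str) -> "EpochedData":
        mask = self.condition == tag
        return EpochedData(self.data[mask], self.srate, list(self.ch_names),
                           self.ch_pos, self.tmin, self.condition[mask])

    def crop(self, t0: float, t1: float) -> "EpochedData":
        """Restrict the sample axis to times in [t0, t1] (inclusive)."""
        t = self.times
        keep = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        if not keep.any():
            raise ValueError(f"empty crop window ({t0}, {t1})")
        return EpochedData(self.data[:, :, keep], self.srate, list(self.ch_names),
                           self.ch_pos, float(t[keep][0]), self.condition)

    # ---- HDF5 round trip -------------------------------------------------
    def to_hdf5(self, path, group: str = "epochs") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("data", data=self.data)
            g.create_dataset("ch_pos", data=self.ch_pos)
            g.create_dataset("condition",
                             data=np.asarray(self.condition, dtype="S"))
            g.attrs["srate"] = self.srate
            g.attrs["tmin"] = self.tmin
            g.attrs["ch_names"] = json.dumps(list(self.ch_names))

    @classmethod
    def from_hdf5(cls, path, group: str = "epochs") -> "EpochedData":
        with h5py.File(path, "r") as f:
            g = f[group]
            return cls(
                data=g["data"][()],
                srate=float(g.attrs["srate"]),
                ch_names=json.loads(g.attrs["ch_names"]),
                ch_pos=g["ch_pos"][()],
                tmin=float(g.attrs["tmin"]),
                condition=g["condition"][()].astype(str),
            )


@dataclass
class SourceModel:
    """Volumetric source model: leadfield plus voxel grid and atlas labels.

    leadfield : ndarray, shape (n_channels, n_voxels, 3)
        Free-orientation forward solutions (x/y/z unit dipoles).
    coords : ndarray, shape (n_voxels, 3), millimetres.
    edge_mm : float, voxel edge length in millimetres.
    labels : ndarray of int, shape (n_voxels,)
        Atlas label per voxel; 0 means unlabeled and is excluded from
        source-cluster candidate selection.
    """

    leadfield: np.ndarray
    coords: np.ndarray
    edge_mm: float
    labels: np.ndarray

    def __post_init__(self):
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.leadfield.ndim != 3 or self.leadfield.shape[2] != 3:
            raise ValueError("leadfield must be (n_channels, n_voxels, 3)")
        if self.coords.shape != (self.leadfield.shape[1], 3):
            raise ValueError("coords must be (n_voxels, 3)")
        if self.labels.shape[0] != self.leadfield.shape[1]:
            raise ValueError("labels must have one entry per voxel")

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.leadfield.shape[1]

    def to_hdf5(self, path, group: str = "source_model") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("leadfield", data=self.leadfield)
            g.create_dataset("coords", data=self.coords)
            g.create_dataset("labels", data=self.labels)
            g.attrs["edge_mm"] = self.edge_mm

    @classmethod
    def from_hdf5(cls, path, group: str = "source_model") -> "SourceModel":
        with h5py.File(path, "r") as f:
            g = f[group]
            return cls(g["leadfield"][()], g["coords"][()],
                       float(g.attrs["edge_mm"]), g["labels"][()])
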