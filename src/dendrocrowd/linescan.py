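"""Line-scan records: time × position matrices of normalized concentration.

The :class:`LineScanRecord` is the shared currency between the 1D reduced
solver, the 3D Brownian simulator, the synthetic fixture generator and the
diffusion-constant fitter.  It mirrors a confocal line-scan acquisition: a
signal sampled at a fixed line period at a set of axial positions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_META_PREFIX = "# meta "


@dataclass
class LineScanRecord:
    """A time × position matrix of (normalized) signal values.

    Parameters
    ----------
    times
        Sample times in seconds, shape ``(nt,)``, strictly increasing.
    positions
        Axial positions in μm, shape ``(nx,)``, strictly increasing.
    values
        Signal matrix, shape ``(nt, nx)``.
    meta
        Acquisition metadata (dt, dx, normalization convention, seed, ...).
    raw_counts
        Optional un-normalized particle counts with the same shape as
        ``values`` (kept by the Brownian recorder).
    """

    times: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.positions.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(nt={self.times.size}, nx={self.positions.size})"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if self.times.size > 1 else np.nan

    @property
    def dx(self) -> float:
        return (
            float(np.median(np.diff(self.positions)))
            if self.positions.size > 1
            else np.nan
        )

    def normalized(self) -> "LineScanRecord":
        """Per-location normalization: the earliest frame with a nonzero
        value at each position is scaled to 1 (the convention used for
        uncaging transients)."""
        vals = self.values.copy()
        for j in range(vals.shape[1]):
            col = vals[:, j]
            nz = np.nonzero(col != 0)[0]
            if nz.size:
                vals[:, j] = col / col[nz[0]]
        meta = dict(self.meta, normalization="first-nonzero-frame-to-1")
        return LineScanRecord(self.times, self.positions, vals, meta, self.raw_counts)

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns time_s, position_um, value."""
        tt, xx = np.meshgrid(self.times, self.positions, indexing="ij")
        return pd.DataFrame(
            {
                "time_s": tt.ravel(),
                "position_um": xx.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        """Write tidy CSV with a ``# meta`` JSON sidecar header line."""
        meta = dict(self.meta, dt_s=self.dt, dx_um=self.dx)
        with open(path, "w") as fh:
            fh.write(_META_PREFIX + json.dumps(meta, default=float) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LineScanRecord":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith(_META_PREFIX):
                meta = json.loads(first[len(_META_PREFIX):])
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body))
        times = np.unique(df["time_s"].to_numpy())
        positions = np.unique(df["position_um"].to_numpy())
        values = (
            df.pivot(index="time_s", columns="position_um", values="value")
            .loc[times, positions]
            .to_numpy()
        )
        return cls(times, positions, values, meta)

    def to_hdf5(self, path) -> None:
        """Binary container for large runs."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("positions", data=self.positions)
            fh.create_dataset("values", data=self.values)
            if self.raw_counts is not None:
                fh.create_dataset("raw_counts", data=self.raw_counts)
            fh.attrs["meta"] = json.dumps(self.meta, default=float)

    @classmethod
    def from_hdf5(cls, path) -> "LineScanRecord":
        import h5py

        with h5py.File(path, "r") as fh:
            raw = fh["raw_counts"][()] if "raw_counts" in fh else None
            return cls(
                fh["times"][()],
                fh["positions"][()],
                fh["values"][()],
                json.loads(fh.attrs["meta"]),
                raw,
            )
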