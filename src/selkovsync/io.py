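"""Snapshot and diagnostics writers.

Two container choices: an HDF5 file with one group per snapshot
(``snap_000/ {time, u1, u2}``, full double precision) or a directory of
delimited-text files (one CSV per snapshot, row-major, axis header, 9
significant digits).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .grids import State

__all__ = ["write_snapshots_hdf5", "write_snapshots_csv", "read_snapshots_hdf5"]


def write_snapshots_hdf5(path, snapshots: Sequence[State]) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        for i, snap in enumerate(snapshots):
            grp = h5.create_group(f"snap_{i:03d}")
            grp.attrs["time"] = snap.time
            grp.create_dataset("u1", data=snap.u1)
            grp.create_dataset("u2", data=snap.u2)


def read_snapshots_hdf5(path, grid):
    import h5py

    out = []
    with h5py.File(path, "r") as h5:
        for key in sorted(h5.keys()):
            grp = h5[key]
            out.append(
                State(
                    grid=grid,
                    u1=grp["u1"][...],
                    u2=grp["u2"][...],
                    time=float(grp.attrs["time"]),
                )
            )
    return out


def write_snapshots_csv(directory, snapshots: Sequence[State], prefix: str = "snap") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, snap in enumerate(snapshots):
        x = snap.grid.axis
        header = f"time={snap.time:.9g}; axis: {' '.join(f'{v:.9g}' for v in x)}"
        for name, fld in (("u1", snap.u1), ("u2", snap.u2)):
            np.savetxt(
                directory / f"{prefix}_{i:03d}_{name}.csv",
                np.atleast_2d(fld),
                fmt="%.9g",
                delimiter=",",
                header=header,
            )
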