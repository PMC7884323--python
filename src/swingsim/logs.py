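"""Columnar trial logs and their on-disk formats.

A :class:`TrialLog` holds the full-rate time series of one block — pivot
kinematics, pendulum angle, hand/assist/rod forces — together with the
physical parameters, the target list, and block metadata, so a log file is
self-contained for downstream metric computation.

Primary format is CSV with a ``#``-prefixed JSON header (text, portable);
an HDF5 layout is available for bulk storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import AssistPoint, EndEffectorModel, PendulumParams
from .task import TargetSpec, targets_from_frame, targets_to_frame

__all__ = ["TrialLog", "LOG_COLUMNS"]

LOG_COLUMNS = ["t", "y", "z", "y_dot", "z_dot", "theta", "theta_dot",
               "F_hand_y", "F_hand_z", "F_assist_y", "assist_point",
               "F_rod_y", "F_rod_z"]


@dataclass
class TrialLog:
    """Time series of one block plus everything needed to interpret it."""

    data: pd.DataFrame
    params: PendulumParams
    ee_model: EndEffectorModel
    targets: list[TargetSpec] = field(default_factory=list)
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(LOG_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"log is missing columns: {sorted(missing)}")

    @property
    def dt(self) -> float:
        t = self.data["t"].to_numpy()
        return float(t[1] - t[0])

    @property
    def duration(self) -> float:
        t = self.data["t"].to_numpy()
        return float(t[-1] - t[0])

    def ball_y(self) -> np.ndarray:
        return (self.data["y"].to_numpy()
                + self.params.l * np.sin(self.data["theta"].to_numpy()))

    def ball_z(self) -> np.ndarray:
        return (self.data["z"].to_numpy()
                - self.params.l * np.cos(self.data["theta"].to_numpy()))

    def assist_at_end_effector(self) -> np.ndarray:
        """Assist force commanded at the end-effector (zero where applied at the ball)."""
        at_ee = (self.data["assist_point"] == AssistPoint.END_EFFECTOR.value)
        return np.where(at_ee, self.data["F_assist_y"].to_numpy(), 0.0)

    # -- serialization ------------------------------------------------------

    def _header(self) -> dict:
        return {
            "params": vars(self.params).copy(),
            "ee_model": {"m_ee": self.ee_model.m_ee, "b_ee": self.ee_model.b_ee},
            "seed": int(self.seed),
            "meta": self.meta,
            "targets": targets_to_frame(self.targets).to_dict("list"),
        }

    def to_csv(self, path) -> None:
        path = Path(path)
        header = "# " + json.dumps(self._header()) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialLog":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError(f"{path} has no JSON header line")
            header = json.loads(first[1:])
            data = pd.read_csv(fh)
        ee = header["ee_model"]
        return cls(data=data,
                   params=PendulumParams(**header["params"]),
                   ee_model=EndEffectorModel(m_ee=ee["m_ee"], b_ee=ee["b_ee"]),
                   targets=targets_from_frame(pd.DataFrame(header["targets"])),
                   seed=header.get("seed", 0),
                   meta=header.get("meta", {}))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            grp = fh.create_group("trial")
            for col in LOG_COLUMNS:
                if col == "assist_point":
                    vals = self.data[col].astype("S16").to_numpy()
                else:
                    vals = self.data[col].to_numpy()
                grp.create_dataset(col, data=vals)
            grp.attrs["header"] = json.dumps(self._header())

    @classmethod
    def from_hdf5(cls, path) -> "TrialLog":
        import h5py

        with h5py.File(path, "r") as fh:
            grp = fh["trial"]
            cols = {}
            for col in LOG_COLUMNS:
                arr = grp[col][()]
                if col == "assist_point":
                    arr = np.char.decode(arr.astype("S16"))
                cols[col] = arr
            header = json.loads(grp.attrs["header"])
        ee = header["ee_model"]
        return cls(data=pd.DataFrame(cols),
                   params=PendulumParams(**header["params"]),
                   ee_model=EndEffectorModel(m_ee=ee["m_ee"], b_ee=ee["b_ee"]),
                   targets=targets_from_frame(pd.DataFrame(header["targets"])),
                   seed=header.get("seed", 0),
                   meta=header.get("meta", {}))
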