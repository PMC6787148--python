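"""Core signal containers: raw tri-axial acceleration and epoch activity counts.

An actigraph samples wrist acceleration at ``nu`` Hz (30 Hz by default).  The
central analysis signal is the *activity count series*: the number of samples
per non-overlapping epoch of length ``delta`` seconds whose gravity-corrected
acceleration magnitude exceeds a threshold.  Five canonical epoch lengths are
used throughout — 5, 10, 15, 30 and 60 s — named CP5s, CP10s, CP15s, CP30s and
CPM (counts per minute).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError, ParameterError

#: Acceleration of gravity used for unit conversion, m/s^2.
G_MS2 = 9.81

#: Canonical epoch lengths (s) -> resolution labels.
RESOLUTION_LABELS = {5: "CP5s", 10: "CP10s", 15: "CP15s", 30: "CP30s", 60: "CPM"}
VALID_DELTAS = tuple(RESOLUTION_LABELS)

_DEFAULT_START = pd.Timestamp("2024-01-01 00:00:00")


def resolution_label(delta: int) -> str:
    """Return the canonical name (CP5s ... CPM) for an epoch length in seconds."""
    try:
        return RESOLUTION_LABELS[int(delta)]
    except KeyError:
        raise ParameterError(
            f"epoch length must be one of {VALID_DELTAS} s, got {delta!r}"
        ) from None


@dataclass
class ActivityCountSeries:
    """Non-negative integer activity counts at a fixed epoch length.

    Parameters
    ----------
    counts : array-like of int
        One count per epoch; non-negative.
    delta : int
        Epoch length in seconds, one of 5, 10, 15, 30, 60.
    start_time : pandas.Timestamp
        Wall-clock time of the first epoch's start.
    label : str, optional
        Resolution name; defaults to the canonical label for ``delta``.
    """

    counts: np.ndarray
    delta: int
    start_time: pd.Timestamp = _DEFAULT_START
    label: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise InputError("counts must be one-dimensional")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int):
                raise InputError("counts must be integers")
            self.counts = as_int
        if self.counts.size and self.counts.min() < 0:
            raise InputError("counts must be non-negative")
        self.delta = int(self.delta)
        if self.delta not in VALID_DELTAS:
            raise ParameterError(
                f"epoch length must be one of {VALID_DELTAS} s, got {self.delta}"
            )
        self.start_time = pd.Timestamp(self.start_time)
        if self.label is None:
            self.label = RESOLUTION_LABELS[self.delta]

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        """Epoch start times."""
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.delta, unit="s"
        )

    @property
    def duration_seconds(self) -> int:
        """Total covered time in seconds."""
        return len(self) * self.delta

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write ``timestamp,count`` CSV; optionally a ``<path>.yaml`` sidecar."""
        frame = pd.DataFrame({"timestamp": self.timestamps, "count": self.counts})
        frame.to_csv(path, index=False)
        if sidecar is not None:
            meta = dict(sidecar)
            meta.setdefault("delta", self.delta)
            meta.setdefault("label", self.label)
            Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_csv(cls, path: str | Path, delta: int | None = None) -> "ActivityCountSeries":
        """Read a ``timestamp,count`` CSV; infer ``delta`` from timestamps if omitted."""
        frame = pd.read_csv(path, parse_dates=["timestamp"])
        if frame.empty:
            raise InputError(f"{path}: empty count series")
        if delta is None:
            if len(frame) < 2:
                raise InputError(f"{path}: cannot infer epoch length from one row")
            delta = int(
                (frame["timestamp"].iloc[1] - frame["timestamp"].iloc[0]).total_seconds()
            )
        return cls(
            counts=frame["count"].to_numpy(),
            delta=delta,
            start_time=frame["timestamp"].iloc[0],
        )


@dataclass
class RawAccelerationSeries:
    """Tri-axial acceleration samples in units of g at sampling frequency ``nu`` Hz."""

    samples: np.ndarray
    nu: float = 30.0
    start_time: pd.Timestamp = _DEFAULT_START

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InputError("samples must have shape (n, 3)")
        self.nu = float(self.nu)
        if self.nu <= 0:
            raise ParameterError("sampling frequency must be positive")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return int(self.samples.shape[0])

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write three float columns with a header naming axes and units (g)."""
        frame = pd.DataFrame(self.samples, columns=["ax_g", "ay_g", "az_g"])
        frame.to_csv(path, index=False)
        if sidecar is not None:
            meta = dict(sidecar)
            meta.setdefault("nu", self.nu)
            Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_csv(cls, path: str | Path, nu: float = 30.0) -> "RawAccelerationSeries":
        """Read a raw CSV; headers ``*_g`` or ``*_ms2`` select the unit (converted to g)."""
        frame = pd.read_csv(path)
        if frame.shape[1] < 3:
            raise InputError(f"{path}: expected three acceleration columns")
        cols = list(frame.columns[:3])
        data = frame[cols].to_numpy(dtype=float)
        if all(c.endswith("_ms2") for c in cols):
            data = data / G_MS2
        elif not all(c.endswith("_g") for c in cols):
            # Unlabelled columns are assumed to already be in g.
            pass
        return cls(samples=data, nu=nu)
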