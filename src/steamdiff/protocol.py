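"""Acquisition protocols, signal datasets and unit conventions.

Canonical internal units
------------------------
length  μm, time ms, diffusivity μm²/ms, b-value ms/μm², rates ms⁻¹.
b-values arrive from scanners in s/mm² and are converted exactly once at
ingest: 1 s/mm² = 1e-3 ms/μm².  Exchange and relaxation rates are
user-facing in s⁻¹ (the unit the field reports) and converted inside the
forward model.

The stimulated-echo (STEAM) protocol is parameterised by the diffusion
weighting b, the gradient separation Δ, the gradient pulse length δ, the
mixing time TM and the echo time TE.  The effective diffusion time is
tD = Δ − δ/3 (exact for rectangular gradient pulses) and the diffusion
wavevector follows from q² = b / tD, so gradient amplitude and the
gyromagnetic ratio are never required inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "B_S_PER_MM2_TO_MS_PER_UM2",
    "AcquisitionPoint",
    "AcquisitionProtocol",
    "SignalDataset",
    "diffusion_time",
    "q_from_b",
    "load_dataset",
    "save_dataset",
]

#: exact conversion factor applied once at ingest
B_S_PER_MM2_TO_MS_PER_UM2 = 1e-3

#: CSV schema (header names, ingest units)
CSV_COLUMNS = [
    "sample_id",
    "group",
    "b_s_per_mm2",
    "delta_sep_ms",
    "delta_pulse_ms",
    "tm_ms",
    "te_ms",
    "signal",
    "sigma",
]


@dataclass(frozen=True)
class AcquisitionPoint:
    """One diffusion-weighted measurement condition.

    Parameters
    ----------
    b : float
        Diffusion weighting in canonical units (ms/μm²).
    delta_sep : float
        Gradient separation Δ (ms).
    delta_pulse : float
        Gradient pulse length δ (ms).
    mixing_time : float
        STEAM mixing time TM (ms).
    echo_time : float
        Echo time TE (ms).
    """

    b: float
    delta_sep: float
    delta_pulse: float
    mixing_time: float
    echo_time: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not self.delta_sep >= self.delta_pulse > 0:
            raise ValueError(
                f"need delta_sep >= delta_pulse > 0, got Δ={self.delta_sep}, δ={self.delta_pulse}"
            )
        if self.diffusion_time <= 0:
            raise ValueError("derived diffusion time must be positive")

    @property
    def diffusion_time(self) -> float:
        """Effective diffusion time tD = Δ − δ/3 (ms)."""
        return self.delta_sep - self.delta_pulse / 3.0

    @property
    def q(self) -> float:
        """Diffusion wavevector q = sqrt(b / tD) (μm⁻¹)."""
        return float(np.sqrt(self.b / self.diffusion_time))


def diffusion_time(point: AcquisitionPoint) -> float:
    """Effective diffusion time tD = Δ − δ/3 of a protocol point (ms)."""
    return point.diffusion_time


def q_from_b(point: AcquisitionPoint) -> float:
    """Diffusion wavevector q (μm⁻¹) recovered from (b, tD).

    Defined so that q²·tD·D reproduces b·D exactly for any diffusivity D.
    """
    return point.q


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered collection of acquisition points, groupable by Δ."""

    points: tuple[AcquisitionPoint, ...]
    name: str = "protocol"

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if not any(p.b > 0 for p in self.points):
            raise ValueError("protocol needs at least one nonzero-b point")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def b(self) -> np.ndarray:
        return np.array([p.b for p in self.points])

    @property
    def delta_sep(self) -> np.ndarray:
        return np.array([p.delta_sep for p in self.points])

    @property
    def diffusion_times(self) -> np.ndarray:
        return np.array([p.diffusion_time for p in self.points])

    def delta_groups(self) -> dict[float, list[int]]:
        """Indices of points grouped by gradient separation Δ."""
        groups: dict[float, list[int]] = {}
        for i, p in enumerate(self.points):
            groups.setdefault(p.delta_sep, []).append(i)
        return dict(sorted(groups.items()))

    def sorted(self) -> "AcquisitionProtocol":
        """Stable sort of the points by (Δ, b)."""
        order = self.argsort()
        return replace(self, points=tuple(self.points[i] for i in order))

    def argsort(self) -> np.ndarray:
        keys = [(p.delta_sep, p.b) for p in self.points]
        return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)


@dataclass
class SignalDataset:
    """Per-ROI mean signal and noise estimate on an acquisition protocol.

    ``signal`` holds the ROI-mean magnitude signal for every protocol point
    and ``sigma`` the per-point noise standard deviation (ROI pixel std).
    Rows are kept sorted by (Δ, b).
    """

    protocol: AcquisitionProtocol
    signal: np.ndarray
    sigma: np.ndarray
    group: str = "control"
    sample_id: str = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.protocol)
        if self.signal.shape != (n,) or self.sigma.shape != (n,):
            raise ValueError(
                f"signal/sigma must have one value per protocol point ({n})"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        order = self.protocol.argsort()
        if not np.array_equal(order, np.arange(n)):
            self.protocol = replace(
                self.protocol, points=tuple(self.protocol.points[i] for i in order)
            )
            self.signal = self.signal[order]
            self.sigma = self.sigma[order]

    def __len__(self) -> int:
        return len(self.protocol)

    @property
    def nonzero_b(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) points."""
        return self.protocol.b > 0

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the on-disk schema (b back in s/mm²)."""
        pts = self.protocol.points
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "group": self.group,
                "b_s_per_mm2": [p.b / B_S_PER_MM2_TO_MS_PER_UM2 for p in pts],
                "delta_sep_ms": [p.delta_sep for p in pts],
                "delta_pulse_ms": [p.delta_pulse for p in pts],
                "tm_ms": [p.mixing_time for p in pts],
                "te_ms": [p.echo_time for p in pts],
                "signal": self.signal,
                "sigma": self.sigma,
            }
        )


def _dataset_from_frame(df: pd.DataFrame, name: str) -> SignalDataset:
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c not in ("sample_id", "group", "sigma")]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if np.any(df["signal"].to_numpy(dtype=float) < 0):
        raise ValueError("negative signal values in input")
    if "sigma" in df.columns:
        sigma = df["sigma"].to_numpy(dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
    else:
        # fall back to the pixel std of the b=0 group: one scalar per dataset
        b0 = df["b_s_per_mm2"].to_numpy(dtype=float) == 0
        if not b0.any():
            raise ValueError("no sigma column and no b=0 rows to estimate it from")
        s0_std = float(np.std(df.loc[b0, "signal"].to_numpy(dtype=float)))
        sigma = np.full(len(df), s0_std if s0_std > 0 else 1.0)
    points = tuple(
        AcquisitionPoint(
            b=float(r.b_s_per_mm2) * B_S_PER_MM2_TO_MS_PER_UM2,
            delta_sep=float(r.delta_sep_ms),
            delta_pulse=float(r.delta_pulse_ms),
            mixing_time=float(r.tm_ms),
            echo_time=float(r.te_ms),
        )
        for r in df.itertuples()
    )
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else name
    group = str(df["group"].iloc[0]) if "group" in df.columns else "control"
    return SignalDataset(
        protocol=AcquisitionProtocol(points=points, name=name),
        signal=df["signal"].to_numpy(dtype=float),
        sigma=np.asarray(sigma, dtype=float),
        group=group,
        sample_id=sample_id,
    )


def load_dataset(path: str | Path, format: str | None = None) -> SignalDataset:
    """Read a signal dataset from CSV or JSON.

    The CSV schema is ``sample_id, group, b_s_per_mm2, delta_sep_ms,
    delta_pulse_ms, tm_ms, te_ms, signal, sigma`` with b in s/mm²; the
    conversion to canonical ms/μm² happens here, exactly once.  JSON
    mirrors the field names one-to-one.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["points"])
        for key in ("sample_id", "group"):
            if key in payload:
                df[key] = payload[key]
    else:
        raise ValueError(f"unknown format {format!r}")
    return _dataset_from_frame(df, name=path.stem)


def save_dataset(dataset: SignalDataset, path: str | Path, format: str | None = None) -> Path:
    """Write a dataset to CSV or JSON in the on-disk schema (b in s/mm²)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    df = dataset.to_frame()
    if format == "csv":
        # 17 significant digits: float64 round-trips bit-exactly
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = {
            "sample_id": dataset.sample_id,
            "group": dataset.group,
            "points": df.drop(columns=["sample_id", "group"]).to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
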