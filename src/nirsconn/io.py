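"""Probe geometry and raw-intensity containers, plus SNIRF and CSV I/O.

A continuous-wave fNIRS montage is a set of light sources and detectors on
the scalp; every (source, detector, wavelength) triple defines a measurement
channel.  The spatial location attributed to a channel is the midpoint of its
source and detector positions, which is the coordinate later used for
spatial clustering.

The canonical on-disk format is SNIRF (an HDF5 container standardised by the
Society for functional Near-Infrared Spectroscopy); a plain-text CSV layout
is provided as a fallback for pipelines that avoid binary files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UnsupportedDataError, ValidationError

__all__ = [
    "Channel",
    "EventMarker",
    "ProbeGeometry",
    "IntensityRecording",
    "channel_midpoints",
    "read_snirf",
    "write_snirf",
    "read_csv_run",
    "write_csv_run",
]


class Channel(NamedTuple):
    """A measurement channel: indices into the source/detector tables plus
    the optical wavelength in nanometres.  Indices are 0-based."""

    source: int
    detector: int
    wavelength: float


class EventMarker(NamedTuple):
    """A stimulus block: onset and duration in seconds, plus a label."""

    onset: float
    duration: float
    label: str


@dataclass
class ProbeGeometry:
    """Optode montage with 3D coordinates (units are whatever the file uses;
    only relative distances matter downstream).

    ``channel_coords`` is derived: row *k* is the midpoint of channel *k*'s
    source and detector positions.  The two wavelength channels of one
    source-detector pair therefore share a single coordinate.
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    channels: list[Channel]
    channel_coords: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        self.detector_positions = np.asarray(self.detector_positions, dtype=float)
        self.channels = [Channel(*c) for c in self.channels]
        if self.source_positions.ndim != 2 or self.source_positions.shape[1] != 3:
            raise ValidationError("source_positions must be an (S, 3) array")
        if self.detector_positions.ndim != 2 or self.detector_positions.shape[1] != 3:
            raise ValidationError("detector_positions must be a (D, 3) array")
        if not self.channels:
            raise ValidationError("geometry must define at least one channel")
        n_src = len(self.source_positions)
        n_det = len(self.detector_positions)
        for k, ch in enumerate(self.channels):
            if not (0 <= ch.source < n_src):
                raise FormatError(
                    f"channel {k} references source {ch.source}, "
                    f"but only {n_src} sources exist"
                )
            if not (0 <= ch.detector < n_det):
                raise FormatError(
                    f"channel {k} references detector {ch.detector}, "
                    f"but only {n_det} detectors exist"
                )
        self.channel_coords = channel_midpoints(self)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def sd_distances(self) -> np.ndarray:
        """Euclidean source-detector separation per channel."""
        src = self.source_positions[[c.source for c in self.channels]]
        det = self.detector_positions[[c.detector for c in self.channels]]
        return np.linalg.norm(src - det, axis=1)

    def pairs(self) -> dict[tuple[int, int], list[int]]:
        """Group channel indices by (source, detector) pair, preserving
        first-appearance order of the pairs."""
        out: dict[tuple[int, int], list[int]] = {}
        for k, ch in enumerate(self.channels):
            out.setdefault((ch.source, ch.detector), []).append(k)
        return out


def channel_midpoints(geometry: ProbeGeometry) -> np.ndarray:
    """Coordinate matrix C (L x 3): row k = (source_k + detector_k) / 2.

    Permutation-equivariant by construction: reordering channels reorders
    rows identically.
    """
    src = geometry.source_positions[[c.source for c in geometry.channels]]
    det = geometry.detector_positions[[c.detector for c in geometry.channels]]
    return (src + det) / 2.0


@dataclass
class IntensityRecording:
    """Raw light intensities for one run (one experimental condition).

    ``intensities`` is channels x time, strictly positive (a logarithm is
    taken during optical-density conversion).  ``wavelengths`` duplicates the
    per-channel wavelength for convenience when the geometry is not at hand.
    """

    intensities: np.ndarray
    fs: float
    wavelengths: np.ndarray
    run_condition: str | None = None
    event_markers: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.event_markers = [EventMarker(*m) for m in self.event_markers]
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a channels x time matrix")
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        if len(self.wavelengths) != self.intensities.shape[0]:
            raise ValidationError(
                "wavelengths length must equal the number of channels"
            )
        if not np.all(self.intensities > 0):
            bad = np.argwhere(~(self.intensities > 0))
            raise DataError(
                f"non-positive intensity in channel {bad[0][0]} "
                f"(sample {bad[0][1]}); raw intensities must be > 0"
            )
        dur = self.duration_s
        for m in self.event_markers:
            if m.onset < 0 or m.onset > dur:
                raise ValidationError(
                    f"event marker onset {m.onset:.2f}s outside run "
                    f"duration {dur:.2f}s"
                )

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def duration_s(self) -> float:
        return self.intensities.shape[1] / self.fs


# ---------------------------------------------------------------------------
# SNIRF (HDF5) I/O
# ---------------------------------------------------------------------------

_CW_AMPLITUDE = 1  # SNIRF dataType code for continuous-wave amplitude


def write_snirf(geometry: ProbeGeometry, recording: IntensityRecording, path) -> None:
    """Write one run as a SNIRF v1.0 file (CW amplitude data).

    The run condition is stored under ``metaDataTags/RunCondition`` and each
    event marker becomes one row of a ``stim`` group (grouped by label).
    """
    if recording.n_channels != geometry.n_channels:
        raise ValidationError(
            f"recording has {recording.n_channels} channels but geometry "
            f"defines {geometry.n_channels}"
        )
    wavelengths = sorted({c.wavelength for c in geometry.channels})
    wl_index = {w: i + 1 for i, w in enumerate(wavelengths)}  # SNIRF is 1-based

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        if recording.run_condition is not None:
            meta.create_dataset("RunCondition", data=str(recording.run_condition))

        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries", data=recording.intensities.T.astype(np.float64)
        )
        t = np.arange(recording.n_samples) / recording.fs
        data.create_dataset("time", data=t)
        for k, ch in enumerate(geometry.channels):
            ml = data.create_group(f"measurementList{k + 1}")
            ml.create_dataset("sourceIndex", data=np.int32(ch.source + 1))
            ml.create_dataset("detectorIndex", data=np.int32(ch.detector + 1))
            ml.create_dataset("wavelengthIndex", data=np.int32(wl_index[ch.wavelength]))
            ml.create_dataset("dataType", data=np.int32(_CW_AMPLITUDE))
            ml.create_dataset("dataTypeIndex", data=np.int32(1))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
        probe.create_dataset("sourcePos3D", data=geometry.source_positions)
        probe.create_dataset("detectorPos3D", data=geometry.detector_positions)

        by_label: dict[str, list[EventMarker]] = {}
        for m in recording.event_markers:
            by_label.setdefault(m.label, []).append(m)
        for i, (label, markers) in enumerate(by_label.items(), start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=label)
            rows = np.array([[m.onset, m.duration, 1.0] for m in markers])
            stim.create_dataset("data", data=rows)


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path) -> tuple[ProbeGeometry, IntensityRecording]:
    """Read a continuous-wave SNIRF file written by :func:`write_snirf` (or
    any conforming SNIRF v1 file with CW amplitude data)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = f.get("nirs") or f.get("nirs1")
        if nirs is None:
            raise FormatError(f"{path}: no /nirs group; not a SNIRF file")
        probe = nirs.get("probe")
        if probe is None:
            raise FormatError(f"{path}: missing probe block")
        src = np.asarray(probe["sourcePos3D"], dtype=float)
        det = np.asarray(probe["detectorPos3D"], dtype=float)
        wavelengths = np.asarray(probe["wavelengths"], dtype=float)

        data = nirs.get("data1")
        if data is None:
            raise FormatError(f"{path}: missing data1 block")
        ts = np.asarray(data["dataTimeSeries"], dtype=float)  # time x channels
        time = np.asarray(data["time"], dtype=float)
        if time.size == 2 and ts.shape[0] > 2:
            fs = 1.0 / time[1]  # [start, dt] encoding
        else:
            dt = np.diff(time)
            fs = 1.0 / float(np.median(dt))

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        )
        if len(ml_names) != ts.shape[1]:
            raise FormatError(
                f"{path}: {len(ml_names)} measurementList entries for "
                f"{ts.shape[1]} data columns"
            )
        channels = []
        for name in ml_names:
            ml = data[name]
            dtype_code = int(ml["dataType"][()])
            if dtype_code != _CW_AMPLITUDE:
                raise UnsupportedDataError(
                    f"{path}: {name} has dataType {dtype_code}; only "
                    f"continuous-wave amplitude ({_CW_AMPLITUDE}) is supported"
                )
            s = int(ml["sourceIndex"][()]) - 1
            d = int(ml["detectorIndex"][()]) - 1
            wi = int(ml["wavelengthIndex"][()]) - 1
            if not (0 <= wi < len(wavelengths)):
                raise FormatError(f"{path}: {name} wavelengthIndex out of range")
            channels.append(Channel(s, d, float(wavelengths[wi])))

        markers: list[EventMarker] = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            label = _read_str(stim["name"])
            rows = np.atleast_2d(np.asarray(stim["data"], dtype=float))
            for row in rows:
                markers.append(EventMarker(float(row[0]), float(row[1]), label))
        markers.sort(key=lambda m: m.onset)

        run_condition = None
        meta = nirs.get("metaDataTags")
        if meta is not None and "RunCondition" in meta:
            run_condition = _read_str(meta["RunCondition"])

    geometry = ProbeGeometry(src, det, channels)
    recording = IntensityRecording(
        intensities=ts.T,
        fs=fs,
        wavelengths=np.array([c.wavelength for c in channels]),
        run_condition=run_condition,
        event_markers=markers,
    )
    return geometry, recording


# ---------------------------------------------------------------------------
# CSV fallback: intensities.csv + probe.csv + events.csv + meta.json
# ---------------------------------------------------------------------------


def write_csv_run(geometry: ProbeGeometry, recording: IntensityRecording, directory) -> None:
    """Plain-text alternative to SNIRF: a directory with intensities.csv
    (time column + one column per channel), probe.csv (sources, detectors
    and channel wiring), events.csv and meta.json."""
    if recording.n_channels != geometry.n_channels:
        raise ValidationError("recording/geometry channel count mismatch")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    t = np.arange(recording.n_samples) / recording.fs
    cols = {"time": t}
    for k in range(recording.n_channels):
        cols[f"ch{k}"] = recording.intensities[k]
    pd.DataFrame(cols).to_csv(directory / "intensities.csv", index=False)

    rows = []
    for i, p in enumerate(geometry.source_positions):
        rows.append(dict(role="source", index=i, x=p[0], y=p[1], z=p[2]))
    for i, p in enumerate(geometry.detector_positions):
        rows.append(dict(role="detector", index=i, x=p[0], y=p[1], z=p[2]))
    for i, ch in enumerate(geometry.channels):
        rows.append(
            dict(
                role="channel",
                index=i,
                source_index=ch.source,
                detector_index=ch.detector,
                wavelength_nm=ch.wavelength,
            )
        )
    pd.DataFrame(rows).to_csv(directory / "probe.csv", index=False)

    pd.DataFrame(
        [m._asdict() for m in recording.event_markers],
        columns=["onset", "duration", "label"],
    ).to_csv(directory / "events.csv", index=False)

    (directory / "meta.json").write_text(
        json.dumps({"fs": recording.fs, "run_condition": recording.run_condition})
    )


def read_csv_run(directory) -> tuple[ProbeGeometry, IntensityRecording]:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())

    probe = pd.read_csv(directory / "probe.csv")
    src = probe[probe.role == "source"].sort_values("index")
    det = probe[probe.role == "detector"].sort_values("index")
    chs = probe[probe.role == "channel"].sort_values("index")
    channels = [
        Channel(int(r.source_index), int(r.detector_index), float(r.wavelength_nm))
        for r in chs.itertuples()
    ]
    geometry = ProbeGeometry(
        src[["x", "y", "z"]].to_numpy(),
        det[["x", "y", "z"]].to_numpy(),
        channels,
    )

    intens = pd.read_csv(directory / "intensities.csv")
    ch_cols = [c for c in intens.columns if c.startswith("ch")]
    ch_cols.sort(key=lambda c: int(c[2:]))
    matrix = intens[ch_cols].to_numpy().T

    events = pd.read_csv(directory / "events.csv")
    markers = [
        EventMarker(float(r.onset), float(r.duration), str(r.label))
        for r in events.itertuples()
    ]
    rc = meta.get("run_condition")
    recording = IntensityRecording(
        intensities=matrix,
        fs=float(meta["fs"]),
        wavelengths=np.array([c.wavelength for c in channels]),
        run_condition=None if rc is None else str(rc),
        event_markers=markers,
    )
    return geometry, recording
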