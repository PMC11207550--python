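"""Signal chain: raw 84-point modulation cycles -> 27-channel absorbance spectra.

Per laser the detector is sampled off-on-off; the single-beam intensity is the
on-signal minus the mean of the two flanking dark samples.  The three trailing
dark samples of each cycle are excluded from that subtraction and surfaced only
as a dark-level diagnostic.  The 1%-split internal reference, after the same
dark correction, is rescaled by the gain ratio and the split ratio into an air
reference single-beam spectrum; absorbance is -log10(sample / corrected
reference).  The 157 frames of a 10-s recording are averaged (arithmetic mean
of per-frame absorbances; median available) into one spectrum, whose
temperature is assigned by linear interpolation of the thermistor trace at the
recording's mid time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataFormatError, RangeError, SignalError
from .synthetic import (
    CYCLE_LENGTH,
    N_LASERS,
    GeneratorConfig,
    RawRecording,
    TemperatureTrace,
)

__all__ = [
    "SingleBeamSpectrum",
    "AbsorbanceSpectrum",
    "demodulate",
    "demodulate_frames",
    "correct_reference",
    "compute_absorbance",
    "aggregate_recording",
    "assign_temperature",
    "process_dataset",
    "write_interchange",
    "read_interchange",
    "SPECTRUM_COLUMNS",
]

_OFF1 = 3 * np.arange(N_LASERS)
_ON = _OFF1 + 1
_OFF2 = _OFF1 + 2

#: absorbance column names in the interchange table
SPECTRUM_COLUMNS = [f"a{k + 1:02d}" for k in range(N_LASERS)]


@dataclass(frozen=True)
class SingleBeamSpectrum:
    """Dark-corrected per-laser intensities for one frame and channel."""

    intensities: np.ndarray
    channel: str
    frame_index: int = 0
    dark_level: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (N_LASERS,):
            raise DataFormatError(f"single-beam spectrum must have {N_LASERS} values")
        object.__setattr__(self, "intensities", arr)


@dataclass
class AbsorbanceSpectrum:
    """One recording's 27-channel absorbance with its temperature assignment."""

    absorbances: np.ndarray
    phantom_id: int
    step_index: int
    recording_index: int
    mid_time_s: float
    assigned_temperature_C: float | None = None
    outlier_flag: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.absorbances, dtype=float)
        if arr.shape != (N_LASERS,):
            raise DataFormatError(f"absorbance spectrum must have {N_LASERS} values")
        self.absorbances = arr
        if self.assigned_temperature_C is not None and not (
            15.0 <= self.assigned_temperature_C <= 30.0
        ):
            raise RangeError(
                f"assigned temperature {self.assigned_temperature_C} outside [15, 30]"
            )


def demodulate_frames(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised demodulation of ``(n, 84)`` cycles.

    Returns ``(intensities (n, 27), trailing_dark (n,))`` where intensity is
    on minus the mean of the two flanking offs, and trailing_dark is the mean
    of the last three (diagnostic-only) dark samples.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] != CYCLE_LENGTH:
        raise DataFormatError(f"modulation cycles must be (n, {CYCLE_LENGTH})")
    if not np.all(np.isfinite(frames)):
        raise DataFormatError("modulation cycles contain non-finite values")
    v = frames[:, _ON] - 0.5 * (frames[:, _OFF1] + frames[:, _OFF2])
    return v, frames[:, -3:].mean(axis=1)


def demodulate(cycle: Sequence[float] | np.ndarray, channel: str = "sample") -> SingleBeamSpectrum:
    """Demodulate one 84-point cycle into a 27-laser single-beam spectrum."""
    arr = np.asarray(cycle, dtype=float)
    if arr.shape != (CYCLE_LENGTH,):
        raise DataFormatError(f"modulation cycle must have {CYCLE_LENGTH} points, got {arr.shape}")
    v, dark = demodulate_frames(arr[None, :])
    return SingleBeamSpectrum(v[0], channel=channel, dark_level=float(dark[0]))


def correct_reference(
    ref: SingleBeamSpectrum | np.ndarray,
    gain_sample: float,
    gain_reference: float,
    split_fraction: float,
) -> SingleBeamSpectrum | np.ndarray:
    """Rescale the internal-reference spectrum into an air reference.

    Multiplies by (gain_sample / gain_reference) * ((1 - split) / split) so the
    result estimates the incident power on the sample path as seen by the
    sample detector.
    """
    if gain_sample <= 0 or gain_reference <= 0:
        raise ConfigError("detector gains must be positive")
    if not (0.0 < split_fraction < 1.0):
        raise ConfigError("split fraction must be in (0, 1)")
    factor = (gain_sample / gain_reference) * ((1.0 - split_fraction) / split_fraction)
    if isinstance(ref, SingleBeamSpectrum):
        return SingleBeamSpectrum(
            ref.intensities * factor, channel=ref.channel,
            frame_index=ref.frame_index, dark_level=ref.dark_level,
        )
    return np.asarray(ref, dtype=float) * factor


def compute_absorbance(
    sample: SingleBeamSpectrum | np.ndarray,
    corrected_ref: SingleBeamSpectrum | np.ndarray,
) -> np.ndarray:
    """A = -log10(sample / corrected reference), per laser.

    Raises :class:`SignalError` naming the first offending laser index if any
    intensity is non-positive (detector fault; never silently clipped).
    """
    s = sample.intensities if isinstance(sample, SingleBeamSpectrum) else np.asarray(sample, float)
    r = corrected_ref.intensities if isinstance(corrected_ref, SingleBeamSpectrum) else np.asarray(corrected_ref, float)
    for name, arr in (("sample", s), ("reference", r)):
        bad = np.nonzero(arr <= 0)[-1]
        if bad.size:
            raise SignalError(
                f"non-positive {name} intensity at laser index {int(bad[0])}"
            )
    return -np.log10(s / r)


def aggregate_recording(
    sample_frames: np.ndarray,
    reference_frames: np.ndarray,
    gain_sample: float,
    gain_reference: float,
    split_fraction: float,
    expected_frames: int = 157,
    stat: Literal["mean", "median"] = "mean",
) -> np.ndarray:
    """Demodulate and combine one recording's frames into a single spectrum.

    Per-frame absorbances are computed and reduced with ``stat`` (arithmetic
    mean by default).  ``expected_frames`` guards against truncated recordings
    and is configurable for reduced test datasets.
    """
    vs, _ = demodulate_frames(sample_frames)
    vr, _ = demodulate_frames(reference_frames)
    if vs.shape[0] != expected_frames or vr.shape[0] != expected_frames:
        raise DataFormatError(
            f"expected {expected_frames} frames per recording, got "
            f"{vs.shape[0]} sample / {vr.shape[0]} reference"
        )
    vr_corr = correct_reference(vr, gain_sample, gain_reference, split_fraction)
    bad_s = np.nonzero(vs <= 0)
    bad_r = np.nonzero(vr_corr <= 0)
    for name, bad in (("sample", bad_s), ("reference", bad_r)):
        if bad[0].size:
            raise SignalError(
                f"non-positive {name} intensity at frame {int(bad[0][0])}, "
                f"laser index {int(bad[1][0])}"
            )
    a = -np.log10(vs / vr_corr)
    if stat == "mean":
        return a.mean(axis=0)
    if stat == "median":
        return np.median(a, axis=0)
    raise ConfigError(f"unknown aggregation stat {stat!r}")


def assign_temperature(trace: TemperatureTrace, mid_time_s: float) -> float:
    """Linearly interpolate the thermistor trace at ``mid_time_s``.

    No extrapolation: a time outside the trace span raises :class:`RangeError`.
    An exact timestamp match returns that reading.
    """
    ts, rs = trace.timestamps_s, trace.readings_C
    if mid_time_s < ts[0] or mid_time_s > ts[-1]:
        raise RangeError(
            f"time {mid_time_s} s outside thermistor trace span [{ts[0]}, {ts[-1]}]"
        )
    return float(np.interp(mid_time_s, ts, rs))


def process_dataset(
    recordings: Iterable[RawRecording],
    traces: dict[int, TemperatureTrace],
    cfg: GeneratorConfig,
    stat: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Run the full signal chain over a raw dataset.

    Returns the interchange table: one row per recording with columns
    phantom_id, step_index, recording_index, mid_time_s, assigned_temp_C,
    outlier_flag, a01..a27.
    """
    rows = []
    rec_duration = cfg.frames_per_recording / cfg.frame_rate_hz
    for rec in recordings:
        a = aggregate_recording(
            rec.sample,
            rec.reference,
            cfg.gain_sample,
            cfg.gain_reference,
            cfg.reference_split_fraction,
            expected_frames=cfg.frames_per_recording,
            stat=stat,
        )
        mid = rec.start_time_s + rec_duration / 2.0
        temp = assign_temperature(traces[rec.phantom_id], mid)
        row = {
            "phantom_id": rec.phantom_id,
            "step_index": rec.step_index,
            "recording_index": rec.recording_index,
            "mid_time_s": mid,
            "assigned_temp_C": temp,
            "outlier_flag": False,
        }
        row.update(dict(zip(SPECTRUM_COLUMNS, a)))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["phantom_id", "step_index", "recording_index"], ignore_index=True
    )


_INTERCHANGE_HEADER = "# nirtherm interchange v1: one row per recording; a01..a27 in absorbance units\n"


def write_interchange(df: pd.DataFrame, path) -> None:
    """Write the interchange CSV with its schema-version header comment."""
    with open(path, "w") as fh:
        fh.write(_INTERCHANGE_HEADER)
        df.to_csv(fh, index=False)


def read_interchange(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ["phantom_id", "assigned_temp_C", *SPECTRUM_COLUMNS] if c not in df.columns]
    if missing:
        raise DataFormatError(f"interchange file {path} missing columns {missing}")
    return df
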