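"""Synthetic dual-channel spectrometer data for tissue-simulating phantoms.

Emulates the raw output of a 27-laser diffuse-reflectance spectrometer probing
a gelatin/Intralipid/water phantom over the first overtone O-H stretch of water
(grid default 1350-1590 nm).  The physics is deliberately minimal:

* The water band warms into a blue-shift, modelled as a weight exchange between
  a "cold" Gaussian (1460 nm) and a "hot" Gaussian (1412 nm); the fraction of
  weight on the hot band grows linearly with temperature at ``shift_rate_per_C``
  around a 22 degC reference.
* Gelatin contributes a fixed Gaussian band (1510 nm); Intralipid contributes a
  wavelength-sloped scattering baseline; each phantom additionally carries a
  random flat absorbance offset (interface/placement variability).
* Each 10-s recording consists of 157 modulation cycles (15.7 Hz).  A cycle is
  84 detector samples: 27 off-on-off laser triplets plus 3 trailing dark
  samples, for the sample and the 1%-split internal reference photodiode.
* Per-recording common-mode power drift, additive dark level, and relative
  detector noise corrupt both channels; optional interface-instability events
  add a flat absorbance offset over contiguous recording blocks.
* Phantom temperature follows the five-step Peltier profile through first-order
  relaxation with time constant ``thermal_time_constant_s`` and is logged every
  ``thermistor_interval_s`` seconds by the thermistor trace.

Randomness is split into one stream per phantom (seeded by ``(seed,
phantom_id)``) so adding a phantom never perturbs another phantom's data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, RangeError
from .phantoms import PhantomSpec, study_phantoms

__all__ = [
    "GeneratorConfig",
    "InstabilityEvent",
    "TemperatureTrace",
    "RawRecording",
    "true_absorbance",
    "simulate_temperature_trace",
    "simulate_dataset",
    "write_dataset",
    "read_frame_logs",
]

N_LASERS = 27
CYCLE_LENGTH = 84  # 27 off-on-off triplets + 3 trailing dark samples

TEMP_MIN_C = 15.0
TEMP_MAX_C = 30.0


@dataclass(frozen=True)
class InstabilityEvent:
    """A flat absorbance offset over a contiguous block of recordings.

    ``start``/``stop`` index recordings within the phantom's time-ordered
    0-99 sequence, half-open ``[start, stop)``.
    """

    phantom_id: int
    start: int
    stop: int
    offset_A: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ConfigError(
                f"instability event for phantom {self.phantom_id}: "
                f"need 0 <= start < stop, got [{self.start}, {self.stop})"
            )

    def covers(self, global_recording_index: int) -> bool:
        return self.start <= global_recording_index < self.stop


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic spectrometer.

    Defaults are the study conditions: 27 wavelengths, 5 steps x 20 recordings
    x 157 frames per phantom, 1% reference split, 300-s thermal time constant,
    1e-3 relative detector noise, 5e-3 common-mode drift, 0.02 A per-phantom
    offsets, no instability events.
    """

    wavelength_grid_nm: tuple[float, ...] = tuple(np.linspace(1350.0, 1590.0, N_LASERS))
    band_cold_center_nm: float = 1460.0
    band_hot_center_nm: float = 1412.0
    band_width_nm: float = 45.0
    shift_rate_per_C: float = 0.02
    reference_temperature_C: float = 22.0
    gelatin_band_center_nm: float = 1510.0
    gelatin_band_width_nm: float = 35.0
    gelatin_absorptivity: float = 0.3
    water_absorptivity: float = 1.0
    scatter_slope_per_nm_per_lipid_pct: float = 5e-5
    phantom_offset_sd_A: float = 0.02
    detector_noise_sd: float = 1e-3
    power_drift_sd: float = 5e-3
    gain_sample: float = 1.0
    gain_reference: float = 1.0
    reference_split_fraction: float = 0.01
    laser_power: float = 1.0
    dark_level: float = 0.01
    thermal_time_constant_s: float = 300.0
    thermistor_interval_s: float = 5.0
    ambient_start_C: float = 22.0
    frames_per_recording: int = 157
    recordings_per_step: int = 20
    frame_rate_hz: float = 15.7
    recording_period_s: float = 60.0
    step_duration_s: float = 1200.0
    instability_events: tuple[InstabilityEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_grid_nm, dtype=float)
        if grid.size != N_LASERS:
            raise ConfigError(f"wavelength grid must have {N_LASERS} values, got {grid.size}")
        if not np.all(np.diff(grid) > 0):
            raise ConfigError("wavelength grid must be strictly increasing")
        if not (0.0 < self.reference_split_fraction < 1.0):
            raise ConfigError("reference_split_fraction must be in (0, 1)")
        for name in (
            "phantom_offset_sd_A",
            "detector_noise_sd",
            "power_drift_sd",
            "band_width_nm",
            "gelatin_band_width_nm",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.thermal_time_constant_s <= 0:
            raise ConfigError("thermal_time_constant_s must be positive")
        if self.gain_sample <= 0 or self.gain_reference <= 0:
            raise ConfigError("detector gains must be positive")
        _check_event_overlap(self.instability_events)

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.wavelength_grid_nm, dtype=float)

    @property
    def recordings_per_phantom(self) -> int:
        return 5 * self.recordings_per_step

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def noiseless(self) -> "GeneratorConfig":
        """Copy with every stochastic amplitude set to zero (for oracles)."""
        return self.with_(
            phantom_offset_sd_A=0.0,
            detector_noise_sd=0.0,
            power_drift_sd=0.0,
            instability_events=(),
        )


def _check_event_overlap(events: Sequence[InstabilityEvent]) -> None:
    by_phantom: dict[int, list[InstabilityEvent]] = {}
    for ev in events:
        by_phantom.setdefault(ev.phantom_id, []).append(ev)
    for pid, evs in by_phantom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.stop:
                raise ConfigError(
                    f"overlapping instability events for phantom {pid}: "
                    f"[{a.start},{a.stop}) and [{b.start},{b.stop})"
                )


@dataclass(frozen=True)
class TemperatureTrace:
    """Thermistor log: strictly increasing timestamps and readings in degC."""

    timestamps_s: np.ndarray
    readings_C: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps_s, dtype=float)
        r = np.asarray(self.readings_C, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ConfigError("trace timestamps and readings must be matching 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ConfigError("trace timestamps must be strictly increasing")
        if np.any(r < TEMP_MIN_C) or np.any(r > TEMP_MAX_C):
            raise ConfigError(f"trace readings outside [{TEMP_MIN_C}, {TEMP_MAX_C}] degC")
        object.__setattr__(self, "timestamps_s", t)
        object.__setattr__(self, "readings_C", r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.timestamps_s, "temperature_C": self.readings_C})


@dataclass(frozen=True)
class RawRecording:
    """One 10-s recording: paired sample/reference modulation-cycle frames."""

    phantom_id: int
    step_index: int
    recording_index: int
    start_time_s: float
    sample: np.ndarray     # (frames, 84)
    reference: np.ndarray  # (frames, 84)

    def __post_init__(self) -> None:
        for name in ("sample", "reference"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != CYCLE_LENGTH:
                raise ConfigError(f"{name} frames must be (n, {CYCLE_LENGTH})")
            object.__setattr__(self, name, arr)
        if self.sample.shape != self.reference.shape:
            raise ConfigError("sample and reference frame blocks must match in shape")

    @property
    def n_frames(self) -> int:
        return self.sample.shape[0]


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


def _phantom_offset(phantom_id: int, cfg: GeneratorConfig) -> float:
    """Per-phantom flat absorbance offset, reproducible from (seed, phantom_id)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, phantom_id, 1]))
    return float(rng.normal(0.0, cfg.phantom_offset_sd_A)) if cfg.phantom_offset_sd_A > 0 else 0.0


def hot_band_weight(temperature_C: float | np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Fraction of water-band weight on the hot (blue) band at ``temperature_C``."""
    phi = 0.5 + cfg.shift_rate_per_C * (np.asarray(temperature_C, dtype=float) - cfg.reference_temperature_C)
    return np.clip(phi, 0.0, 1.0)


def true_absorbance(
    wavelength_nm: float | np.ndarray,
    temperature_C: float,
    phantom: PhantomSpec,
    cfg: GeneratorConfig,
) -> np.ndarray | float:
    """Noise-free absorbance of ``phantom`` at the given wavelength(s) and temperature.

    A(lambda, T) = w a_w [(1-phi) G_cold + phi G_hot] + g a_g G_gel
                   + scatter baseline + phantom offset,
    with phi = clip(0.5 + shift_rate (T - T_ref), 0, 1).  Warming moves weight
    from the cold to the hot (shorter-wavelength) band: the blue-shift.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    grid = cfg.grid
    if not (TEMP_MIN_C <= temperature_C <= TEMP_MAX_C):
        raise RangeError(
            f"temperature {temperature_C} degC outside [{TEMP_MIN_C}, {TEMP_MAX_C}]"
        )
    if np.any(lam < grid[0]) or np.any(lam > grid[-1]):
        raise RangeError("wavelength outside the configured grid span")

    phi = hot_band_weight(temperature_C, cfg)
    water = phantom.water_fraction * cfg.water_absorptivity * (
        (1.0 - phi) * _gaussian(lam, cfg.band_cold_center_nm, cfg.band_width_nm)
        + phi * _gaussian(lam, cfg.band_hot_center_nm, cfg.band_width_nm)
    )
    gelatin = phantom.gelatin_fraction * cfg.gelatin_absorptivity * _gaussian(
        lam, cfg.gelatin_band_center_nm, cfg.gelatin_band_width_nm
    )
    scatter = (
        cfg.scatter_slope_per_nm_per_lipid_pct
        * phantom.intralipid_pct
        * (grid[-1] - lam)
    )
    a = water + gelatin + scatter + _phantom_offset(phantom.phantom_id, cfg)
    return float(a[0]) if scalar else a


def phantom_temperature(t_s: float | np.ndarray, step_profile_C: Sequence[float], cfg: GeneratorConfig) -> np.ndarray:
    """Matrix temperature at time(s) ``t_s`` under first-order Peltier relaxation.

    Each 20-min step relaxes toward its set point with time constant tau,
    starting from the temperature reached at the end of the previous step
    (ambient before the first step).  Continuous across step boundaries.
    """
    if cfg.thermal_time_constant_s <= 0:
        raise ConfigError("thermal time constant must be positive")
    if len(step_profile_C) != 5:
        raise ConfigError("step profile must have exactly 5 set points")
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    out = np.empty_like(t)
    tau = cfg.thermal_time_constant_s
    dur = cfg.step_duration_s
    t_entry = cfg.ambient_start_C
    for k, t_set in enumerate(step_profile_C):
        t0, t1 = k * dur, (k + 1) * dur
        sel = (t >= t0) & (t < t1) if k < 4 else (t >= t0) & (t <= t1)
        out[sel] = t_set + (t_entry - t_set) * np.exp(-(t[sel] - t0) / tau)
        t_entry = t_set + (t_entry - t_set) * np.exp(-dur / tau)
    if np.any(t < 0) or np.any(t > 5 * dur):
        raise RangeError("time outside the five-step measurement window")
    return out


def simulate_temperature_trace(step_profile_C: Sequence[float], cfg: GeneratorConfig) -> TemperatureTrace:
    """Thermistor trace for one phantom: relaxation model sampled every interval."""
    n = int(round(5 * cfg.step_duration_s / cfg.thermistor_interval_s)) + 1
    ts = np.arange(n) * cfg.thermistor_interval_s
    return TemperatureTrace(ts, phantom_temperature(ts, step_profile_C, cfg))


# ---------------------------------------------------------------------------
# Raw stream synthesis
# ---------------------------------------------------------------------------

_ON_SLOTS = 3 * np.arange(N_LASERS) + 1


def _event_offset(phantom_id: int, global_rec: int, events: Sequence[InstabilityEvent]) -> float:
    return sum(ev.offset_A for ev in events if ev.phantom_id == phantom_id and ev.covers(global_rec))


def simulate_dataset(
    phantoms: Sequence[PhantomSpec] | None = None,
    cfg: GeneratorConfig | None = None,
) -> tuple[list[RawRecording], dict[int, TemperatureTrace], pd.DataFrame]:
    """Generate the full raw dataset for the given phantoms.

    Returns ``(recordings, traces, ledger)``.  The ledger is a DataFrame with
    one row per recording holding the ground truth: true mid-recording
    temperature, any instability offset applied, and the 27 true absorbances
    (columns ``true_a01``..``true_a27``).
    """
    if cfg is None:
        cfg = GeneratorConfig()
    if phantoms is None:
        phantoms = study_phantoms()
    if len(phantoms) == 0:
        raise ConfigError("need at least one phantom")

    grid = cfg.grid
    split = cfg.reference_split_fraction
    sample_scale = cfg.gain_sample * (1.0 - split) * cfg.laser_power
    ref_scale = cfg.gain_reference * split * cfg.laser_power

    recordings: list[RawRecording] = []
    traces: dict[int, TemperatureTrace] = {}
    ledger_rows: list[dict] = []

    for phantom in phantoms:
        pid = phantom.phantom_id
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, pid, 2]))
        traces[pid] = simulate_temperature_trace(phantom.step_profile_C, cfg)

        n_rec = cfg.recordings_per_phantom
        rec_duration = cfg.frames_per_recording / cfg.frame_rate_hz
        drift = 1.0 + (
            rng.normal(0.0, cfg.power_drift_sd, size=n_rec)
            if cfg.power_drift_sd > 0
            else np.zeros(n_rec)
        )

        for g in range(n_rec):
            step = g // cfg.recordings_per_step
            rec = g % cfg.recordings_per_step
            start = step * cfg.step_duration_s + rec * cfg.recording_period_s
            mid = start + rec_duration / 2.0
            t_true = float(phantom_temperature(mid, phantom.step_profile_C, cfg)[0])
            ev_offset = _event_offset(pid, g, cfg.instability_events)
            a_true = np.asarray(true_absorbance(grid, t_true, phantom, cfg)) + ev_offset

            nf = cfg.frames_per_recording
            sample = np.full((nf, CYCLE_LENGTH), cfg.dark_level)
            reference = np.full((nf, CYCLE_LENGTH), cfg.dark_level)
            sample[:, _ON_SLOTS] += sample_scale * drift[g] * 10.0 ** (-a_true)
            reference[:, _ON_SLOTS] += ref_scale * drift[g]
            if cfg.detector_noise_sd > 0:
                sample += rng.normal(
                    0.0, cfg.detector_noise_sd * sample_scale, size=sample.shape
                )
                reference += rng.normal(
                    0.0, cfg.detector_noise_sd * ref_scale, size=reference.shape
                )

            recordings.append(
                RawRecording(pid, step, rec, start, sample, reference)
            )
            row = {
                "phantom_id": pid,
                "step_index": step,
                "recording_index": rec,
                "start_time_s": start,
                "mid_time_s": mid,
                "true_temperature_C": t_true,
                "event_offset_A": ev_offset,
                "has_event": ev_offset != 0.0,
            }
            row.update({f"true_a{k + 1:02d}": a_true[k] for k in range(N_LASERS)})
            ledger_rows.append(row)

    return recordings, traces, pd.DataFrame(ledger_rows)


# ---------------------------------------------------------------------------
# Disk interchange (per-phantom frame logs, ledger JSON, trace CSVs)
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path,
    recordings: Iterable[RawRecording],
    traces: dict[int, TemperatureTrace],
    ledger: pd.DataFrame,
) -> Path:
    """Write frame logs (per-phantom CSV), traces (CSV) and the ledger (JSON).

    Frame-log columns: frame_index, slot_index (0-83), channel, value, with
    step/recording identifiers.  Intended for reduced configurations; the
    full-size study is normally piped in memory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_phantom: dict[int, list[RawRecording]] = {}
    for rec in recordings:
        by_phantom.setdefault(rec.phantom_id, []).append(rec)
    for pid, recs in sorted(by_phantom.items()):
        chunks = []
        for rec in recs:
            nf = rec.n_frames
            idx = pd.MultiIndex.from_product(
                [range(nf), range(CYCLE_LENGTH)], names=["frame_index", "slot_index"]
            ).to_frame(index=False)
            for channel, arr in (("sample", rec.sample), ("reference", rec.reference)):
                chunk = idx.copy()
                chunk.insert(0, "step_index", rec.step_index)
                chunk.insert(1, "recording_index", rec.recording_index)
                chunk.insert(2, "start_time_s", rec.start_time_s)
                chunk["channel"] = channel
                chunk["value"] = arr.reshape(-1)
                chunks.append(chunk)
        pd.concat(chunks, ignore_index=True).to_csv(
            out / f"phantom_{pid:02d}_frames.csv", index=False
        )
        traces[pid].to_frame().to_csv(out / f"phantom_{pid:02d}_trace.csv", index=False)
    ledger.to_json(out / "ledger.json", orient="records", indent=1)
    return out


def read_frame_logs(in_dir: str | Path) -> tuple[list[RawRecording], dict[int, TemperatureTrace]]:
    """Read back a frame-log directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    recordings: list[RawRecording] = []
    traces: dict[int, TemperatureTrace] = {}
    for path in sorted(in_dir.glob("phantom_*_frames.csv")):
        pid = int(path.stem.split("_")[1])
        df = pd.read_csv(path)
        for (step, rec_idx, start), grp in df.groupby(
            ["step_index", "recording_index", "start_time_s"], sort=True
        ):
            arrays = {}
            for channel, cgrp in grp.groupby("channel"):
                cgrp = cgrp.sort_values(["frame_index", "slot_index"])
                nf = cgrp["frame_index"].nunique()
                arrays[channel] = cgrp["value"].to_numpy().reshape(nf, CYCLE_LENGTH)
            recordings.append(
                RawRecording(pid, int(step), int(rec_idx), float(start),
                             arrays["sample"], arrays["reference"])
            )
        tdf = pd.read_csv(in_dir / f"phantom_{pid:02d}_trace.csv")
        traces[pid] = TemperatureTrace(
            tdf["time_s"].to_numpy(), tdf["temperature_C"].to_numpy()
        )
    recordings.sort(key=lambda r: (r.phantom_id, r.step_index, r.recording_index))
    return recordings, traces
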