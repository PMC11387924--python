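"""Cohort and report serialization.

A cohort lives in one directory per participant-night::

    cohort/
      manifest.json                # schema version, config, seed, ids
      p000/
        hypnogram.csv              # epoch_start_s, stage
        beats.csv                  # beat_s
        respiration.csv            # time_s, amplitude
        snore_trace.csv            # time_s, db
        events.json
        meta.json
        devices/<name>/
          hr.csv / br.csv          # epoch_start_s, value, quality_flag
          hypnogram.csv
          snore.csv                # epoch_start_s, snore
          summary.json             # ahi, bdi

CSV dialect: UTF-8, comma-separated, header row, '.' decimal, missing
values as empty fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .epochs import (
    BinarySeries,
    DEVICE_STAGES,
    EpochSeries,
    Hypnogram,
    REFERENCE_STAGES,
    Waveform,
)
from .errors import CohortFormatError
from .events import Event, EventList
from .records import DeviceNight, NightRecord
from .simulate import DEVICE_PRESETS, DeviceModel, SimulationConfig

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run: simulation settings, device
    models, metric options, thresholds and the master seed."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    devices: List[DeviceModel] = dataclasses.field(
        default_factory=lambda: [DEVICE_PRESETS[n]() for n in
                                 ("wsa", "emfit", "somnofy")])
    seed: int = 0
    max_lag_s: float = 300.0
    loa_multiplier: float = 1.96
    mape_aggregation: str = "pooled"
    sad_denominator: str = "pooled"

    def to_dict(self) -> Dict:
        sim = dataclasses.asdict(self.simulation)
        sim["stage_transition"] = np.asarray(sim["stage_transition"]).tolist()
        return {
            "schema_version": SCHEMA_VERSION,
            "simulation": sim,
            "devices": [dataclasses.asdict(d) for d in self.devices],
            "seed": self.seed,
            "max_lag_s": self.max_lag_s,
            "loa_multiplier": self.loa_multiplier,
            "mape_aggregation": self.mape_aggregation,
            "sad_denominator": self.sad_denominator,
        }

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        sim = dict(data.get("simulation", {}))
        if "stage_transition" in sim:
            sim["stage_transition"] = np.asarray(sim["stage_transition"])
        devices = []
        for d in data.get("devices", []):
            d = dict(d)
            for key in ("hr_clip", "br_clip"):
                if d.get(key) is not None:
                    d[key] = tuple(d[key])
            if "name" in d and set(d) == {"name"}:
                devices.append(DEVICE_PRESETS[d["name"]]())
            else:
                devices.append(DeviceModel(**d))
        kwargs = {k: data[k] for k in ("seed", "max_lag_s", "loa_multiplier",
                                       "mape_aggregation", "sad_denominator")
                  if k in data}
        return cls(simulation=SimulationConfig(**sim), devices=devices, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cohort round trip
# ---------------------------------------------------------------------------

def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def write_cohort(cohort: Sequence[NightRecord], directory,
                 config: Optional[RunConfig] = None, seed: Optional[int] = None
                 ) -> None:
    """Serialize a cohort; a manifest records schema, config and seed."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    ids = []
    for record in cohort:
        pid = record.participant_id
        ids.append(pid)
        pdir = root / pid
        pdir.mkdir(exist_ok=True)
        if record.hypnogram is not None:
            _write_csv(pdir / "hypnogram.csv", record.hypnogram.to_frame())
        if record.beats_s is not None:
            _write_csv(pdir / "beats.csv", pd.DataFrame({"beat_s": record.beats_s}))
        for channel, series in (("ref_hr", record.ref_hr), ("ref_br", record.ref_br)):
            if series is not None:
                _write_csv(pdir / f"{channel}.csv", series.to_frame())
        if record.respiration is not None:
            w = record.respiration
            _write_csv(pdir / "respiration.csv",
                       pd.DataFrame({"time_s": w.times_s, "amplitude": w.values}))
        if record.snore_trace is not None:
            w = record.snore_trace
            _write_csv(pdir / "snore_trace.csv",
                       pd.DataFrame({"time_s": w.times_s, "db": w.values}))
        if record.events is not None:
            payload = [dataclasses.asdict(e) for e in record.events]
            (pdir / "events.json").write_text(json.dumps({
                "night_duration_s": record.events.night_duration_s,
                "events": payload}, indent=1))
        meta = {"participant_id": pid, "setting": record.setting,
                "lights_off_s": record.lights_off_s,
                "lights_on_s": record.lights_on_s,
                "metadata": record.metadata}
        (pdir / "meta.json").write_text(json.dumps(meta, indent=1))
        for name, dev in record.devices.items():
            ddir = pdir / "devices" / name
            ddir.mkdir(parents=True, exist_ok=True)
            for channel, series in (("hr", dev.hr), ("br", dev.br)):
                if series is None:
                    continue
                df = series.to_frame()
                df["quality_flag"] = np.where(np.isnan(df["value"]), "missing", "ok")
                _write_csv(ddir / f"{channel}.csv", df)
            if dev.hypnogram is not None:
                _write_csv(ddir / "hypnogram.csv", dev.hypnogram.to_frame())
            if dev.snore_epochs is not None:
                _write_csv(ddir / "snore.csv", pd.DataFrame({
                    "epoch_start_s": dev.snore_epochs.epoch_start_s,
                    "snore": dev.snore_epochs.values.astype(int)}))
            (ddir / "summary.json").write_text(json.dumps(
                {"ahi": dev.ahi, "bdi": dev.bdi,
                 "epoch_s": dev.hypnogram.epoch_s if dev.hypnogram else None}))
    manifest = {"schema_version": SCHEMA_VERSION, "participants": ids,
                "seed": seed,
                "config": config.to_dict() if config is not None else None}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _require(path: Path, participant: str, channel: str) -> Path:
    if not path.exists():
        raise CohortFormatError(
            f"participant {participant!r}: missing channel {channel!r} ({path.name})")
    return path


def _read_epoch_series(path: Path, unit: str) -> EpochSeries:
    df = pd.read_csv(path)
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    step = float(np.round(np.median(np.diff(starts)))) if len(starts) > 1 else 30.0
    return EpochSeries(starts, df["value"].to_numpy(dtype=float), step, unit=unit)


def _read_hypnogram(path: Path) -> Hypnogram:
    df = pd.read_csv(path)
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    step = float(np.round(np.median(np.diff(starts)))) if len(starts) > 1 else 30.0
    stages = df["stage"].to_numpy(dtype=object)
    vocab = REFERENCE_STAGES if set(stages) <= set(REFERENCE_STAGES) else DEVICE_STAGES
    return Hypnogram(starts, stages, step, vocabulary=vocab)


def read_cohort(directory) -> List[NightRecord]:
    """Load a serialized cohort; raises :class:`CohortFormatError` naming
    the participant and channel when a required file is absent."""
    root = Path(directory)
    manifest_path = _require(root / "manifest.json", "<cohort>", "manifest")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise CohortFormatError(
            f"cohort schema version {version!r} != supported {SCHEMA_VERSION!r}")
    records = []
    for pid in manifest["participants"]:
        pdir = root / pid
        meta = json.loads(_require(pdir / "meta.json", pid, "meta").read_text())
        hyp = _read_hypnogram(_require(pdir / "hypnogram.csv", pid, "hypnogram"))
        beats = None
        if (pdir / "beats.csv").exists():
            beats = pd.read_csv(pdir / "beats.csv")["beat_s"].to_numpy(dtype=float)
        ref_hr = (_read_epoch_series(pdir / "ref_hr.csv", "bpm")
                  if (pdir / "ref_hr.csv").exists() else None)
        ref_br = (_read_epoch_series(pdir / "ref_br.csv", "cpm")
                  if (pdir / "ref_br.csv").exists() else None)
        respiration = None
        if (pdir / "respiration.csv").exists():
            df = pd.read_csv(pdir / "respiration.csv")
            t = df["time_s"].to_numpy(dtype=float)
            fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
            respiration = Waveform(fs=round(fs, 6), values=df["amplitude"].to_numpy(),
                                   start_s=float(t[0]))
        snore_trace = None
        if (pdir / "snore_trace.csv").exists():
            df = pd.read_csv(pdir / "snore_trace.csv")
            t = df["time_s"].to_numpy(dtype=float)
            fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
            snore_trace = Waveform(fs=round(fs, 6), values=df["db"].to_numpy(),
                                   start_s=float(t[0]))
        events = None
        if (pdir / "events.json").exists():
            payload = json.loads((pdir / "events.json").read_text())
            events = EventList([Event(**e) for e in payload["events"]],
                               night_duration_s=payload.get("night_duration_s"))
        record = NightRecord(
            participant_id=pid, setting=meta.get("setting", "lab"),
            beats_s=beats, respiration=respiration,
            ref_hr=ref_hr, ref_br=ref_br, hypnogram=hyp,
            snore_trace=snore_trace, events=events,
            lights_off_s=meta.get("lights_off_s", 0.0),
            lights_on_s=meta.get("lights_on_s", 0.0),
            metadata=meta.get("metadata", {}))
        devices_dir = pdir / "devices"
        if devices_dir.exists():
            for ddir in sorted(devices_dir.iterdir()):
                name = ddir.name
                dev = DeviceNight(device=name)
                if (ddir / "hr.csv").exists():
                    dev.hr = _read_epoch_series(ddir / "hr.csv", "bpm")
                if (ddir / "br.csv").exists():
                    dev.br = _read_epoch_series(ddir / "br.csv", "cpm")
                if (ddir / "hypnogram.csv").exists():
                    dev.hypnogram = _read_hypnogram(ddir / "hypnogram.csv")
                if (ddir / "snore.csv").exists():
                    df = pd.read_csv(ddir / "snore.csv")
                    starts = df["epoch_start_s"].to_numpy(dtype=float)
                    step = (float(np.round(np.median(np.diff(starts))))
                            if len(starts) > 1 else 30.0)
                    dev.snore_epochs = BinarySeries(
                        starts, df["snore"].to_numpy(dtype=bool), step)
                if (ddir / "summary.json").exists():
                    s = json.loads((ddir / "summary.json").read_text())
                    dev.ahi, dev.bdi = s.get("ahi"), s.get("bdi")
                record.devices[name] = dev
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def write_report(bundle: Dict, directory, config: Optional[RunConfig] = None) -> None:
    """Write a report bundle: DataFrames as CSV, everything else as JSON,
    plus a manifest with the schema version and config hash."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    json_payload = {}
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(root / f"{key}.csv", index=True)
        else:
            json_payload[key] = value
    if json_payload:
        (root / "report.json").write_text(json.dumps(json_payload, indent=1,
                                                     default=str))
    manifest = {"schema_version": SCHEMA_VERSION,
                "config_hash": config.config_hash() if config else None,
                "seed": config.seed if config else None,
                "files": sorted(p.name for p in root.iterdir())}
    (root / "report_manifest.json").write_text(json.dumps(manifest, indent=1))
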