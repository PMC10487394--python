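"""File contracts, configuration and run manifest.

Every inter-stage artifact is a flat UTF-8 CSV with a header row:

* RR export (one per participant):  beat_time_ms, rr_ms
* questionnaire table:              participant_id, timestamp, kss, sss
* truth channel (simulation only):  participant_id, time_point, state_name,
                                    vlf_power_target, lf_power_target,
                                    hf_power_target
* NN export + removal log:          beat_time_ms, rr_ms / index, reason
* observation table:                participant_id, time_point, kss, sss,
                                    then the 27 metric columns by name

Configuration is a single JSON file that round-trips losslessly; a run
manifest (JSON) records the config hash, input files, package version and
per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hrv_metrics import ALL_METRICS, SampleEntropyConfig, SpectralConfig
from .preprocess import FilterConfig, NNSeries, RRSeries, SegmentSpec

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "RunManifest",
    "read_rr_csv",
    "write_rr_csv",
    "read_questionnaire_csv",
    "write_questionnaire_csv",
    "write_nn_csv",
    "read_observations_csv",
    "write_observations_csv",
    "write_tables",
]

log = logging.getLogger("eveninghrv")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class DataError(ValueError):
    """Unreadable or contract-violating input data."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, JSON-(de)serializable."""

    filter: FilterConfig = FilterConfig()
    segments: SegmentSpec = SegmentSpec()
    spectral: SpectralConfig = SpectralConfig()
    sampen: SampleEntropyConfig = SampleEntropyConfig()
    recording_start: str = "19:45"
    sd_ddof: int = 0
    classifier_policy: str = "cohort_evening"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            raw = json.loads(text)
            return cls(
                filter=FilterConfig(**raw.get("filter", {})),
                segments=SegmentSpec(**{
                    k: tuple(v) if k == "time_points" else v
                    for k, v in raw.get("segments", {}).items()}),
                spectral=SpectralConfig(**{
                    k: tuple(v) if k.endswith("_band") else v
                    for k, v in raw.get("spectral", {}).items()}),
                sampen=SampleEntropyConfig(**raw.get("sampen", {})),
                recording_start=raw.get("recording_start", "19:45"),
                sd_ddof=int(raw.get("sd_ddof", 0)),
                classifier_policy=raw.get("classifier_policy", "cohort_evening"),
                seed=int(raw.get("seed", 0)),
            )
        except (TypeError, ValueError, KeyError) as e:
            raise ConfigError(f"bad configuration: {e}") from e

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    input_files: list = field(default_factory=list)
    version: str = __version__
    counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _read_csv_strict(path, columns, numeric, max_reject_frac=0.10):
    """Line-validated CSV reader: malformed rows are rejected and logged,
    > max_reject_frac rejected rows is a hard failure."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if list(df.columns) != list(columns):
        raise DataError(f"{path}: expected header {list(columns)}, got {list(df.columns)}")
    bad = np.zeros(len(df), dtype=bool)
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        newly = vals.isna().to_numpy() & ~bad
        for i in np.flatnonzero(newly):
            log.warning("%s: line %d rejected (bad %s=%r)", path, i + 2, col,
                        df[col].iloc[i])
        bad |= vals.isna().to_numpy()
        df[col] = vals
    if len(df) and bad.sum() / len(df) > max_reject_frac:
        raise DataError(f"{path}: {bad.sum()}/{len(df)} malformed rows (>10%)")
    return df.loc[~bad].reset_index(drop=True)


def read_rr_csv(path, participant_id: str = "") -> RRSeries:
    df = _read_csv_strict(path, ["beat_time_ms", "rr_ms"], ["beat_time_ms", "rr_ms"])
    bt = df["beat_time_ms"].to_numpy(dtype=float)
    if len(bt) > 1:
        drops = np.flatnonzero(np.diff(bt) <= 0)
        if len(drops):
            raise DataError(f"{path}: beat_time_ms not increasing at line {drops[0] + 3}")
    if np.any(df["rr_ms"].to_numpy(dtype=float) <= 0):
        i = int(np.flatnonzero(df["rr_ms"].to_numpy(dtype=float) <= 0)[0])
        raise DataError(f"{path}: non-positive rr_ms at line {i + 2}")
    return RRSeries(beat_time=bt, rr=df["rr_ms"].to_numpy(dtype=float),
                    participant_id=participant_id or Path(path).stem)


def write_rr_csv(series: RRSeries, path) -> None:
    pd.DataFrame({"beat_time_ms": series.beat_time, "rr_ms": series.rr}
                 ).to_csv(path, index=False, float_format="%.6f")


def read_questionnaire_csv(path) -> list:
    """Rows as (participant_id, timestamp 'HH:MM', kss, sss)."""
    df = _read_csv_strict(path, ["participant_id", "timestamp", "kss", "sss"],
                          ["kss", "sss"])
    rows = []
    for i, row in df.iterrows():
        ts = str(row["timestamp"])
        if ":" not in ts:
            log.warning("%s: line %d rejected (bad timestamp %r)", path, i + 2, ts)
            continue
        rows.append((str(row["participant_id"]), ts, int(row["kss"]), int(row["sss"])))
    return rows


def write_questionnaire_csv(rows, path) -> None:
    pd.DataFrame(rows, columns=["participant_id", "timestamp", "kss", "sss"]
                 ).to_csv(path, index=False)


def write_nn_csv(nn: NNSeries, path, log_path=None) -> None:
    write_rr_csv(nn, path)
    if log_path is not None:
        pd.DataFrame(list(nn.removal_log) or [], columns=["index", "reason"]
                     ).to_csv(log_path, index=False)


OBS_COLUMNS = ["participant_id", "time_point", "kss", "sss", *ALL_METRICS]


def write_observations_csv(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False, columns=[c for c in OBS_COLUMNS +
               [c for c in obs.columns if c not in OBS_COLUMNS]
               if c in obs.columns], float_format="%.10g")


def read_observations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing observation columns {missing}")
    return df


def write_tables(tables: dict, outdir) -> list:
    """Write each analysis table as <name>.csv under outdir; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(tables):
        p = outdir / f"{name}.csv"
        tables[name].to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    return paths
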