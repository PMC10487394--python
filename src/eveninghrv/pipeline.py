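"""End-to-end stage glue: simulate -> filter -> segments -> metrics ->
observation table. Used by both the CLI and programmatic callers."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .hrv_metrics import ALL_METRICS, compute_record
from .io import (DataError, PipelineConfig, write_questionnaire_csv,
                 write_rr_csv)
from .preprocess import (FilterConfig, NNSeries, SegmentSpec, align_questionnaire,
                         clock_to_ms, extract_segment, filter_nn)
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["simulate_to_dir", "observations_from_recordings", "truth_table"]

log = logging.getLogger("eveninghrv")


def simulate_to_dir(cohort_cfg: CohortConfig, outdir) -> dict:
    """Generate a cohort and write its RR exports, questionnaire and truth
    channel under outdir. Returns per-stage counts for the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recordings, q_rows = generate_cohort(cohort_cfg)
    for rec in recordings:
        write_rr_csv(rec.rr_series, outdir / f"rr_{rec.participant_id}.csv")
    write_questionnaire_csv(q_rows, outdir / "questionnaire.csv")
    truth_table(recordings).to_csv(outdir / "truth.csv", index=False)
    n_beats = sum(len(r.rr_series) for r in recordings)
    return {"recordings": len(recordings), "beats": n_beats,
            "questionnaire_rows": len(q_rows)}


def truth_table(recordings) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        for cell in rec.truth:
            rows.append({"participant_id": rec.participant_id, **cell})
    return pd.DataFrame(rows, columns=["participant_id", "time_point",
                                       "state_name", "vlf_power_target",
                                       "lf_power_target", "hf_power_target"])


def observations_from_recordings(rr_by_pid: dict, q_rows, cfg: PipelineConfig
                                 ) -> pd.DataFrame:
    """Filter each recording, cut grid-aligned segments, compute the metric
    battery and join questionnaire scores.

    rr_by_pid maps participant_id -> RRSeries (raw). Cells lacking a
    qualifying segment or a questionnaire match are dropped (logged).
    Returns the tidy observation table.
    """
    spec = cfg.segments
    scores = align_questionnaire(q_rows, spec, warn=log.warning)
    rows = []
    for pid in sorted(rr_by_pid):
        nn = filter_nn(rr_by_pid[pid], cfg.filter)
        for tp in spec.time_points:
            target = clock_to_ms(tp, cfg.recording_start)
            seg = extract_segment(nn, target, spec, cfg.filter,
                                  participant_id=pid, time_point=tp)
            if seg is None:
                log.warning("participant %s @ %s: no qualifying segment", pid, tp)
                continue
            if (pid, tp) not in scores:
                log.warning("participant %s @ %s: no questionnaire match", pid, tp)
                continue
            kss, sss = scores[(pid, tp)]
            rec = compute_record(seg, cfg.spectral, cfg.sampen, ddof=cfg.sd_ddof)
            rows.append({"participant_id": pid, "time_point": tp,
                         "kss": kss, "sss": sss, **rec})
    return pd.DataFrame(rows, columns=["participant_id", "time_point",
                                       "kss", "sss", *ALL_METRICS])
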