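"""Four-condition autonomic classifier over HRV records.

The framework distinguishes awake / stressed / drowsy / fatigued conditions
by the balance of normalized LF and HF band power relative to a reference:

* stressed — lfnu above, hfnu below reference (sympathetic dominance),
* drowsy  — lfnu below, hfnu above reference (vagal dominance), typically
  with reduced overall variability, lower cvi and modified_csi, higher
  sample entropy,
* the two remaining quadrants map to awake (both above) and fatigued (both
  below) by default; that assignment is configurable because the framework
  leaves those cells open.

The reference is a set of per-metric medians: by default the cohort at the
8 p.m. grid time — the biological-evening anchor separating the daytime and
nighttime circadian regimes. Auxiliary signature metrics (sdnn, cvi,
modified_csi, sampen) contribute direction flags and a concordance score
but never override the lfnu/hfnu quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceStats",
    "ConditionLabel",
    "SignatureTable",
    "DEFAULT_SIGNATURES",
    "build_reference",
    "classify_condition",
    "classify_observations",
    "evaluate_on_truth",
]

CONDITIONS = ("awake", "stressed", "drowsy", "fatigued")

# metrics a reference must carry; lfnu/hfnu decide, the rest are evidence
REFERENCE_METRICS = ("lfnu", "hfnu", "lf_hf_ratio", "sdnn", "cvi",
                     "modified_csi", "sampen")


@dataclass(frozen=True)
class SignatureTable:
    """Expected direction of change (vs reference) per condition.

    'increase' / 'decrease' per metric; metrics absent from a condition's
    row carry no expectation there. quadrant_assignment maps the two
    unspecified (lfnu, hfnu) quadrants.
    """

    stressed: dict = field(default_factory=lambda: {
        "lfnu": "increase", "hfnu": "decrease", "lf_hf_ratio": "increase"})
    drowsy: dict = field(default_factory=lambda: {
        "lfnu": "decrease", "hfnu": "increase", "lf_hf_ratio": "decrease",
        "sdnn": "decrease", "cvi": "decrease", "modified_csi": "decrease",
        "sampen": "increase"})
    quadrant_assignment: dict = field(default_factory=lambda: {
        ("above", "above"): "awake", ("below", "below"): "fatigued"})
    tie_label: str = "awake"

    def expected(self, condition: str) -> dict:
        return {"stressed": self.stressed, "drowsy": self.drowsy}.get(condition, {})


DEFAULT_SIGNATURES = SignatureTable()


@dataclass(frozen=True)
class ReferenceStats:
    """Per-metric reference medians plus the provenance of the stratum."""

    medians: dict
    source: str  # e.g. "cohort@20:00", "participant:P001", "user"

    def __post_init__(self) -> None:
        for k, v in self.medians.items():
            if not math.isfinite(v):
                raise ValueError(f"reference median for {k} is not finite")


@dataclass(frozen=True)
class ConditionLabel:
    label: str
    evidence: dict  # metric -> "increase" / "decrease" / "tie"
    concordance: float  # fraction of the label's signature metrics concordant
    reference_source: str
    boundary: bool = False  # lfnu/hfnu tie with the reference


def build_reference(obs: pd.DataFrame, policy: str = "cohort_evening",
                    *, anchor_time_point: Optional[str] = None,
                    participant_id: Optional[str] = None) -> ReferenceStats:
    """Per-metric medians over the chosen reference stratum.

    policy 'cohort_evening': all observations at the anchor grid time
    (default: the earliest time point, the 8 p.m. biological-evening
    anchor). policy 'participant': all observations of one participant.
    Requires >= 3 observations in the stratum.
    """
    if policy == "cohort_evening":
        tp = anchor_time_point or sorted(obs["time_point"].unique())[0]
        stratum = obs[obs["time_point"] == tp]
        source = f"cohort@{tp}"
    elif policy == "participant":
        if participant_id is None:
            raise ValueError("participant policy needs participant_id")
        stratum = obs[obs["participant_id"] == participant_id]
        source = f"participant:{participant_id}"
    else:
        raise ValueError(f"unknown reference policy {policy!r}")
    if len(stratum) < 3:
        raise ValueError(f"reference stratum too small (n={len(stratum)})")
    med = {m: float(stratum[m].median()) for m in REFERENCE_METRICS
           if m in stratum.columns}
    return ReferenceStats(medians=med, source=source)


def _direction(value: float, ref: float) -> str:
    if math.isnan(value) or math.isnan(ref) or value == ref:
        return "tie"
    return "increase" if value > ref else "decrease"


def classify_condition(record: dict, ref: ReferenceStats,
                       signatures: SignatureTable = DEFAULT_SIGNATURES
                       ) -> ConditionLabel:
    """Assign one of the four conditions from the lfnu/hfnu quadrant.

    (lfnu above ref, hfnu below) -> stressed; (below, above) -> drowsy;
    remaining quadrants per the configured assignment. A tie on either axis
    falls back to the least-committal tie label (default awake) with a
    boundary flag. Raises on missing lfnu/hfnu.
    """
    lfnu = record.get("lfnu", math.nan)
    hfnu = record.get("hfnu", math.nan)
    if math.isnan(lfnu) or math.isnan(hfnu):
        raise ValueError("record unclassifiable: lfnu/hfnu missing")
    d_lf = _direction(lfnu, ref.medians["lfnu"])
    d_hf = _direction(hfnu, ref.medians["hfnu"])
    boundary = "tie" in (d_lf, d_hf)
    if boundary:
        label = signatures.tie_label
    elif d_lf == "increase" and d_hf == "decrease":
        label = "stressed"
    elif d_lf == "decrease" and d_hf == "increase":
        label = "drowsy"
    else:
        key = ("above" if d_lf == "increase" else "below",
               "above" if d_hf == "increase" else "below")
        label = signatures.quadrant_assignment[key]

    evidence = {}
    for m in REFERENCE_METRICS:
        if m in ref.medians and m in record:
            evidence[m] = _direction(record[m], ref.medians[m])
    expected = signatures.expected(label)
    if expected:
        hits = [evidence.get(m) == d for m, d in expected.items() if m in evidence]
        concordance = float(np.mean(hits)) if hits else math.nan
    else:
        concordance = math.nan
    return ConditionLabel(label=label, evidence=evidence,
                          concordance=concordance,
                          reference_source=ref.source, boundary=boundary)


def classify_observations(obs: pd.DataFrame, ref: ReferenceStats,
                          signatures: SignatureTable = DEFAULT_SIGNATURES
                          ) -> pd.DataFrame:
    """Classify every observation row; returns a tidy classification table."""
    rows = []
    for _, row in obs.iterrows():
        rec = {m: row[m] for m in REFERENCE_METRICS if m in row.index}
        try:
            lab = classify_condition(rec, ref, signatures)
        except ValueError:
            rows.append({"participant_id": row["participant_id"],
                         "time_point": row["time_point"], "label": "unclassifiable",
                         "concordance": math.nan, "boundary": False})
            continue
        out = {"participant_id": row["participant_id"],
               "time_point": row["time_point"], "label": lab.label,
               "concordance": lab.concordance, "boundary": lab.boundary}
        out.update({f"dir_{m}": d for m, d in lab.evidence.items()})
        rows.append(out)
    return pd.DataFrame(rows)


def evaluate_on_truth(classified: pd.DataFrame, truth: pd.DataFrame
                      ) -> tuple[pd.DataFrame, float]:
    """Confusion table against the generator's truth channel.

    Returns (confusion, stressed_vs_drowsy_accuracy): the confusion table is
    truth state x predicted label over all matched cells; the accuracy is
    computed over cells whose true state is stressed or drowsy only — the
    discrimination the evening design turns on.
    """
    merged = classified.merge(truth, on=["participant_id", "time_point"],
                              how="inner", validate="one_to_one")
    confusion = pd.crosstab(merged["state_name"], merged["label"],
                            dropna=False)
    sub = merged[merged["state_name"].isin(["stressed", "drowsy"])]
    if len(sub):
        acc = float((sub["state_name"] == sub["label"]).mean())
    else:
        acc = math.nan
    return confusion, acc
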