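"""Synthetic evening cohort generator.

Emulates a home-based evening study: participants wear a chest-strap beat
logger from before 8 p.m. until bedtime and answer the Karolinska (KSS, 1-9)
and Stanford (SSS, 1-7) sleepiness scales every 30 minutes. Each
(participant, time point) cell carries a latent autonomic state — awake,
stressed, drowsy or fatigued — that fixes the spectral structure of the
beat-interval series and shifts the emitted sleepiness scores.

The tachogram model is a sum of narrowband random-phase harmonic processes,
one per analysis band (VLF/LF/HF), each with a programmed total variance,
plus per-beat white noise. Band powers of the generated series are therefore
analytically controlled, which is what makes parameter-recovery testing of
the spectral pipeline possible. An integrate-to-threshold pacemaker model
would be more physiological; it is deliberately not used because its band
powers are only approximately controllable.

A truth channel (per-cell state name and programmed band powers) is emitted
alongside the data and is never read by the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .preprocess import RRSeries, clock_to_ms

__all__ = [
    "AutonomicStateParams",
    "CohortConfig",
    "GeneratedRecording",
    "STATE_PRESETS",
    "default_state_schedule",
    "generate_rr_series",
    "inject_artifacts",
    "generate_cohort",
]


@dataclass(frozen=True)
class AutonomicStateParams:
    """Generative parameters of one latent autonomic state.

    Band-power targets are the population variances (ms^2) of the narrowband
    tachogram components; broadband_sd is per-beat white noise (ms);
    artifact/ectopic rates are expected events per minute.
    """

    state_name: str
    mean_rr: float
    vlf_power_target: float
    lf_power_target: float
    hf_power_target: float
    broadband_sd: float = 0.0
    artifact_rate: float = 0.0
    ectopic_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.state_name not in {"awake", "stressed", "drowsy", "fatigued"}:
            raise ValueError(f"unknown state {self.state_name!r}")
        if not (400.0 <= self.mean_rr <= 1300.0):
            raise ValueError("mean_rr outside physiological bounds [400, 1300] ms")
        if min(self.vlf_power_target, self.lf_power_target, self.hf_power_target) < 0:
            raise ValueError("power targets must be >= 0")
        if min(self.broadband_sd, self.artifact_rate, self.ectopic_rate) < 0:
            raise ValueError("rates and broadband_sd must be >= 0")


# Default state presets. Magnitudes are chosen to be typical of seated adults
# in the evening: total power a few thousand ms^2 when alert, sympathetic
# dominance (high normalized LF) when stressed, vagal dominance with an
# overall variability collapse when drowsy.
STATE_PRESETS: dict[str, AutonomicStateParams] = {
    "awake": AutonomicStateParams("awake", mean_rr=820.0, vlf_power_target=1200.0,
                                  lf_power_target=1300.0, hf_power_target=450.0,
                                  broadband_sd=8.0, artifact_rate=0.3,
                                  ectopic_rate=0.1),
    "stressed": AutonomicStateParams("stressed", mean_rr=760.0, vlf_power_target=1100.0,
                                     lf_power_target=1900.0, hf_power_target=210.0,
                                     broadband_sd=8.0, artifact_rate=0.3,
                                     ectopic_rate=0.1),
    "drowsy": AutonomicStateParams("drowsy", mean_rr=900.0, vlf_power_target=290.0,
                                   lf_power_target=330.0, hf_power_target=700.0,
                                   broadband_sd=5.0, artifact_rate=0.3,
                                   ectopic_rate=0.1),
    "fatigued": AutonomicStateParams("fatigued", mean_rr=860.0, vlf_power_target=420.0,
                                     lf_power_target=430.0, hf_power_target=260.0,
                                     broadband_sd=6.0, artifact_rate=0.3,
                                     ectopic_rate=0.1),
}

# Narrow synthesis sub-bands, kept away from the analysis-band edges so Welch
# leakage stays inside the right band.
_SYNTH_BANDS = {
    "vlf": (0.008, 0.032),
    "lf": (0.06, 0.13),
    "hf": (0.18, 0.34),
}
_HARMONICS_PER_BAND = 24


@dataclass(frozen=True)
class SleepinessCoupling:
    """Latent-Gaussian ordinal emission for KSS/SSS.

    The latent sleepiness for a cell is base + slope * hours-past-8pm +
    state_offset[state] + N(0, noise_sd); KSS is the latent clipped to 1-9,
    SSS a rescaled clip to 1-7. Stressed and drowsy states are the
    high-sleepiness states of the design, so they carry large offsets.
    """

    base: float = 3.6
    slope_per_hour: float = 1.1
    noise_sd: float = 0.9
    state_offset: tuple = (("awake", 0.0), ("stressed", 3.2),
                           ("drowsy", 3.2), ("fatigued", 1.5))

    def offsets(self) -> dict[str, float]:
        return dict(self.state_offset)


def default_state_schedule(n_participants: int, time_points, seed: int):
    """Random schedule mirroring the study narrative.

    A growing fraction of the cohort is in a high-sleepiness state as the
    evening progresses; at 8 p.m. that state is 'stressed' (biological-
    evening resistance), afterwards 'drowsy'. The remainder are 'awake'
    early and 'fatigued' occasionally late.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))
    high_frac = np.linspace(0.25, 0.7, num=len(time_points))
    schedule: dict[tuple[str, str], AutonomicStateParams] = {}
    for p in range(n_participants):
        pid = f"P{p+1:03d}"
        for k, tp in enumerate(time_points):
            if rng.random() < high_frac[k]:
                state = "stressed" if k == 0 else "drowsy"
            else:
                state = "awake" if k < 3 or rng.random() < 0.8 else "fatigued"
            schedule[(pid, tp)] = STATE_PRESETS[state]
    return schedule


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 32
    time_points: tuple[str, ...] = ("20:00", "20:30", "21:00", "21:30", "22:00")
    recording_start: str = "19:45"
    recording_span_min: float = 30.0  # minutes of recording per time point
    seed: int = 0
    state_schedule: Optional[dict] = None
    sleepiness_coupling: SleepinessCoupling = SleepinessCoupling()
    questionnaire_jitter_s: float = 300.0  # sd of completion-time offset, capped

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        mins = [clock_to_ms(tp, "00:00") for tp in self.time_points]
        if sorted(mins) != mins or len(set(mins)) != len(mins):
            raise ValueError("time_points must be strictly increasing")


@dataclass(frozen=True)
class GeneratedRecording:
    participant_id: str
    rr_series: RRSeries
    questionnaire_rows: tuple  # (clock, kss, sss)
    truth: tuple  # per time point: dict(state_name, programmed powers)
    artifact_mask: tuple  # indices into rr_series of injected artifact beats


def _tachogram(params: AutonomicStateParams, duration_s: float, rng) -> tuple:
    """Random-phase harmonic tachogram x(t) on a dense grid.

    Returns (grid_dt, x) where x[k] = x(k * grid_dt). Each band contributes
    `_HARMONICS_PER_BAND` cosines with equal amplitudes, total variance equal
    to the band's power target (sum of a^2/2 per cosine).
    """
    dt = 0.25  # s, 4 Hz grid
    t = np.arange(0.0, duration_s + 2.0, dt)
    x = np.full_like(t, params.mean_rr)
    for band, target in (("vlf", params.vlf_power_target),
                         ("lf", params.lf_power_target),
                         ("hf", params.hf_power_target)):
        if target <= 0:
            continue
        lo, hi = _SYNTH_BANDS[band]
        k = _HARMONICS_PER_BAND
        freqs = rng.uniform(lo, hi, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
        amp = np.sqrt(2.0 * target / k)
        x = x + amp * np.cos(2 * np.pi * freqs[:, None] * t[None, :]
                             + phases[:, None]).sum(axis=0)
    return dt, x


def _beats_from_tachogram(dt: float, x: np.ndarray, duration_s: float,
                          broadband_sd: float, rng) -> tuple:
    """Sample the tachogram at beat times: rr_i = x(t_{i-1}) + noise."""
    n_max = int(duration_s / 0.35) + 2  # rr >= ~350 ms floor
    noise = rng.normal(0.0, broadband_sd, size=n_max) if broadband_sd > 0 else np.zeros(n_max)
    beat_time = np.empty(n_max)
    rr = np.empty(n_max)
    t = 0.0
    i = 0
    nx = len(x)
    while True:
        gi = int(t / dt)
        if gi >= nx - 1:
            gi = nx - 2
        w = t / dt - gi
        val = x[gi] * (1.0 - w) + x[gi + 1] * w + noise[i]
        val = max(val, 300.0)  # keep time advancing under extreme noise
        t_next = t + val / 1000.0
        if t_next > duration_s or i >= n_max:
            break
        beat_time[i] = t_next * 1000.0
        rr[i] = val
        t = t_next
        i += 1
    return beat_time[:i], rr[:i]


def generate_rr_series(params: AutonomicStateParams, duration_s: float,
                       seed: int) -> RRSeries:
    """Beat-interval series with programmed VLF/LF/HF band powers.

    The tachogram is mean_rr plus one narrowband harmonic process per band
    (population variance = the band's power target) plus white per-beat
    noise of sd broadband_sd; beats are placed iteratively, each interval
    read off the tachogram at the previous beat time.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E1]))
    dt, x = _tachogram(params, duration_s, rng)
    beat_time, rr = _beats_from_tachogram(dt, x, duration_s, params.broadband_sd, rng)
    return RRSeries(beat_time=beat_time, rr=rr)


def inject_artifacts(rr: RRSeries, artifact_rate: float, ectopic_rate: float,
                     seed: int) -> tuple[RRSeries, np.ndarray]:
    """Insert spike and ectopic-beat artifacts; return (series, truth mask).

    Spikes replace an interval with a value outside the 400-1300 ms
    physiological bounds (total time is altered, as with a real sensor
    glitch). Ectopic events split one interval into an early short beat and
    its complement, preserving cumulative time. Counts are Poisson with the
    given per-minute rates. The mask lists output indices of injected beats
    that violate the physiological bounds by construction, so every masked
    beat is removable by the bound filter.
    """
    if artifact_rate < 0 or ectopic_rate < 0:
        raise ValueError("rates must be >= 0")
    if artifact_rate == 0 and ectopic_rate == 0:
        return rr, np.array([], dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA27]))
    minutes = (rr.beat_time[-1] - rr.beat_time[0]) / 60_000.0 if len(rr) else 0.0
    bt = list(rr.beat_time)
    iv = list(rr.rr)
    flags = [False] * len(iv)

    n_spike = rng.poisson(artifact_rate * minutes)
    for pos in rng.choice(len(iv), size=min(n_spike, len(iv)), replace=False):
        short = rng.random() < 0.5
        iv[pos] = float(rng.uniform(150.0, 340.0) if short else rng.uniform(1400.0, 1800.0))
        flags[pos] = True
    # rebuild beat times after spike resizing (spikes change elapsed time)
    bt = list(np.cumsum(iv) + (rr.beat_time[0] - rr.rr[0]))

    n_ect = rng.poisson(ectopic_rate * minutes)
    for _ in range(n_ect):
        pos = int(rng.integers(0, len(iv)))
        if flags[pos] or iv[pos] < 500.0:
            continue
        early = float(rng.uniform(150.0, min(340.0, iv[pos] - 150.0)))
        rest = iv[pos] - early
        t_end = bt[pos]
        bt[pos:pos + 1] = [t_end - rest, t_end]
        iv[pos:pos + 1] = [early, rest]
        # only the premature short beat is guaranteed filter-removable
        flags[pos:pos + 1] = [True, rest < 400.0 or rest > 1300.0]

    mask = np.flatnonzero(flags)
    out = RRSeries(beat_time=np.asarray(bt), rr=np.asarray(iv),
                   participant_id=rr.participant_id)
    return out, mask


def _emit_scores(cfg: CohortConfig, state_name: str, hours_past_8pm: float,
                 rng) -> tuple[int, int]:
    c = cfg.sleepiness_coupling
    latent = (c.base + c.slope_per_hour * hours_past_8pm
              + c.offsets()[state_name] + rng.normal(0.0, c.noise_sd))
    kss = int(np.clip(round(latent), 1, 9))
    # SSS spans 1-7 over the same latent range
    sss = int(np.clip(round(1.0 + (latent - 1.0) * 6.0 / 8.0), 1, 7))
    return kss, sss


def generate_cohort(config: CohortConfig = CohortConfig()):
    """Generate one recording plus questionnaire rows per participant.

    The recording is a concatenation of `recording_span_min`-minute blocks,
    one per time point, each synthesized from the cell's scheduled autonomic
    state; beat times are continuous across blocks. Sleepiness scores follow
    a latent trajectory that rises across the evening and is shifted upward
    in stressed/drowsy cells. Returns (recordings, questionnaire_rows) where
    questionnaire_rows is a tidy list of (participant_id, clock, kss, sss).
    """
    tps = config.time_points
    schedule = config.state_schedule
    if schedule is None:
        schedule = default_state_schedule(config.n_participants, tps, config.seed)
    pids = [f"P{p+1:03d}" for p in range(config.n_participants)]
    for pid in pids:
        for tp in tps:
            if (pid, tp) not in schedule:
                raise ValueError(f"state_schedule missing cell ({pid}, {tp})")

    span_ms = config.recording_span_min * 60_000.0
    grid_ms = [clock_to_ms(tp, config.recording_start) for tp in tps]
    recordings: list[GeneratedRecording] = []
    q_rows: list[tuple[str, str, int, int]] = []
    for p, pid in enumerate(pids):
        prng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + p]))
        bt_all, rr_all, mask_all, truth = [], [], [], []
        offset = 0.0
        for k, tp in enumerate(tps):
            params = schedule[(pid, tp)]
            block_seed = int(prng.integers(0, 2**31 - 1))
            block = generate_rr_series(params, span_ms / 1000.0, block_seed)
            block, mask = inject_artifacts(block, params.artifact_rate,
                                           params.ectopic_rate, block_seed + 1)
            # place block so its centre sits at the grid time
            start = grid_ms[k] - span_ms / 2.0
            start = max(start, offset)  # never overlap the previous block
            mask_all.extend(int(m) + len(bt_all) for m in mask)
            bt_all.extend(block.beat_time + start)
            rr_all.extend(block.rr)
            # artifacts may stretch the block past its nominal span; the next
            # block must begin after the last emitted beat either way
            offset = start + (block.beat_time[-1] if len(block) else span_ms) + 1.0
            truth.append({"time_point": tp, "state_name": params.state_name,
                          "vlf_power_target": params.vlf_power_target,
                          "lf_power_target": params.lf_power_target,
                          "hf_power_target": params.hf_power_target})
            # questionnaire completion time jitters around the grid time
            jit = float(np.clip(prng.normal(0.0, config.questionnaire_jitter_s),
                                -840.0, 840.0))  # keep inside the 15-min tolerance
            t_min = int(round((grid_ms[k] + jit * 1000.0) / 60_000.0))
            h0, m0 = (int(v) for v in config.recording_start.split(":"))
            total_min = h0 * 60 + m0 + t_min
            clock = f"{total_min // 60:02d}:{total_min % 60:02d}"
            hours = clock_to_ms(tp, "20:00") / 3_600_000.0
            kss, sss = _emit_scores(config, params.state_name, hours, prng)
            q_rows.append((pid, clock, kss, sss))
        series = RRSeries(beat_time=np.asarray(bt_all), rr=np.asarray(rr_all),
                          participant_id=pid)
        rows = tuple(r for r in q_rows if r[0] == pid)
        recordings.append(GeneratedRecording(
            participant_id=pid, rr_series=series,
            questionnaire_rows=tuple((c, k, s) for _, c, k, s in rows),
            truth=tuple(truth), artifact_mask=tuple(mask_all)))
    return recordings, q_rows
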