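"""Dual-channel synthetic accelerometry with a ground-truth clock model.

The generator emulates the situation the alignment method is built for:
two body-worn monitors recording the same person, each on its own
real-time clock. The reference device samples on the ideal clock (sample
``n`` at true time ``n/fs``); the secondary device's clock follows
C(t) = f*t + theta with skew ``f = 1 + skew_ppm * 1e-6`` and offset
``theta``, so its sample ``n`` is physically taken at true time
``f * n/fs + theta``. A positive offset therefore makes shared events
appear EARLIER (by sample index) in the secondary stream — a negative
lag under the pipeline's sign convention — and the implied ground truth
is ``beta0 = -offset_s * fs`` and ``beta1 = -skew_ppm * 1e-6 * fs``
(first-order in ppm; the quadratic correction is below 1e-7 samples/s
for realistic skews).

Movement content is scripted: gait-like bursts (a 2 Hz train of
heel-strike impulses — spectrally a 2 Hz fundamental with decaying 4 and
6 Hz harmonics — with per-step random amplitude so the correlogram's
central peak strictly dominates its ±0.5 s side peaks), sedentary noise,
and "unshared" blocks in which both channels move but independently —
these produce the gross lag outliers the robust fit must reject.
An optional sampling halt (the firmware fault seen in the field) shifts
the secondary clock by a fixed amount mid-recording.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .drift_model import AlignmentEstimate, accumulated_day7_drift_s
from .signal_io import TriaxialRecording, WearSite, write_csv

SEGMENT_KINDS = ("sedentary", "walk", "run", "unshared")


@dataclasses.dataclass(frozen=True)
class ClockSpec:
    """Ground-truth secondary clock: C(t) = (1 + skew_ppm*1e-6)*t + offset_s."""

    skew_ppm: float = 0.0
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.skew_ppm) > 1000:
            raise ValueError(f"|skew_ppm| must be <= 1000, got {self.skew_ppm}")

    @property
    def skew_factor(self) -> float:
        return 1.0 + self.skew_ppm * 1e-6


@dataclasses.dataclass(frozen=True)
class Segment:
    start_s: float
    duration_s: float
    kind: str
    amplitude_g: float = 0.4
    step_hz: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclasses.dataclass
class ActivityScript:
    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping segments at {a.start_s}-{a.end_s} and "
                    f"{b.start_s}-{b.end_s}")
        self.segments = segs


# ---------------------------------------------------------------------------
# Waveform model

_STEP_AMP_MOD = 0.5        # stride-to-stride amplitude variability
_RAMP_FRACTION = 0.15      # taper at burst edges
_STEP_WIDTH_FRAC = 0.14    # impulse width sigma as a fraction of the step period


def _gait_wave(t: np.ndarray, seg: Segment, phase_frac: float,
               step_amps: np.ndarray, cadence_scale: float = 1.0) -> np.ndarray:
    """Gait burst evaluated at absolute times ``t`` (true-time seconds).

    A train of Gaussian heel-strike impulses, one per step (period
    ``1/step_hz``), with random per-step amplitudes. The Fourier series
    of such a train is a fundamental at the step frequency plus decaying
    harmonics (~1:0.3:0.05 at the default impulse width), and — unlike a
    pure sinusoid — the train keeps its one-per-step periodicity through
    the rectification step of the pre-processing, which is what places
    the correlogram side peaks one step period from the centre.
    """
    period = 1.0 / (seg.step_hz * cadence_scale)
    sigma = _STEP_WIDTH_FRAC * period
    rel = t - seg.start_s
    ramp = min(5.0, _RAMP_FRACTION * seg.duration_s)
    env = np.clip(rel / ramp, 0.0, 1.0) * np.clip((seg.duration_s - rel) / ramp, 0.0, 1.0)
    pos = rel / period - phase_frac          # continuous step coordinate
    k = np.round(pos).astype(np.intp)
    w = np.zeros_like(rel)
    n_steps = len(step_amps)
    for off in (-1, 0, 1):
        ko = k + off
        inside = (ko >= 0) & (ko < n_steps)
        amps = np.where(inside, step_amps[np.clip(ko, 0, n_steps - 1)], 0.0)
        d = (pos - ko) * period
        w += amps * np.exp(-0.5 * (d / sigma) ** 2)
    return seg.amplitude_g * env * w


def _draw_burst_params(rng: np.random.Generator, seg: Segment) -> dict:
    n_steps = max(int(np.ceil(seg.duration_s * seg.step_hz)) + 2, 1)
    return {
        "phase_frac": float(rng.uniform(0.0, 1.0)),
        "step_amps": 1.0 + _STEP_AMP_MOD * rng.uniform(-1.0, 1.0, size=n_steps),
    }


def _sec_sample_times(n_lo: int, n_hi: int, fs: float, clock: ClockSpec,
                      halt: tuple[float, float] | None) -> np.ndarray:
    n = np.arange(n_lo, n_hi, dtype=np.float64)
    tau = clock.skew_factor * n / fs + clock.offset_s
    if halt is not None:
        halt_t, halt_dur = halt
        tau = np.where(tau >= halt_t, tau + halt_dur, tau)
    return tau


def generate_pair(script: ActivityScript, clock: ClockSpec, days: float,
                  fs: float = 30.0, seed: int = 0, noise_g: float = 0.008,
                  sec_amp_scale: float = 0.75, jitter_s: float = 0.010,
                  halt: tuple[float, float] | None = None,
                  ) -> tuple[TriaxialRecording, TriaxialRecording, AlignmentEstimate]:
    """Generate a reference/secondary pair plus its ground-truth alignment.

    Parameters
    ----------
    script:
        Movement schedule in true-time seconds.
    clock:
        Secondary device clock relative to the reference.
    days:
        Recording duration (both devices record the same sample count).
    noise_g:
        SD of the additive white sensor noise per axis (g). The default
        0.008 g keeps purely sedentary hours just below the 0.01 g
        activity gate (mean |ENMO| of N(0, sigma) noise is ~0.8*sigma).
    sec_amp_scale, jitter_s:
        Channel asymmetry of shared bursts: amplitude scaling and SD of a
        per-burst timing jitter on the secondary (wrist mechanics differ
        from hip mechanics).
    halt:
        Optional ``(time_s, duration_s)`` sampling halt of the secondary
        device: data recorded after ``time_s`` map to true times shifted
        ``duration_s`` later, emulating the firmware fault that produces
        abnormal apparent drift.
    seed:
        Single seed for every random draw (noise, phases, jitter).
    """
    if days <= 0:
        raise ValueError("days must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(days * 86_400.0 * fs))

    ref = (noise_g * rng.standard_normal((n, 3), dtype=np.float32))
    sec = (noise_g * rng.standard_normal((n, 3), dtype=np.float32))
    ref[:, 2] += 1.0
    sec[:, 2] += 1.0

    duration_s = n / fs
    f = clock.skew_factor
    halt_margin = (abs(halt[1]) if halt else 0.0) + abs(clock.offset_s) + 2.0

    for seg in script.segments:
        if seg.start_s >= duration_s * max(f, 1.0) + halt_margin:
            continue
        # parameter draw order is fixed so output is seed-deterministic
        shared = _draw_burst_params(rng, seg)
        jitter = float(rng.normal(0.0, jitter_s))
        if seg.kind == "unshared":
            indep = _draw_burst_params(rng, seg)
            cad_ref, cad_sec = 0.95, 1.07   # uncorrelated cadences
        else:
            indep = shared
            cad_ref = cad_sec = 1.0
        if seg.kind == "sedentary":
            continue

        # reference channel: ideal clock, t_n = n / fs
        i_lo = max(int(np.ceil(seg.start_s * fs)), 0)
        i_hi = min(int(np.floor(seg.end_s * fs)) + 1, n)
        if i_hi > i_lo:
            t = np.arange(i_lo, i_hi, dtype=np.float64) / fs
            w = _gait_wave(t, seg, shared["phase_frac"], shared["step_amps"],
                           cadence_scale=cad_ref)
            ref[i_lo:i_hi, 2] += w.astype(np.float32)
            ref[i_lo:i_hi, 0] += (0.35 * w).astype(np.float32)

        # secondary channel: warped clock
        lo_t = seg.start_s - halt_margin
        hi_t = seg.end_s + halt_margin
        j_lo = max(int(np.floor((lo_t - clock.offset_s) / f * fs)), 0)
        j_hi = min(int(np.ceil((hi_t - clock.offset_s) / f * fs)) + 1, n)
        if j_hi > j_lo:
            tau = _sec_sample_times(j_lo, j_hi, fs, clock, halt)
            mask = (tau >= seg.start_s) & (tau <= seg.end_s)
            if mask.any():
                params = indep if seg.kind == "unshared" else shared
                w = _gait_wave(tau[mask] - jitter, seg, params["phase_frac"],
                               params["step_amps"], cadence_scale=cad_sec)
                w = sec_amp_scale * w
                idx = np.arange(j_lo, j_hi)[mask]
                sec[idx, 2] += w.astype(np.float32)
                sec[idx, 0] += (0.35 * w).astype(np.float32)

    truth_beta0 = -clock.offset_s * fs
    truth_beta1 = -clock.skew_ppm * 1e-6 * fs
    truth = AlignmentEstimate(
        initial_offset_s=truth_beta0 / fs,
        drift_samples_per_s=truth_beta1,
        accumulated_day7_s=accumulated_day7_drift_s(truth_beta1, fs),
        working_fs=fs,
    )
    ref_rec = TriaxialRecording(samples=ref, fs=fs, device_id="ref",
                                wear_site=WearSite.hip)
    sec_rec = TriaxialRecording(samples=sec, fs=fs, device_id="sec",
                                wear_site=WearSite.wrist)
    return ref_rec, sec_rec, truth


def daily_routine_script(days: float, seed: int = 0, walks_per_day: int = 3,
                         walk_minutes: float = 10.0,
                         unshared_blocks: int = 0,
                         amp_range: tuple[float, float] = (0.25, 0.5),
                         step_hz: float = 2.0) -> ActivityScript:
    """Free-living-like schedule: a few gait bursts per day, rest sedentary.

    ``unshared_blocks`` inserts that many hours (spread across days, at
    05:30) in which both channels move independently — outlier fodder.
    """
    rng = np.random.default_rng(seed)
    base_hours = [8.25, 13.5, 18.75, 10.9, 16.1, 20.4][:walks_per_day]
    segments: list[Segment] = []
    n_days = int(np.ceil(days))
    for d in range(n_days):
        for h in base_hours:
            start = (d * 24.0 + h + rng.uniform(-0.3, 0.3)) * 3600.0
            if start / 86_400.0 >= days:
                continue
            segments.append(Segment(start_s=start, duration_s=walk_minutes * 60.0,
                                    kind="walk",
                                    amplitude_g=float(rng.uniform(*amp_range)),
                                    step_hz=step_hz))
    for k in range(unshared_blocks):
        d = int(np.floor(k * max(n_days, 1) / max(unshared_blocks, 1)))
        start = (d * 24.0 + 5.5) * 3600.0
        if start / 86_400.0 >= days:
            continue
        segments.append(Segment(start_s=start, duration_s=walk_minutes * 60.0,
                                kind="unshared",
                                amplitude_g=float(rng.uniform(*amp_range)),
                                step_hz=step_hz))
    return ActivityScript(segments=segments)


# ---------------------------------------------------------------------------
# Fixture suite

FIXTURE_NAMES = ("smoke", "full7d", "outlier_heavy", "abnormal_drift")


def _fixture_defs(seed: int) -> dict[str, dict]:
    return {
        "smoke": dict(
            days=600.0 / 86_400.0,
            clock=ClockSpec(skew_ppm=500.0, offset_s=0.5),
            script=ActivityScript([
                Segment(30.0, 90.0, "walk", 0.40),
                Segment(210.0, 90.0, "walk", 0.35),
                Segment(420.0, 120.0, "walk", 0.45),
            ]),
            jitter_s=0.002,
            config={"block_s": 120.0},
        ),
        "full7d": dict(
            days=7.0,
            clock=ClockSpec(skew_ppm=20.0, offset_s=2.0),
            script=daily_routine_script(7.0, seed=seed + 1),
            config={},
        ),
        "outlier_heavy": dict(
            days=1.0,
            clock=ClockSpec(skew_ppm=100.0, offset_s=-1.0),
            script=daily_routine_script(1.0, seed=seed + 2, walks_per_day=4,
                                        unshared_blocks=1),
            config={},
        ),
        "abnormal_drift": dict(
            days=2.0,
            clock=ClockSpec(skew_ppm=50.0, offset_s=1.0),
            script=daily_routine_script(2.0, seed=seed + 3, walks_per_day=4),
            halt=(86_400.0, 400.0),
            config={},
        ),
    }


def write_fixture_suite(outdir: str | Path, seed: int = 0,
                        which: tuple[str, ...] | None = None) -> dict:
    """Write deterministic fixture pairs and a JSON manifest of ground truths.

    ``which`` selects a subset of :data:`FIXTURE_NAMES` (the multi-day
    fixtures write CSVs of hundreds of MB; callers that only need a quick
    pair should request ``("smoke",)``). Same seed → byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = FIXTURE_NAMES if which is None else tuple(which)
    defs = _fixture_defs(seed)
    manifest: dict[str, dict] = {}
    for idx, name in enumerate(names):
        if name not in defs:
            raise ValueError(f"unknown fixture {name!r}")
        d = defs[name]
        ref, sec, truth = generate_pair(
            d["script"], d["clock"], d["days"], seed=seed + 100 + idx,
            jitter_s=d.get("jitter_s", 0.010), halt=d.get("halt"))
        ref_path = outdir / f"{name}_ref.csv"
        sec_path = outdir / f"{name}_sec.csv"
        write_csv(ref, ref_path)
        write_csv(sec, sec_path)
        manifest[name] = {
            "ref": ref_path.name,
            "sec": sec_path.name,
            "seed": seed,
            "days": d["days"],
            "clock": {"skew_ppm": d["clock"].skew_ppm,
                      "offset_s": d["clock"].offset_s},
            "halt": list(d["halt"]) if d.get("halt") else None,
            "config": d["config"],
            "truth": truth.to_dict(),
        }
    with open(outdir / "fixtures.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
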