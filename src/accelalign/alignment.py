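"""Stage III: resample the secondary recording onto the reference timebase.

Two steps: the initial offset is removed by trimming (positive offset:
the secondary runs late, so its first ``beta0`` samples are dropped) or
prepending (negative offset: samples replicating the first triple are
inserted — a gravity-consistent hold, since zero-g triples are physically
impossible at rest and would corrupt downstream ENMO). Then the residual
linear clock map is undone by resampling: output sample ``n`` reads the
secondary stream at source position ``n * (1 + drift / fs)``.

The default 'previous' (previous-neighbour hold) interpolation preserves
the original amplitude set — no new acceleration values are invented —
which keeps amplitude-sensitive intensity metrics intact. 'linear' and
'cubic' give smoother output for waveform-shape applications.
"""
from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.interpolate import CubicSpline

from .drift_model import AlignmentEstimate
from .signal_io import TriaxialRecording

log = logging.getLogger(__name__)

INTERPOLATION_METHODS = ("previous", "linear", "cubic")


@dataclasses.dataclass
class AlignedRecording:
    recording: TriaxialRecording
    applied: AlignmentEstimate
    interpolation: str


def apply_offset(rec: TriaxialRecording, offset_samples: int) -> TriaxialRecording:
    """Trim (positive offset) or prepend (negative) samples at the start.

    Prepended samples replicate the first sample triple.
    """
    offset_samples = int(offset_samples)
    if abs(offset_samples) >= rec.n_samples:
        raise ValueError(
            f"|offset| = {abs(offset_samples)} samples >= recording length "
            f"{rec.n_samples}")
    if offset_samples > 0:
        samples = rec.samples[offset_samples:]
    elif offset_samples < 0:
        pad = np.repeat(rec.samples[:1], -offset_samples, axis=0)
        samples = np.concatenate([pad, rec.samples], axis=0)
    else:
        return rec
    return rec.replace(samples=samples)


def apply_drift_resample(rec: TriaxialRecording, drift_samples_per_s: float,
                         method: str = "previous",
                         phase_samples: float = 0.0) -> TriaxialRecording:
    """Undo a linear clock drift by warped resampling.

    Output sample ``n`` reads the source at position
    ``n * (1 + drift_samples_per_s / fs) + phase_samples``. Positions
    beyond the source are truncated (count logged). The warp is anchored
    at the recording start, consistent with the offset being defined at
    time zero.
    """
    if method not in INTERPOLATION_METHODS:
        raise ValueError(f"method must be one of {INTERPOLATION_METHODS}")
    factor = 1.0 + drift_samples_per_s / rec.fs
    if factor <= 0:
        raise ValueError(f"non-monotone clock map (factor {factor})")
    n_src = rec.n_samples
    # number of output samples whose source position stays inside the data
    n_out = int(math.floor((n_src - 1 - phase_samples) / factor)) + 1
    n_out = max(min(n_out, int(math.ceil(n_src / factor)) + 1), 0)
    if n_out < 1:
        raise ValueError("drift warp leaves no samples inside the recording")
    if n_out < n_src:
        log.debug("drift resample truncates %d trailing samples", n_src - n_out)
    pos = np.arange(n_out, dtype=np.float64) * factor + phase_samples
    pos = np.clip(pos, 0.0, n_src - 1)
    src = np.asarray(rec.samples, dtype=np.float64)
    if method == "previous":
        idx = np.floor(pos).astype(np.intp)
        out = src[idx]
    elif method == "linear":
        grid = np.arange(n_src, dtype=np.float64)
        out = np.column_stack([np.interp(pos, grid, src[:, ax]) for ax in range(3)])
    else:  # cubic
        grid = np.arange(n_src, dtype=np.float64)
        out = CubicSpline(grid, src, axis=0)(pos)
    return rec.replace(samples=out)


def align_pair(ref: TriaxialRecording, sec: TriaxialRecording,
               est: AlignmentEstimate, method: str = "previous",
               round_offset: bool = False) -> AlignedRecording:
    """Apply an estimated offset and drift to the secondary recording.

    By default the fractional part of the offset is folded into the
    resampling phase (no half-sample rounding bias); ``round_offset=True``
    selects the strict integer mode, trimming by round(beta0) only.
    """
    if ref.fs != sec.fs:
        raise ValueError("reference and secondary must share the working rate")
    beta0 = est.initial_offset_s * sec.fs
    if round_offset:
        k, frac = int(round(beta0)), 0.0
    else:
        k = int(math.floor(beta0))
        frac = beta0 - k
    shifted = apply_offset(sec, k)
    corrected = apply_drift_resample(shifted, est.drift_samples_per_s,
                                     method=method, phase_samples=frac)
    return AlignedRecording(recording=corrected, applied=est, interpolation=method)
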