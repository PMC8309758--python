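"""Stage I block processing: per-hour lag estimation by cross-correlation.

Both preprocessed streams are cut into non-overlapping blocks (1 h by
default) on the nominal timebase. A block contributes one lag observation
when the raw movement level of *both* devices exceeds the activity gate —
a cross-correlation needs shared movement in both channels. The lag of a
block is the argmax of the coefficient-normalized cross-correlogram over
a ±``max_lag`` search window (±1000 samples = ±33.3 s at 30 Hz).

Sign convention (fixed here, relied on everywhere): a POSITIVE lag means
the secondary stream's events occur LATER than the reference's, i.e. the
secondary must be shifted backwards by ``lag`` samples to align.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as sps

from .preprocess import PreprocessedSignal

log = logging.getLogger(__name__)


class DegenerateBlockError(ValueError):
    """Block has zero variance after preprocessing; no lag can be estimated."""


class InsufficientBlocksError(ValueError):
    """Fewer than two usable lag observations; the drift fit is impossible."""

    def __init__(self, message: str, gate_table: list[dict] | None = None):
        super().__init__(message)
        self.gate_table = gate_table or []


@dataclasses.dataclass(frozen=True)
class LagObservation:
    """One per usable block: where, when and how confidently a lag was found."""

    block_index: int
    time_s: float           # block start on the reference timebase (s)
    lag_samples: int        # positive = secondary later
    peak_corr: float        # normalized correlation at the peak, in [-1, 1]


def partition_blocks(sig: PreprocessedSignal | np.ndarray, fs: float | None = None,
                     block_s: float = 3600.0) -> list[np.ndarray]:
    """Cut a signal into consecutive full blocks of ``block_s`` seconds.

    Blocks are anchored at the recording start; a trailing partial block
    is dropped. Returns views, not copies.
    """
    if isinstance(sig, PreprocessedSignal):
        values, fs = sig.values, sig.fs
    else:
        values = np.asarray(sig)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    n_block = int(round(block_s * fs))
    if n_block <= 0:
        raise ValueError("block_s * fs must be positive")
    n = len(values) // n_block
    return [values[i * n_block:(i + 1) * n_block] for i in range(n)]


def block_is_active(block_enmo: np.ndarray, threshold: float = 0.01) -> bool:
    """Activity gate: mean absolute ENMO strictly exceeds ``threshold`` (g).

    The gate is evaluated on raw per-sample ENMO (before dead-band and
    filtering) so that it measures movement, not filter output.
    """
    block_enmo = np.asarray(block_enmo)
    if block_enmo.size == 0:
        raise ValueError("empty block")
    return bool(np.mean(np.abs(block_enmo)) > threshold)


def correlogram(ref_block: np.ndarray, sec_block: np.ndarray,
                max_lag: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient-normalized cross-correlogram over lags −max_lag…+max_lag.

    Normalization divides the raw correlation by sqrt(Σref² · Σsec²) —
    the global 'coeff' scaling, so the zero-lag autocorrelation of a
    signal with itself is exactly 1.
    """
    ref = np.asarray(ref_block, dtype=np.float64)
    sec = np.asarray(sec_block, dtype=np.float64)
    if ref.shape != sec.shape or ref.ndim != 1:
        raise ValueError("blocks must be 1-D and of equal length")
    denom = np.sqrt(float(ref @ ref) * float(sec @ sec))
    if denom == 0.0:
        raise DegenerateBlockError("zero-variance block")
    method = "fft" if len(ref) * max_lag > 50_000 else "direct"
    c_full = sps.correlate(sec, ref, mode="full", method=method)
    lags_full = sps.correlation_lags(len(sec), len(ref), mode="full")
    center = len(ref) - 1
    lo = max(center - max_lag, 0)
    hi = min(center + max_lag, len(c_full) - 1)
    return lags_full[lo:hi + 1], c_full[lo:hi + 1] / denom


def _argmax_lag(lags: np.ndarray, corr: np.ndarray) -> int:
    """Peak lag with tie-breaking: smallest |lag|, then the negative one."""
    peak = corr.max()
    cands = lags[corr == peak]
    if len(cands) > 1:
        log.info("correlogram peak tie among lags %s; taking smallest |lag|",
                 cands.tolist())
    return int(min(cands, key=lambda k: (abs(k), k)))


def estimate_block_lag(ref_block: np.ndarray, sec_block: np.ndarray,
                       max_lag: int = 1000) -> tuple[int, float]:
    """Lag (samples) and peak correlation for one block pair.

    Positive lag = secondary later than reference.
    """
    lags, corr = correlogram(ref_block, sec_block, max_lag=max_lag)
    lag = _argmax_lag(lags, corr)
    return lag, float(corr[lags == lag][0])


def _block_time(mode: str, i: int, block_s: float, fs: float,
                ref_block: np.ndarray, sec_block: np.ndarray) -> float:
    """Reference time assigned to block ``i``'s lag observation.

    'start' and 'midpoint' are the obvious anchors, but the lag of a
    block is physically measured at the time of the shared movement
    inside it — 'centroid' (default) uses the activity-weighted centroid
    of the two preprocessed signals, which removes an intercept bias of
    up to ``drift * block_s`` samples that a fixed anchor incurs when
    movement sits late in its block.
    """
    t0 = i * block_s
    if mode == "start":
        return t0
    if mode == "midpoint":
        return t0 + block_s / 2.0
    if mode == "centroid":
        w = ref_block * sec_block
        total = float(w.sum())
        if total <= 0.0:
            return t0 + block_s / 2.0
        return t0 + float(w @ np.arange(len(w))) / total / fs
    raise ValueError(f"unknown block_time_mode {mode!r}")


def collect_lag_series(ref: PreprocessedSignal, sec: PreprocessedSignal,
                       ref_enmo: np.ndarray, sec_enmo: np.ndarray,
                       block_s: float = 3600.0, activity_gate_g: float = 0.01,
                       max_lag_samples: int = 1000,
                       min_peak_corr: float = 0.0,
                       block_time_mode: str = "centroid") -> list[LagObservation]:
    """One LagObservation per block where both devices pass the activity gate.

    Blocks are paired index-aligned on the nominal timebase; the true
    misalignment between paired blocks (bounded by the clock offset) is
    absorbed by the ±``max_lag_samples`` search window. ``time_s`` is on
    the reference device's timebase, anchored per ``block_time_mode``
    (see :func:`_block_time`).
    """
    obs, _ = collect_lag_series_with_diagnostics(
        ref, sec, ref_enmo, sec_enmo, block_s=block_s,
        activity_gate_g=activity_gate_g, max_lag_samples=max_lag_samples,
        min_peak_corr=min_peak_corr, block_time_mode=block_time_mode)
    return obs


def collect_lag_series_with_diagnostics(
        ref: PreprocessedSignal, sec: PreprocessedSignal,
        ref_enmo: np.ndarray, sec_enmo: np.ndarray,
        block_s: float = 3600.0, activity_gate_g: float = 0.01,
        max_lag_samples: int = 1000, min_peak_corr: float = 0.0,
        block_time_mode: str = "centroid",
) -> tuple[list[LagObservation], list[dict]]:
    """As :func:`collect_lag_series`, additionally returning a per-block
    diagnostic table (gate decisions and lags for every block, including
    gated-out ones)."""
    if ref.fs != sec.fs:
        raise ValueError("both signals must share the working rate")
    ref_blocks = partition_blocks(ref, block_s=block_s)
    sec_blocks = partition_blocks(sec, block_s=block_s)
    ref_gate = partition_blocks(ref_enmo, fs=ref.fs, block_s=block_s)
    sec_gate = partition_blocks(sec_enmo, fs=sec.fs, block_s=block_s)

    observations: list[LagObservation] = []
    gate_table: list[dict] = []
    for i in range(min(len(ref_blocks), len(sec_blocks))):
        active_ref = block_is_active(ref_gate[i], activity_gate_g)
        active_sec = block_is_active(sec_gate[i], activity_gate_g)
        row = {"block_index": i, "time_s": i * block_s,
               "active_ref": active_ref, "active_sec": active_sec,
               "lag": None, "peak_corr": None}
        gate_table.append(row)
        if not (active_ref and active_sec):
            log.debug("block %d gated out (ref active=%s, sec active=%s)",
                      i, active_ref, active_sec)
            continue
        try:
            lag, peak = estimate_block_lag(ref_blocks[i], sec_blocks[i],
                                           max_lag=max_lag_samples)
        except DegenerateBlockError as exc:
            log.info("block %d dropped: %s", i, exc)
            continue
        if peak < min_peak_corr:
            log.info("block %d dropped: peak_corr %.3f < %.3f",
                     i, peak, min_peak_corr)
            continue
        row["lag"], row["peak_corr"] = lag, peak
        log.info("block %d: lag=%+d samples, peak_corr=%.3f", i, lag, peak)
        t_obs = _block_time(block_time_mode, i, block_s, ref.fs,
                            ref_blocks[i], sec_blocks[i])
        observations.append(LagObservation(block_index=i, time_s=t_obs,
                                           lag_samples=lag, peak_corr=peak))
    if len(observations) < 2:
        raise InsufficientBlocksError(
            f"insufficient active blocks: {len(observations)} usable "
            f"observation(s) from {len(gate_table)} block(s)", gate_table)
    return observations, gate_table


def side_peak_spacing_s(lags: np.ndarray, corr: np.ndarray, fs: float,
                        min_prominence_frac: float = 0.15) -> float | None:
    """Mean distance (s) from the global correlogram peak to its nearest
    side peaks.

    For gait-driven blocks the side peaks sit one step period away from
    the central peak (0.5 s at the common 2 Hz step frequency) — the
    correlation of one step with its neighbours. The prominence floor
    (fraction of the peak value) ignores the shallow ripple that
    rectified signals superimpose between step correlations. Returns
    None when no side peak is found on either side.
    """
    k0 = _argmax_lag(lags, corr)
    peaks, _ = sps.find_peaks(corr, prominence=min_prominence_frac * corr.max())
    peak_lags = lags[peaks]
    left = peak_lags[peak_lags < k0]
    right = peak_lags[peak_lags > k0]
    dists = []
    if left.size:
        dists.append(k0 - left.max())
    if right.size:
        dists.append(right.min() - k0)
    if not dists:
        return None
    return float(np.mean(dists)) / fs


def max_lag_window_s(max_lag: int = 1000, fs: float = 30.0) -> float:
    """Half-width of the lag search window in seconds (1000 @ 30 Hz → 33.3 s)."""
    return max_lag / fs
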