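"""Stage II: linear lag-vs-time model with iterative outlier exclusion.

The observed block lags are modelled as

    lag(i) = beta1 * time(i) + beta0

where ``beta1`` (samples/s) is the relative clock drift between the two
devices and ``beta0`` (samples) the initial offset at the reference
recording start. The model rests on the RTC picture C(t) = f*t + theta:
a constant relative skew f produces a lag that is exactly linear in time.

Blocks whose movement is not shared between wear sites (arm-only
activity, say) yield lags that are invalid data points rather than noisy
ones. They are removed by iteratively refitting ordinary least squares
and dropping points whose standardized residual exceeds a threshold that
grows exponentially across iterations: t0 = 1, t_{k+1} = exp(t_k),
giving 1, 2.718..., 15.15..., after which the recurrence explodes and
naturally stops excluding anything.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .lag_estimation import LagObservation

log = logging.getLogger(__name__)

_ZERO_RESIDUAL_RMSE = 1e-12
SECONDS_PER_DAY = 86_400.0


@dataclasses.dataclass(frozen=True)
class ExclusionRecord:
    block_index: int
    iteration: int
    standardized_residual: float


@dataclasses.dataclass
class DriftFit:
    """OLS fit of lag on time after outlier exclusion.

    ``rmse`` is the regression residual standard error
    sqrt(SSE / (n − 2)), in samples; ``r2`` the coefficient of
    determination of the final (post-exclusion) fit.
    """

    beta0: float                 # initial offset, samples
    beta1: float                 # drift, samples per second
    rmse: float
    r2: float
    n_used: int
    excluded: list[ExclusionRecord]
    iterations: int
    degenerate: bool = False
    beta0_se: float = float("nan")
    beta1_se: float = float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded"] = [dataclasses.asdict(e) for e in self.excluded]
        return d


@dataclasses.dataclass
class AlignmentEstimate:
    """Drift fit converted to physical units.

    ``initial_offset_s`` = beta0 / working_fs;
    ``accumulated_day7_s`` = beta1 / working_fs * 86400 * 7, the total
    misalignment in seconds accumulated over a 7-day recording.
    """

    initial_offset_s: float
    drift_samples_per_s: float
    accumulated_day7_s: float
    working_fs: float = 30.0
    fit: DriftFit | None = None

    @property
    def beta0_samples(self) -> float:
        return self.initial_offset_s * self.working_fs

    def to_dict(self) -> dict:
        d = {
            "initial_offset_s": self.initial_offset_s,
            "drift_samples_per_s": self.drift_samples_per_s,
            "accumulated_day7_s": self.accumulated_day7_s,
            "working_fs": self.working_fs,
        }
        if self.fit is not None:
            d["fit"] = self.fit.to_dict()
        return d


# ---------------------------------------------------------------------------
# OLS core


@dataclasses.dataclass
class _OLS:
    beta0: float
    beta1: float
    resid: np.ndarray
    rmse: float
    r2: float
    leverage: np.ndarray
    beta0_se: float
    beta1_se: float


def _ols(t: np.ndarray, y: np.ndarray) -> _OLS:
    n = len(t)
    t_mean = t.mean()
    sxx = float(((t - t_mean) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("singular design: all time points identical")
    beta1 = float(((t - t_mean) * (y - y.mean())).sum() / sxx)
    beta0 = float(y.mean() - beta1 * t_mean)
    resid = y - (beta0 + beta1 * t)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    dfe = max(n - 2, 1)
    rmse = math.sqrt(sse / dfe)
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    leverage = 1.0 / n + (t - t_mean) ** 2 / sxx
    beta1_se = rmse / math.sqrt(sxx)
    beta0_se = rmse * math.sqrt(1.0 / n + t_mean ** 2 / sxx)
    return _OLS(beta0, beta1, resid, rmse, r2, leverage, beta0_se, beta1_se)


def exclusion_thresholds(explicit: Sequence[float] | None = None) -> Iterable[float]:
    """Yield per-iteration thresholds: the explicit list if given, else the
    recurrence t0 = 1, t_{k+1} = exp(t_k)."""
    if explicit is not None:
        yield from explicit
        return
    t = 1.0
    while True:
        yield t
        t = math.exp(t) if t < 700 else math.inf


def fit_drift(observations: Sequence[LagObservation],
              residual_mode: str = "standardized",
              threshold_sequence: Sequence[float] | None = None,
              exclusion_mode: str = "all") -> DriftFit:
    """Fit lag = beta1 * time + beta0 with iterative outlier exclusion.

    At iteration k the current OLS fit's standardized residuals are
    compared against threshold t_k; every point beyond it is dropped and
    the model refit. The loop stops when an iteration drops nothing, when
    residuals are exactly zero, or when fewer than 2 points would remain
    (the previous fit is kept and flagged ``degenerate``).
    """
    if len(observations) < 2:
        raise ValueError(f"need at least 2 observations, got {len(observations)}")
    obs = list(observations)
    t = np.array([o.time_s for o in obs], dtype=np.float64)
    y = np.array([o.lag_samples for o in obs], dtype=np.float64)

    active = np.arange(len(obs))
    excluded: list[ExclusionRecord] = []
    fit = _ols(t[active], y[active])
    iterations = 0
    degenerate = False

    thresholds = exclusion_thresholds(threshold_sequence)
    for k, thr in enumerate(thresholds):
        if fit.rmse < _ZERO_RESIDUAL_RMSE:
            break
        if residual_mode == "studentized":
            denom = fit.rmse * np.sqrt(np.clip(1.0 - fit.leverage, 1e-12, None))
        else:
            denom = fit.rmse
        sr = fit.resid / denom
        out = np.abs(sr) > thr
        if exclusion_mode == "worst" and out.sum() > 1:
            worst = np.argmax(np.abs(sr))
            out = np.zeros_like(out)
            out[worst] = True
        if not out.any():
            break
        if len(active) - int(out.sum()) < 2:
            log.warning("iteration %d would leave < 2 points; keeping previous fit", k)
            degenerate = True
            break
        for j in np.flatnonzero(out):
            excluded.append(ExclusionRecord(
                block_index=obs[active[j]].block_index,
                iteration=k,
                standardized_residual=float(sr[j])))
            log.debug("iteration %d: excluding block %d (standardized residual %.2f > %.2f)",
                      k, obs[active[j]].block_index, sr[j], thr)
        active = active[~out]
        fit = _ols(t[active], y[active])
        iterations = k + 1

    return DriftFit(beta0=fit.beta0, beta1=fit.beta1, rmse=fit.rmse, r2=fit.r2,
                    n_used=len(active), excluded=excluded, iterations=iterations,
                    degenerate=degenerate,
                    beta0_se=fit.beta0_se, beta1_se=fit.beta1_se)


def to_alignment_estimate(fit: DriftFit, working_fs: float = 30.0) -> AlignmentEstimate:
    """Convert a sample-domain fit to seconds (offset, accumulated day-7 drift)."""
    return AlignmentEstimate(
        initial_offset_s=fit.beta0 / working_fs,
        drift_samples_per_s=fit.beta1,
        accumulated_day7_s=accumulated_day7_drift_s(fit.beta1, working_fs),
        working_fs=working_fs,
        fit=fit,
    )


def accumulated_day7_drift_s(drift_samples_per_s: float, working_fs: float = 30.0) -> float:
    """Total drift in seconds accumulated after 7 days at the given rate."""
    return drift_samples_per_s / working_fs * SECONDS_PER_DAY * 7.0


def reference_from_manual_marks(offset_start: float, offset_end: float,
                                time_start: float, time_end: float,
                                working_fs: float = 30.0) -> AlignmentEstimate:
    """Drift/offset from two manually identified alignment marks.

    Given the sample shifts that visually align the two streams near the
    recording start and end, the drift is the slope between the marks and
    the initial offset the back-extrapolation to time zero:

        drift = (offset_end − offset_start) / (time_end − time_start)
        initial offset (samples) = offset_start − drift * time_start
    """
    if time_end == time_start:
        raise ValueError("time_end must differ from time_start")
    drift = (offset_end - offset_start) / (time_end - time_start)
    beta0 = offset_start - drift * time_start
    fit = DriftFit(beta0=beta0, beta1=drift, rmse=0.0, r2=1.0, n_used=2,
                   excluded=[], iterations=0)
    return AlignmentEstimate(
        initial_offset_s=beta0 / working_fs,
        drift_samples_per_s=drift,
        accumulated_day7_s=accumulated_day7_drift_s(drift, working_fs),
        working_fs=working_fs,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Closed-form RTC arithmetic


def skew_drift_s(skew_ppm: float, duration_s: float = 7 * SECONDS_PER_DAY) -> float:
    """Clock error in seconds accumulated by a ``skew_ppm`` clock over
    ``duration_s`` (default 7 days): 20 ppm → 12.096 s."""
    return skew_ppm * 1e-6 * duration_s


def relative_skew_ppm(skew_a_ppm: float, skew_b_ppm: float) -> float:
    """Relative skew between two devices; ±20 ppm worst case → 40 ppm."""
    return skew_b_ppm - skew_a_ppm


def temperature_skew_ppm(delta_temp_c: float,
                         coeff_ppm_per_c2: float = -0.04) -> float:
    """RTC skew induced by a temperature deviation of the crystal.

    Typical crystals lose ~0.04 ppm per squared °C away from their turnover
    temperature, so a 5 °C difference between wear sites contributes only
    ~1 ppm — which is why temperature is left out of the drift model.
    """
    return coeff_ppm_per_c2 * delta_temp_c ** 2
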