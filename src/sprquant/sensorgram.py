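"""Sensorgram processing and synthetic two-channel data generation.

File format: tab-delimited text with ``#``-prefixed ``key = value`` metadata
header lines followed by a header row ``time_s\tresponse_deg\tchannel``.

Synthetic sensorgrams follow the Langmuir 1:1 interaction model

    dR/dt = k_on * C * (R_max - R) - k_off * R

whose association phase has the closed form
``R(t) = R_eq * (1 - exp(-(k_on*C + k_off) * t))`` with
``R_eq = R_max * k_on * C / (k_on * C + k_off)``, and whose dissociation
phase decays as ``exp(-k_off * t)`` from the end-of-association level.
An optional bulk refractive-index jump (present only while analyte flows)
and a linear drift model the common-mode artifacts removed by
reference-channel subtraction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from sprquant.errors import FitError, SensorgramFormatError, ValidationError

_COLUMNS = ("time_s", "response_deg", "channel")

#: Default assay metadata mirroring the instrument settings.
DEFAULT_METADATA = {
    "flow_rate_ul_min": 20.0,
    "temperature_c": 20.0,
    "analyte": "",
    "concentration_um": float("nan"),
}


@dataclass(frozen=True)
class Sensorgram:
    """Time series of SPR angular response for one flow channel."""

    time: np.ndarray
    response: np.ndarray
    channel: str = "ch1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValidationError("time and response must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValidationError(
                f"time must be strictly increasing (violated at sample {bad})"
            )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class InjectionSchedule:
    """Timing of one association/dissociation cycle (seconds)."""

    start_s: float
    association_s: float
    dissociation_s: float
    concentration_m: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValidationError("injection start must be >= 0")
        if not self.association_s > 0 or not self.dissociation_s > 0:
            raise ValidationError("association and dissociation durations must be > 0")
        if self.concentration_m < 0:
            raise ValidationError("concentration must be >= 0")


@dataclass(frozen=True)
class LangmuirParameters:
    """1:1 interaction model parameters."""

    k_on: float  # 1/(M s)
    k_off: float  # 1/s
    r_max: float  # degrees

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.r_max < 0:
            raise ValidationError("Langmuir parameters must be >= 0")


def write_sensorgram(s: Sensorgram, path: str | Path) -> None:
    """Write a sensorgram as delimited text; round-trips at full precision."""
    lines = []
    for key in ("flow_rate_ul_min", "temperature_c", "analyte", "concentration_um"):
        if key in s.metadata:
            lines.append(f"# {key} = {s.metadata[key]}")
    for key in sorted(s.metadata):
        if key not in DEFAULT_METADATA:
            lines.append(f"# {key} = {s.metadata[key]}")
    lines.append("\t".join(_COLUMNS))
    for t, r in zip(s.time, s.response):
        lines.append(f"{float(t)!r}\t{float(r)!r}\t{s.channel}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sensorgram(path: str | Path) -> Sensorgram:
    """Read a sensorgram written by :func:`write_sensorgram`.

    Raises :class:`SensorgramFormatError` for missing columns or
    non-monotone time, naming the offending row.
    """
    text = Path(path).read_text()
    metadata: dict = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                metadata[key.strip()] = _coerce(value.strip())
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise SensorgramFormatError(f"{path}: no data rows")
    df = pd.read_csv(
        io.StringIO("\n".join(body_lines)), sep="\t", float_precision="round_trip"
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SensorgramFormatError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = int(bad[0]) + 2  # +1 zero-based step, +1 header row
            raise SensorgramFormatError(
                f"{path}: time not strictly increasing at data row {row}"
            )
    channels = df["channel"].unique()
    if len(channels) != 1:
        raise SensorgramFormatError(
            f"{path}: expected a single channel per file, found {list(channels)}"
        )
    return Sensorgram(
        time=t,
        response=df["response_deg"].to_numpy(dtype=float),
        channel=str(channels[0]),
        metadata=metadata,
    )


def _coerce(value: str):
    try:
        return float(value)
    except ValueError:
        return value


def reference_subtract(active: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Pointwise active-minus-reference correction.

    The reference is linearly interpolated onto the active time grid when
    the grids differ; the active grid must lie within the reference range.
    Metadata and channel label are inherited from the active channel.
    """
    if (
        active.time[0] < reference.time[0] - 1e-12
        or active.time[-1] > reference.time[-1] + 1e-12
    ):
        raise ValidationError(
            "reference channel does not cover the active time range "
            f"([{active.time[0]}, {active.time[-1]}] vs "
            f"[{reference.time[0]}, {reference.time[-1]}])"
        )
    if active.time.shape == reference.time.shape and np.array_equal(
        active.time, reference.time
    ):
        ref_on_active = reference.response
    else:
        ref_on_active = np.interp(active.time, reference.time, reference.response)
    return replace(active, response=active.response - ref_on_active)


@dataclass(frozen=True)
class PlateauEstimate:
    """Steady-state response over a time window: mean, spread, sample count."""

    mean_deg: float
    sd_deg: float
    n_samples: int

    def __float__(self) -> float:
        return self.mean_deg


def steady_state_response(
    s: Sensorgram, window: tuple[float, float]
) -> PlateauEstimate:
    """Mean response over [t0, t1] with its within-window standard deviation.

    The window must lie inside the series and contain at least 3 samples.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValidationError(f"window must satisfy t0 < t1, got {window}")
    if t0 < s.time[0] or t1 > s.time[-1]:
        raise ValidationError(
            f"window {window} outside series range [{s.time[0]}, {s.time[-1]}]"
        )
    mask = (s.time >= t0) & (s.time <= t1)
    n = int(mask.sum())
    if n < 3:
        raise ValidationError(f"window {window} contains only {n} samples (need >= 3)")
    values = s.response[mask]
    return PlateauEstimate(
        mean_deg=float(values.mean()), sd_deg=float(values.std(ddof=1)), n_samples=n
    )


def langmuir_curve(
    t: np.ndarray,
    params: LangmuirParameters,
    schedule: InjectionSchedule,
) -> np.ndarray:
    """Noise-free Langmuir 1:1 response evaluated on arbitrary times."""
    t = np.asarray(t, dtype=float)
    c = schedule.concentration_m
    kobs = params.k_on * c + params.k_off
    if kobs > 0:
        r_eq = params.r_max * params.k_on * c / kobs
    else:
        r_eq = 0.0
    t_assoc = t - schedule.start_s
    assoc_end = schedule.start_s + schedule.association_s
    r_assoc = r_eq * -np.expm1(-kobs * np.clip(t_assoc, 0.0, None))
    r_end = r_eq * -np.expm1(-kobs * schedule.association_s)
    r_diss = r_end * np.exp(-params.k_off * np.clip(t - assoc_end, 0.0, None))
    return np.where(t < assoc_end, np.where(t_assoc < 0, 0.0, r_assoc), r_diss)


def simulate_sensorgram(
    params: LangmuirParameters,
    schedule: InjectionSchedule,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    *,
    sample_interval_s: float = 1.0,
    bulk_shift_deg: float = 0.0,
    drift_deg_per_s: float = 0.0,
    channel: str = "active",
    metadata: Optional[dict] = None,
) -> Sensorgram:
    """Simulate one channel of an association/dissociation cycle.

    Parameters
    ----------
    params, schedule
        Kinetic model and injection timing.  Set ``params.r_max`` to 0 for
        an uncoated reference channel (bulk shift and drift still apply).
    noise_sd : float
        Standard deviation of additive i.i.d. Gaussian noise, degrees.
    seed : int, optional
        Seed for the noise generator; fixed seed gives a bit-reproducible
        series.
    bulk_shift_deg : float
        Common-mode bulk refractive-index step present only while the
        analyte is flowing (association window).
    drift_deg_per_s : float
        Linear baseline drift applied to the whole series.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if not sample_interval_s > 0:
        raise ValidationError("sample_interval_s must be > 0")
    t_end = schedule.start_s + schedule.association_s + schedule.dissociation_s
    n = int(np.floor(t_end / sample_interval_s)) + 1
    t = sample_interval_s * np.arange(n)
    r = langmuir_curve(t, params, schedule)
    in_assoc = (t >= schedule.start_s) & (
        t < schedule.start_s + schedule.association_s
    )
    r = r + bulk_shift_deg * in_assoc + drift_deg_per_s * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    meta = dict(DEFAULT_METADATA)
    meta["concentration_um"] = schedule.concentration_m * 1e6
    if metadata:
        meta.update(metadata)
    return Sensorgram(time=t, response=r, channel=channel, metadata=meta)


@dataclass(frozen=True)
class LangmuirFit:
    """Result of fitting the 1:1 model to a single-cycle sensorgram."""

    params: LangmuirParameters
    residual_norm: float
    low_signal: bool


def fit_langmuir(
    s: Sensorgram,
    schedule: InjectionSchedule,
    *,
    low_signal_threshold_deg: float = 1e-3,
) -> LangmuirFit:
    """Least-squares estimation of (k_on, k_off, R_max) from one cycle.

    Fits the closed-form association/dissociation phases jointly.  A fit
    whose estimated R_max falls below ``low_signal_threshold_deg`` is
    flagged ``low_signal`` (the rate constants are then meaningless).

    Raises :class:`FitError` on non-convergence, carrying the best iterate.
    """
    c = schedule.concentration_m
    if not c > 0:
        raise ValidationError("schedule concentration must be > 0 for fitting")

    t = s.time
    r = s.response

    span = float(np.ptp(r))
    r_max0 = max(float(np.max(r)), low_signal_threshold_deg)
    k_off0 = 1e-3
    k_on0 = 1.0 / (c * max(schedule.association_s / 3.0, 1.0))

    def model(tt, log_kon, log_koff, r_max):
        p = LangmuirParameters(
            k_on=float(np.exp(log_kon)),
            k_off=float(np.exp(log_koff)),
            r_max=abs(r_max),
        )
        return langmuir_curve(tt, p, schedule)

    p0 = (np.log(k_on0), np.log(k_off0), r_max0)
    if span <= low_signal_threshold_deg:
        # flat series: report a zero-amplitude fit rather than failing
        est = LangmuirParameters(k_on=0.0, k_off=0.0, r_max=float(np.mean(np.abs(r))))
        resid = float(np.linalg.norm(r))
        return LangmuirFit(params=est, residual_norm=resid, low_signal=True)
    try:
        popt, _ = curve_fit(model, t, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        best = LangmuirParameters(
            k_on=float(np.exp(p0[0])), k_off=float(np.exp(p0[1])), r_max=p0[2]
        )
        raise FitError(
            "Langmuir fit did not converge", best=best, diagnostic=str(exc)
        ) from exc
    est = LangmuirParameters(
        k_on=float(np.exp(popt[0])),
        k_off=float(np.exp(popt[1])),
        r_max=abs(float(popt[2])),
    )
    resid = float(np.linalg.norm(r - model(t, *popt)))
    return LangmuirFit(
        params=est,
        residual_norm=resid,
        low_signal=est.r_max < low_signal_threshold_deg,
    )
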