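"""Photobleaching curves, ratiometric biosensor responses and brightness.

Two-channel (donor/acceptor) intensity time series arise in two assays:

* photostability runs, where a tandem construct is continuously excited at
  the donor wavelength and acceptor bleaching shows up as donor dequenching
  (a donor *rise* mirroring the acceptor decay); and
* biosensor experiments, where an agonist step changes the FRET efficiency
  and an antagonist reverses it, read out as the acceptor/donor ratio.

Traces are background-subtracted and normalized to the mean of the first
few frames; bleach curves are summarised as percent-of-initial at probe
times, biosensor traces as (baseline, amplitude, recovery) of the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "IntensityTrace",
    "BleachSummary",
    "RatioResponse",
    "background_subtract_and_normalize",
    "percent_remaining",
    "ratio_response",
    "relative_brightness",
    "cohort_mean_ci",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Timestamped two-channel intensity series with optional events (s)."""

    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    background_donor: float | np.ndarray = 0.0
    background_acceptor: float | np.ndarray = 0.0
    agonist_s: float | None = None
    antagonist_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.donor, dtype=float)
        a = np.asarray(self.acceptor, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor", a)
        if not (t.shape == d.shape == a.shape):
            raise ValueError("time, donor and acceptor must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class BleachSummary:
    """Percent of initial intensity per channel at requested probe times."""

    percent_remaining_at: dict[float, dict[str, float]]


@dataclass(frozen=True)
class RatioResponse:
    ratio: np.ndarray
    baseline: float
    amplitude_pct: float
    recovery_pct: float
    responder: bool


def background_subtract_and_normalize(
    trace: IntensityTrace, n_baseline_frames: int = 1
) -> IntensityTrace:
    """Subtract backgrounds and scale each channel so the mean of the first
    ``n_baseline_frames`` frames is 1.  Idempotent on background-free traces."""
    if not 1 <= n_baseline_frames <= trace.time_s.size:
        raise ValueError("n_baseline_frames out of range")
    out = {}
    for name, channel, bg in (
        ("donor", trace.donor, trace.background_donor),
        ("acceptor", trace.acceptor, trace.background_acceptor),
    ):
        corrected = channel - np.asarray(bg, dtype=float)
        base = float(corrected[:n_baseline_frames].mean())
        if base <= 0:
            raise ValueError(f"{name}: non-positive baseline after background subtraction")
        out[name] = corrected / base
    return replace(
        trace,
        donor=out["donor"],
        acceptor=out["acceptor"],
        background_donor=0.0,
        background_acceptor=0.0,
    )


def percent_remaining(trace: IntensityTrace, channel: str, t_probe_s: float) -> float:
    """Percent of initial intensity at the nearest frame at or before t_probe.

    Assumes a normalized trace (initial value 1 == 100%).  Donor channels of
    bleaching tandems can exceed 100% — dequenching as the acceptor dies.
    """
    if channel not in ("donor", "acceptor"):
        raise ValueError("channel must be 'donor' or 'acceptor'")
    t = trace.time_s
    if t_probe_s < t[0]:
        raise ValueError("probe time precedes the first frame")
    idx = int(np.searchsorted(t, t_probe_s, side="right") - 1)
    return float(getattr(trace, channel)[idx] * 100.0)


def bleach_summary(trace: IntensityTrace, probe_times_s: list[float]) -> BleachSummary:
    return BleachSummary(
        {
            t: {ch: percent_remaining(trace, ch, t) for ch in ("donor", "acceptor")}
            for t in probe_times_s
        }
    )


def ratio_response(
    trace: IntensityTrace,
    responder_threshold_pct: float = 5.0,
    numerator: str = "acceptor",
    plateau_frames: int = 5,
) -> RatioResponse:
    """Summarise an agonist/antagonist experiment from the FRET ratio.

    Baseline is the mean ratio before the agonist; amplitude the maximal
    relative deviation between agonist and antagonist (percent of baseline);
    recovery the fraction of that amplitude reversed at the post-antagonist
    plateau (mean of the final ``plateau_frames`` frames).
    """
    if trace.agonist_s is None or trace.antagonist_s is None:
        raise ValueError("agonist and antagonist event times are required")
    t = trace.time_s
    if not t[0] <= trace.agonist_s < trace.antagonist_s <= t[-1]:
        raise ValueError("events must be ordered and inside the trace span")
    if numerator == "acceptor":
        ratio = trace.acceptor / trace.donor
    elif numerator == "donor":
        ratio = trace.donor / trace.acceptor
    else:
        raise ValueError("numerator must be 'acceptor' or 'donor'")
    pre = ratio[t < trace.agonist_s]
    if pre.size == 0:
        raise ValueError("no frames before the agonist event")
    baseline = float(pre.mean())
    if baseline <= 0:
        raise ValueError("non-positive baseline ratio")
    window = (t >= trace.agonist_s) & (t <= trace.antagonist_s)
    deviation = np.abs(ratio[window] - baseline) / baseline
    amplitude_pct = float(deviation.max() * 100.0) if window.any() else 0.0
    post = ratio[t > trace.antagonist_s]
    if post.size:
        plateau = float(post[-min(plateau_frames, post.size):].mean())
        residual_pct = abs(plateau - baseline) / baseline * 100.0
        recovery_pct = (
            (1.0 - residual_pct / amplitude_pct) * 100.0 if amplitude_pct > 0 else 0.0
        )
    else:
        recovery_pct = 0.0
    return RatioResponse(
        ratio=ratio,
        baseline=baseline,
        amplitude_pct=amplitude_pct,
        recovery_pct=recovery_pct,
        responder=amplitude_pct >= responder_threshold_pct,
    )


def relative_brightness(sample_intensity: float, reference_intensity: float) -> float:
    """Brightness of a protein relative to a co-expressed reference.

    Both intensities are background-subtracted cell means; co-expression
    from a T2A construct guarantees equal copy numbers, so the ratio is the
    per-molecule brightness ratio.
    """
    if reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    if sample_intensity < 0:
        raise ValueError("sample intensity must be non-negative")
    return sample_intensity / reference_intensity


def cohort_mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and normal-approximation confidence interval across cells."""
    from scipy import stats

    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if v.size < 2:
        return mean, mean, mean
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return mean, mean - z * sem, mean + z * sem
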