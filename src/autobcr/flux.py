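"""Autonomous BCR signaling strength from ratiometric calcium-flux data.

The statistic scores a single gated sample in four steps:

1. ``baseline_threshold`` — the 95th percentile (configurable quantile,
   linear interpolation between order statistics) of the per-event 405/485
   signal intensity ratio (SIR) during the baseline window, before 4-OHT.
2. ``unresponsive_fraction`` — the crosslink window is tiled with
   consecutive 20-s bins; the bin with the highest median SIR is the peak of
   the maximal response, and the fraction ``u`` of its events at or below the
   baseline threshold estimates the totally unresponsive cells.
3. ``q_aut`` — the fraction of autonomous-window events above the threshold,
   corrected for unresponsive cells by dividing by ``1 - u`` (capped at 1).
4. ``cal_sir_aut`` — the median SIR of those above-threshold autonomous
   events, calibrated to (divided by) the median SIR in the peak crosslink
   bin.

Signaling strength is the arithmetic product ``q_aut * cal_sir_aut``; a BCR
is called signaling when its replicate-averaged strength exceeds the upper
limit observed among known non-signaling controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import FluxProtocol, FluxSeries

__all__ = [
    "SignalingResult",
    "baseline_threshold",
    "unresponsive_fraction",
    "q_aut",
    "cal_sir_aut",
    "signaling_strength",
    "average_replicates",
    "classify_signaling",
]

MIN_BASELINE_EVENTS = 20


@dataclass
class SignalingResult:
    """All intermediates and the final strength for one measurement."""

    baseline_threshold: float
    q_aut: float
    cal_sir_aut: float
    strength: float
    unresponsive_fraction: float
    peak_bin: tuple[float, float]
    n_events: dict[str, int]
    sample_id: str = ""
    replicate_index: int = 0
    classification: str | None = None


def _phase_sir(series: FluxSeries, lo: float, hi: float) -> np.ndarray:
    t = series.time_s
    mask = (t >= lo) & (t < hi)
    return series.sir[mask]


def baseline_threshold(series: FluxSeries, protocol: FluxProtocol) -> float:
    """Responder threshold: the baseline-window SIR quantile (default 0.95).

    Uses linear interpolation between order statistics so the value is
    reproducible across implementations.
    """
    sir = _phase_sir(series, 0.0, protocol.t_4oht_s)
    if len(sir) < MIN_BASELINE_EVENTS:
        raise ValueError(
            f"only {len(sir)} baseline events (< {MIN_BASELINE_EVENTS}); sample unusable"
        )
    return float(np.quantile(sir, protocol.baseline_quantile))


def unresponsive_fraction(
    series: FluxSeries, protocol: FluxProtocol, threshold: float
) -> tuple[float, tuple[float, float]]:
    """Fraction of events in the peak crosslink bin at or below threshold.

    The peak bin is the full ``bin_width_s`` bin within the crosslink window
    whose median SIR is maximal (ties broken toward the earlier bin).
    Returns ``(u, (bin_start_s, bin_end_s))``.
    """
    bins = protocol.crosslink_bins
    if not bins:
        raise ValueError(
            f"crosslink window shorter than one {protocol.bin_width_s}-s bin; cannot "
            "locate the maximum response"
        )
    best: tuple[float, float] | None = None
    best_median = -np.inf
    for lo, hi in bins:
        sir = _phase_sir(series, lo, hi)
        if len(sir) == 0:
            continue
        med = float(np.median(sir))
        if med > best_median:
            best_median = med
            best = (lo, hi)
    if best is None:
        raise ValueError("no events in any full crosslink bin")
    sir = _phase_sir(series, *best)
    u = float(np.mean(sir <= threshold))
    return u, best


def q_aut(
    series: FluxSeries, protocol: FluxProtocol, threshold: float, u: float
) -> float:
    """Responder fraction in the autonomous window, corrected for totally
    unresponsive cells: ``min(raw / (1 - u), 1)``."""
    if u >= 1:
        raise ValueError(
            "unresponsive fraction u >= 1: every crosslink-peak event is below "
            "threshold, correction impossible"
        )
    sir = _phase_sir(series, protocol.t_4oht_s, protocol.autonomous_end_s)
    if len(sir) == 0:
        raise ValueError("no events in the autonomous window")
    raw = float(np.mean(sir > threshold))
    return min(raw / (1.0 - u), 1.0)


def cal_sir_aut(series: FluxSeries, protocol: FluxProtocol, threshold: float) -> float:
    """Median SIR of above-threshold autonomous events, calibrated to the
    median SIR of the peak crosslink bin.

    By convention a sample with no above-threshold autonomous event returns
    0 (it shows no autonomous signal to calibrate).
    """
    aut = _phase_sir(series, protocol.t_4oht_s, protocol.autonomous_end_s)
    responders = aut[aut > threshold]
    if len(responders) == 0:
        return 0.0
    _, peak = unresponsive_fraction(series, protocol, threshold)
    peak_sir = _phase_sir(series, *peak)
    return float(np.median(responders) / np.median(peak_sir))


def signaling_strength(series: FluxSeries, protocol: FluxProtocol | None = None) -> SignalingResult:
    """Full per-sample statistic: strength = Q_aut x calSIR_aut.

    The series is expected to be gated to BCR-expressing (GFP+) live cells
    already.  Sub-stage errors propagate annotated with the stage name.
    """
    protocol = protocol or FluxProtocol()

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except ValueError as e:
            raise ValueError(f"[{name}] {e}") from e

    thr = _stage("baseline_threshold", baseline_threshold, series, protocol)
    u, peak = _stage("unresponsive_fraction", unresponsive_fraction, series, protocol, thr)
    q = _stage("q_aut", q_aut, series, protocol, thr, u)
    cal = _stage("cal_sir_aut", cal_sir_aut, series, protocol, thr)
    t = series.time_s
    n_events = {
        "baseline": int(np.sum(t < protocol.t_4oht_s)),
        "autonomous": int(
            np.sum((t >= protocol.t_4oht_s) & (t < protocol.autonomous_end_s))
        ),
        "crosslink": int(
            np.sum((t >= protocol.autonomous_end_s) & (t < protocol.crosslink_end_s))
        ),
    }
    return SignalingResult(
        baseline_threshold=thr,
        q_aut=q,
        cal_sir_aut=cal,
        strength=q * cal,
        unresponsive_fraction=u,
        peak_bin=peak,
        n_events=n_events,
        sample_id=series.sample_id,
        replicate_index=series.replicate_index,
    )


def average_replicates(results: Sequence[SignalingResult | float]) -> float:
    """Arithmetic mean strength over replicate measurements (the per-BCR
    summary plotted as one symbol per sample)."""
    if not results:
        raise ValueError("cannot average an empty list of replicates")
    vals = [r.strength if isinstance(r, SignalingResult) else float(r) for r in results]
    return float(np.mean(vals))


def classify_signaling(mean_strength: float, null_strengths: Sequence[float]) -> str:
    """Call a BCR signaling when its mean strength exceeds the upper limit
    (maximum) of the non-signaling control strengths; ties are called
    non_signaling (conservative)."""
    if len(null_strengths) == 0:
        raise ValueError("need at least one non-signaling control strength")
    threshold = max(float(v) for v in null_strengths)
    return "signaling" if mean_strength > threshold else "non_signaling"
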