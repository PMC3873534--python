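"""Threshold event detection on raw traces and cross-channel duplicate removal.

Detection mirrors the acquisition convention of the intra-operative
recordings: candidate action potentials are voltage excursions outside
±2.8 SDs of the entire trace, captured as 1.1 ms snippets at 29412 Hz.
A contiguous suprathreshold excursion yields one event anchored at its
extremum, so a single action potential is never double-counted.

Duplicate removal targets the same physical spike appearing on two
microwires: scanning all spikes of an epoch in global time order, any spike
following a retained spike on a *different* channel by less than 100 us is
deleted (the boundary corresponds to three sample intervals at 29412 Hz).
Same-channel intervals are untouched — the rule exists to remove
cross-channel copies, not genuine short ISIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain
from .synth import VoltageTrace

__all__ = ["DetectionParams", "DetectedEvents", "detect_events", "remove_duplicate_spikes"]

DUPLICATE_THRESHOLD_US = 100.0


@dataclass(frozen=True)
class DetectionParams:
    threshold_sd: float = 2.8
    window_ms: float = 1.1
    sampling_hz: float = 29412.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be > 0")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")


@dataclass
class DetectedEvents:
    """Event times (s), trigger sample indices and waveform snippets."""

    times_s: np.ndarray
    indices: np.ndarray
    snippets: np.ndarray  # (n_events, window_samples)
    threshold: float      # absolute threshold in trace units


def detect_events(trace: VoltageTrace, params: DetectionParams = DetectionParams()) -> DetectedEvents:
    """Detect threshold-crossing events and capture waveform snippets.

    The threshold is ``threshold_sd`` times the SD of the *entire* trace.
    Each maximal run of consecutive suprathreshold samples produces a single
    event anchored at the sample of largest absolute voltage; the snippet of
    ``window_ms`` is centered on that anchor (edge events are zero-padded).
    """
    v = np.asarray(trace.samples, float)
    win = max(int(round(params.window_ms / 1000.0 * trace.sampling_hz)), 1)
    if v.size < win:
        raise ValueError("trace shorter than the capture window")
    sd = float(v.std())
    if sd == 0.0:
        raise ValueError("zero-variance trace: threshold undefined")
    thr = params.threshold_sd * sd
    above = np.abs(v) > thr
    if not above.any():
        empty = np.empty((0, win))
        return DetectedEvents(np.empty(0), np.empty(0, int), empty, thr)
    # maximal runs of suprathreshold samples
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [v.size]))
    anchors = np.array(
        [s + int(np.argmax(np.abs(v[s:e]))) for s, e in zip(starts, ends)], dtype=int
    )
    half = win // 2
    snippets = np.zeros((anchors.size, win))
    for k, a in enumerate(anchors):
        lo, hi = a - half, a - half + win
        s0, s1 = max(lo, 0), min(hi, v.size)
        snippets[k, s0 - lo : s1 - lo] = v[s0:s1]
    times = anchors / trace.sampling_hz
    return DetectedEvents(times, anchors, snippets, thr)


def remove_duplicate_spikes(
    trains: list[SpikeTrain], threshold_us: float = DUPLICATE_THRESHOLD_US
) -> list[SpikeTrain]:
    """Delete cross-channel near-coincident spikes from one epoch's trains.

    All spikes are merged and scanned once in global time order (ties broken
    toward the lower-numbered channel).  A spike is deleted when any *retained*
    spike on a different channel precedes it by less than ``threshold_us``.
    The scan is idempotent and leaves same-channel spike pairs alone.
    """
    thr_s = threshold_us * 1e-6
    times = []
    chans = []
    origin = []  # (train index, spike index)
    for k, tr in enumerate(trains):
        times.append(tr.spike_times)
        chans.append(np.full(tr.n_spikes, tr.channel_id))
        origin.append(np.stack([np.full(tr.n_spikes, k), np.arange(tr.n_spikes)], axis=1))
    if not times:
        return []
    t = np.concatenate(times)
    c = np.concatenate(chans)
    o = np.concatenate(origin) if t.size else np.empty((0, 2), int)
    order = np.lexsort((c, t))  # time first, lower channel wins ties
    t, c, o = t[order], c[order], o[order]

    keep = np.ones(t.size, dtype=bool)
    retained: list[int] = []  # indices of retained spikes, trailing window only
    for i in range(t.size):
        # drop retained entries that fell out of the 100 us window
        while retained and t[i] - t[retained[0]] >= thr_s:
            retained.pop(0)
        if any(c[j] != c[i] for j in retained):
            keep[i] = False
        else:
            retained.append(i)

    deleted_by_train: dict[int, set[int]] = {}
    for k_idx in np.flatnonzero(~keep):
        tr_i, sp_i = int(o[k_idx, 0]), int(o[k_idx, 1])
        deleted_by_train.setdefault(tr_i, set()).add(sp_i)
    out = []
    for k, tr in enumerate(trains):
        dele = deleted_by_train.get(k)
        if not dele:
            out.append(tr)
        else:
            mask = np.ones(tr.n_spikes, bool)
            mask[list(dele)] = False
            out.append(tr.replace_times(tr.spike_times[mask]))
    return out
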