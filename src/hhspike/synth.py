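"""Synthetic spike-train sessions with the population structure the analysis assumes.

No raw clinical data accompanies the intra-operative microwire study this
package re-implements, so every downstream stage is exercised on simulated
sessions with known ground truth.  The generator emulates, at its defaults:

* two firing-rate classes (log-normal scatter around medians 0.6 and
  15.0 sp/s, class boundary 2 sp/s),
* three burst-index classes (medians 0.015, 0.18 and 0.39 of ``B_isi``, the
  ratio of interspike intervals under 10 ms to those of at least 10 ms),
* a positive rate-burst correlation (target Pearson rho ~ 0.66), induced by
  coupling each unit's rate-class and burst-class draws through a shared
  latent Gaussian,
* a controllable fraction of synchronously firing unit pairs, concentrated
  among fast-firing units, realized by thinned and jittered copies of a
  per-epoch master train,
* rare evolving discharges (~3.6% of units): transient ramps of the firing
  rate above baseline,
* sessions of 2-3 epochs of 300 s per patient with up to 8 channels
  (the default cohort layout is 14 patients / 37 epochs / 222 units), and
* raw voltage traces sampled at 29412 Hz for the detection stage.

Bursty trains are a two-state renewal process: burst onsets form a Poisson
process, each burst carries a geometric number of spikes with gamma
intra-burst intervals (mean < 10 ms), superimposed on a Poisson background.
Burst parameters for a target ``B_isi`` are solved analytically
(:func:`bursty_params_for`).

All generators are reproducible: one master seed, with per-epoch and
per-unit streams derived by counter so any unit's train is independent of
generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import Epoch, Session, SpikeTrain

__all__ = [
    "PopulationConfig",
    "SyncPairParams",
    "VoltageTrace",
    "PopulationResult",
    "DEFAULT_COHORT_LAYOUT",
    "generate_poisson_train",
    "generate_bursty_train",
    "bursty_params_for",
    "generate_synchronous_pair",
    "inject_discharge",
    "generate_population",
    "render_trace",
    "default_spike_template",
]

# Units per epoch for each patient of the reference intra-operative cohort
# (14 patients, 37 five-minute epochs, 222 sorted units in total).
DEFAULT_COHORT_LAYOUT: tuple[tuple[int, ...], ...] = (
    (1, 5),
    (4, 1),
    (3, 13),
    (7, 14, 12),
    (5, 9, 8),
    (3, 3),
    (3, 1),
    (7, 4, 10),
    (3, 6, 2),
    (12, 12, 8),
    (1, 3, 1),
    (1, 7, 8),
    (9, 8, 7),
    (6, 13, 2),
)

_ISI_THRESHOLD_S = 0.010  # boundary between "burst" and "regular" intervals


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------


def generate_poisson_train(
    rate: float,
    duration_s: float,
    seed,
    unit_id: str = "u0",
    channel_id: int = 1,
    epoch_id: str = "e0",
) -> SpikeTrain:
    """Homogeneous Poisson spike train; expected count is ``rate * duration_s``."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = _rng(seed)
    n = rng.poisson(rate * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    return SpikeTrain(unit_id, channel_id, times, epoch_id)


def generate_bursty_train(
    baseline_rate: float,
    burst_rate: float,
    mean_spikes_per_burst: float,
    intra_burst_isi_ms: float,
    duration_s: float,
    seed,
    unit_id: str = "u0",
    channel_id: int = 1,
    epoch_id: str = "e0",
) -> SpikeTrain:
    """Two-state renewal train: Poisson burst onsets on a Poisson background.

    Each burst carries ``N ~ Geometric(1/mean_spikes_per_burst)`` spikes
    (support >= 1) separated by gamma intervals (shape 2) with mean
    ``intra_burst_isi_ms``.  With ``mean_spikes_per_burst=1`` the process
    degenerates to a Poisson train at ``baseline_rate + burst_rate``.
    """
    if baseline_rate < 0 or burst_rate < 0:
        raise ValueError("rates must be >= 0")
    if mean_spikes_per_burst < 1:
        raise ValueError("mean_spikes_per_burst must be >= 1")
    if not (0 < intra_burst_isi_ms < 10):
        raise ValueError("intra_burst_isi_ms must lie in (0, 10) ms")
    rng = _rng(seed)
    base = generate_poisson_train(baseline_rate, duration_s, rng).spike_times
    n_bursts = rng.poisson(burst_rate * duration_s)
    onsets = rng.uniform(0.0, duration_s, size=n_bursts)
    pieces = [base]
    mean_s = intra_burst_isi_ms / 1000.0
    for onset in onsets:
        if mean_spikes_per_burst == 1:
            n_spk = 1
        else:
            # geometric burst sizes, truncated at 12 spikes: physiological
            # bursts are short, and untruncated tails mimic discharges
            n_spk = min(int(rng.geometric(1.0 / mean_spikes_per_burst)), 12)
        if n_spk == 1:
            pieces.append(np.array([onset]))
            continue
        isis = rng.gamma(shape=2.0, scale=mean_s / 2.0, size=n_spk - 1)
        pieces.append(onset + np.concatenate(([0.0], np.cumsum(isis))))
    times = np.concatenate(pieces)
    times = np.sort(times[(times >= 0) & (times < duration_s)])
    return SpikeTrain(unit_id, channel_id, times, epoch_id)


def bursty_params_for(
    rate: float,
    target_bisi: float,
    intra_burst_isi_ms: float = 4.0,
    mean_spikes_per_burst: float = 4.0,
) -> dict:
    """Two-state renewal parameters whose expected ``B_isi`` matches a target.

    Solves for the burst-onset rate by bisection on a closed-form model of the
    expected fraction of sub-10 ms intervals: intra-burst gamma intervals plus
    the short tail of the exponential gaps between events.  If the intrinsic
    (pure Poisson) short-interval fraction at ``rate`` already exceeds the
    target, the train is left Poisson (``burst_rate = 0``) — a fast Poisson
    train is already mildly "bursty" by the interval criterion.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if target_bisi < 0:
        raise ValueError("target_bisi must be >= 0")
    mu = mean_spikes_per_burst
    mean_s = intra_burst_isi_ms / 1000.0
    p_gamma = float(stats.gamma.cdf(_ISI_THRESHOLD_S, a=2.0, scale=mean_s / 2.0))
    p_target = target_bisi / (1.0 + target_bisi)

    def short_fraction(r_burst: float) -> float:
        b = rate - r_burst * mu
        n_intra = r_burst * (mu - 1.0)  # intra-burst intervals per second
        n_gap = max(rate - n_intra, 1e-12)
        lam_gap = b + r_burst  # event rate seen by the gap intervals
        p_gap = 1.0 - math.exp(-lam_gap * _ISI_THRESHOLD_S)
        return (n_intra * p_gamma + n_gap * p_gap) / rate

    r_max = rate / mu
    if short_fraction(0.0) >= p_target or target_bisi == 0:
        r_burst = 0.0
    elif short_fraction(r_max) <= p_target:
        r_burst = r_max
    else:
        lo, hi = 0.0, r_max
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if short_fraction(mid) < p_target:
                lo = mid
            else:
                hi = mid
        r_burst = 0.5 * (lo + hi)
    return {
        "baseline_rate": rate - r_burst * mu,
        "burst_rate": r_burst,
        "mean_spikes_per_burst": mu,
        "intra_burst_isi_ms": intra_burst_isi_ms,
    }


@dataclass(frozen=True)
class SyncPairParams:
    """Mechanism for a synchronously firing pair: both units carry thinned,
    jittered copies of a shared master train plus independent background."""

    master_rate: float
    copy_prob_a: float
    copy_prob_b: float
    jitter_sd_ms: float = 1.0
    independent_rate_a: float = 0.0
    independent_rate_b: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.copy_prob_a <= 1 and 0 <= self.copy_prob_b <= 1):
            raise ValueError("copy probabilities must lie in [0, 1]")
        if min(self.master_rate, self.independent_rate_a, self.independent_rate_b) < 0:
            raise ValueError("rates must be >= 0")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")


def _copy_master(
    master: np.ndarray,
    copy_prob: float,
    jitter_sd_s: float,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    kept = master[rng.random(master.size) < copy_prob]
    if jitter_sd_s > 0 and kept.size:
        kept = kept + rng.normal(0.0, jitter_sd_s, size=kept.size)
    return kept[(kept >= 0) & (kept < duration_s)]


def generate_synchronous_pair(
    params: SyncPairParams,
    duration_s: float,
    seed,
    epoch_id: str = "e0",
) -> tuple[SpikeTrain, SpikeTrain]:
    """Pair of trains with an excess of (near-)zero-lag coincidences.

    The expected coincidence surplus is ``copy_prob_a * copy_prob_b *
    master_rate`` per second, spread around zero delay by the jitter.
    """
    rng = _rng(seed)
    master = generate_poisson_train(params.master_rate, duration_s, rng).spike_times
    jit = params.jitter_sd_ms / 1000.0
    a = _copy_master(master, params.copy_prob_a, jit, duration_s, rng)
    b = _copy_master(master, params.copy_prob_b, jit, duration_s, rng)
    bg_a = generate_poisson_train(params.independent_rate_a, duration_s, rng).spike_times
    bg_b = generate_poisson_train(params.independent_rate_b, duration_s, rng).spike_times
    ta = np.sort(np.concatenate([a, bg_a]))
    tb = np.sort(np.concatenate([b, bg_b]))
    return (
        SpikeTrain("a", 1, ta, epoch_id),
        SpikeTrain("b", 2, tb, epoch_id),
    )


def inject_discharge(
    train: SpikeTrain,
    onset_s: float,
    duration_s: float,
    peak_rate: float,
    seed,
    epoch_duration_s: Optional[float] = None,
    baseline_rate: Optional[float] = None,
) -> SpikeTrain:
    """Superimpose an evolving discharge: an inhomogeneous Poisson ramp of the
    firing rate from baseline up to ``peak_rate`` and back over the window.

    The extra rate profile is triangular, peaking at the window midpoint.  A
    zero-length window, or a peak at or below baseline, returns the train
    unchanged.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    if epoch_duration_s is not None and onset_s + duration_s > epoch_duration_s + 1e-9:
        raise ValueError("discharge window extends beyond the epoch")
    if duration_s == 0:
        return train
    total = epoch_duration_s
    if total is None:
        total = max(train.spike_times[-1] if train.n_spikes else 0.0, onset_s + duration_s)
    if baseline_rate is None:
        baseline_rate = train.n_spikes / total if total > 0 else 0.0
    extra_peak = peak_rate - baseline_rate
    if extra_peak <= 0:
        return train
    rng = _rng(seed)
    n_extra = rng.poisson(0.5 * extra_peak * duration_s)  # triangle area
    u = rng.random(n_extra)
    frac = np.where(u <= 0.5, np.sqrt(u / 2.0), 1.0 - np.sqrt((1.0 - u) / 2.0))
    times = np.sort(np.concatenate([train.spike_times, onset_s + duration_s * frac]))
    return train.replace_times(times)


# ---------------------------------------------------------------------------
# raw voltage traces
# ---------------------------------------------------------------------------


@dataclass
class VoltageTrace:
    """Single-channel extracellular voltage trace in arbitrary units."""

    samples: np.ndarray
    sampling_hz: float = 29412.0

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_hz


def default_spike_template(sampling_hz: float = 29412.0, width_ms: float = 1.1) -> np.ndarray:
    """Biphasic action-potential template of unit negative peak amplitude."""
    n = max(int(round(width_ms / 1000.0 * sampling_hz)), 5)
    i = np.arange(n)
    # sharp negative trough (~0.1 ms) followed by a slow positive rebound
    trough = -np.exp(-0.5 * ((i - n // 4) / 1.5) ** 2)
    rebound = 0.2 * np.exp(-0.5 * ((i - n // 2) / (n / 8.0)) ** 2)
    wave = trough + rebound
    return wave / np.abs(wave).max()


def render_trace(
    trains: list[SpikeTrain],
    duration_s: float,
    noise_sd: float,
    seed,
    waveform_template: Optional[np.ndarray] = None,
    amplitude: float = 10.0,
    sampling_hz: float = 29412.0,
) -> VoltageTrace:
    """Gaussian noise plus a spike template at each spike time of ``trains``.

    ``amplitude`` scales the template's unit peak (in the same arbitrary units
    as ``noise_sd``).  The template is anchored so its extremum falls at the
    spike sample.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be > 0")
    rng = _rng(seed)
    n = int(round(duration_s * sampling_hz))
    trace = rng.normal(0.0, noise_sd, size=n)
    if waveform_template is None:
        waveform_template = default_spike_template(sampling_hz)
    tpl = amplitude * np.asarray(waveform_template, float)
    peak_off = int(np.argmax(np.abs(tpl)))
    for tr in trains:
        if tr.n_spikes and tr.spike_times[-1] > duration_s:
            raise ValueError("spike beyond trace duration")
        idx = np.round(tr.spike_times * sampling_hz).astype(int)
        for i in idx:
            lo = i - peak_off
            hi = lo + tpl.size
            s0, s1 = max(lo, 0), min(hi, n)
            if s0 < s1:
                trace[s0:s1] += tpl[s0 - lo : s1 - lo]
    return VoltageTrace(trace, sampling_hz)


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------


@dataclass
class PopulationConfig:
    """Targets and shape of a synthetic recording session.

    Defaults reproduce the reference cohort: 14 patients contributing 37
    five-minute epochs with 222 units in total, two rate classes with medians
    0.6 / 15.0 sp/s, three burst classes with ``B_isi`` medians 0.015 / 0.18 /
    0.39, rate-burst Pearson correlation ~ 0.66, about half of unit pairs
    synchronous (enriched among fast-firing units) and 3.6% of units carrying
    an evolving discharge.
    """

    n_patients: int = 14
    epochs_per_patient: int = 3
    epoch_duration_s: float = 300.0
    units_per_epoch_mean: float = 6.0
    cohort_layout: Optional[tuple[tuple[int, ...], ...]] = DEFAULT_COHORT_LAYOUT
    rate_class_mix: tuple[float, float] = (0.4, 0.6)  # slow, fast
    slow_rate_median: float = 0.6
    fast_rate_median: float = 15.0
    #: slow rates scatter log-normally (skewed toward zero); fast rates are
    #: truncated-Gaussian so each class is one raw-scale mixture component
    slow_rate_sigma_log: float = 0.5
    fast_rate_sd: float = 5.0
    burst_class_medians: tuple[float, float, float] = (0.015, 0.18, 0.39)
    burst_class_mix: tuple[float, float, float] = (0.35, 0.35, 0.30)
    burst_class_sds: tuple[float, float, float] = (0.008, 0.045, 0.08)
    target_rate_burst_rho: float = 0.66
    latent_rho: float = 0.9
    sync_pair_fraction: float = 0.51
    sync_fast_bias: float = 1.8
    sync_master_rate: float = 4.0
    sync_copy_prob: float = 0.35
    sync_copy_scale: float = 0.35
    sync_jitter_ms: float = 1.0
    #: relative spread of per-patient network participation (lesions differ
    #: in how synchronous their networks are); 0 disables
    sync_patient_spread: float = 0.5
    discharge_unit_fraction: float = 0.036
    discharge_duration_s: float = 10.0
    discharge_extra_rate: float = 25.0
    anesthesia_effects: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (*self.rate_class_mix, *self.burst_class_mix,
                  self.sync_pair_fraction, self.discharge_unit_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")
        if abs(sum(self.rate_class_mix) - 1) > 1e-9 or abs(sum(self.burst_class_mix) - 1) > 1e-9:
            raise ValueError("class mixes must sum to 1")
        if min(self.slow_rate_median, self.fast_rate_median, *self.burst_class_medians) <= 0:
            raise ValueError("medians must be > 0")
        if self.epoch_duration_s <= 0:
            raise ValueError("epoch_duration_s must be > 0")
        if self.epochs_per_patient not in (2, 3):
            raise ValueError("epochs_per_patient must be 2 or 3")
        if self.cohort_layout is not None:
            self.cohort_layout = tuple(tuple(int(n) for n in row) for row in self.cohort_layout)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["cohort_layout"] is not None:
            d["cohort_layout"] = [list(r) for r in d["cohort_layout"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        if d.get("cohort_layout") is not None:
            d["cohort_layout"] = tuple(tuple(r) for r in d["cohort_layout"])
        for key in ("rate_class_mix", "burst_class_medians", "burst_class_mix"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PopulationResult:
    """A generated session plus its ground truth."""

    session: Session
    units: pd.DataFrame   # one row per unit: true classes, targets, flags
    pairs: pd.DataFrame   # one row per within-epoch unit pair: coupling flag
    config: PopulationConfig


def _join_probs(cfg: PopulationConfig) -> tuple[float, float]:
    """Per-class probabilities of joining the epoch's synchronous network.

    Solved so the expected fraction of *detected* synchronous pairs
    approximates ``sync_pair_fraction`` while fast units join
    ``sync_fast_bias`` times more often than slow units.  Weakly coupled
    slow units rarely reach significance, so the mean join probability is
    inflated by an average-detectability factor (~0.8).
    """
    a_mean = min(1.0, math.sqrt(cfg.sync_pair_fraction) / 0.8)
    w_slow, w_fast = cfg.rate_class_mix
    a_slow = a_mean / (w_slow + w_fast * cfg.sync_fast_bias)
    a_fast = min(1.0, a_slow * cfg.sync_fast_bias)
    return min(1.0, a_slow), a_fast


def _epoch_layout(cfg: PopulationConfig, rng: np.random.Generator) -> list[list[int]]:
    if cfg.cohort_layout is not None:
        return [list(row) for row in cfg.cohort_layout]
    layout = []
    for _ in range(cfg.n_patients):
        counts = 1 + rng.poisson(max(cfg.units_per_epoch_mean - 1, 0), size=cfg.epochs_per_patient)
        layout.append(counts.tolist())
    return layout


def _draw_covariates(rng: np.random.Generator, patient_flags: dict) -> dict:
    return {
        "sevoflurane_pct": round(float(rng.uniform(0.5, 3.0)), 2),
        "midazolam_at_induction": patient_flags["midazolam"],
        "propofol_at_induction": patient_flags["propofol"],
        "fentanyl_use": patient_flags["fentanyl"],
        "temperature_c": round(float(rng.normal(36.5, 0.6)), 2),
        "gas_carrier": patient_flags["gas"],
        "decadron_use": patient_flags["decadron"],
        "minutes_since_last_change": round(float(rng.uniform(0.0, 30.0)), 1),
    }


def generate_population(config: PopulationConfig) -> PopulationResult:
    """Generate a full session with ground-truth labels.

    Per-unit random streams are derived from the master seed by counter
    (patient, epoch, unit index), so each unit's train does not depend on the
    order in which other units are generated.
    """
    from .model import AnesthesiaRecord  # local import to avoid cycle confusion

    cfg = config
    top = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    layout = _epoch_layout(cfg, top)
    a_slow, a_fast = _join_probs(cfg)
    p_slow = cfg.rate_class_mix[0]
    burst_cuts = np.cumsum(cfg.burst_class_mix)[:2]
    burst_names = np.array(["low", "mid", "high"])
    T = cfg.epoch_duration_s

    unit_rows: list[dict] = []
    pair_rows: list[dict] = []
    patients: dict[str, list[Epoch]] = {}
    unit_counter = 0

    for p_idx, epochs in enumerate(layout):
        pid = f"P{p_idx + 1:02d}"
        prng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, p_idx))
        )
        patient_flags = {
            "midazolam": bool(prng.random() < 0.5),
            "propofol": bool(prng.random() < 0.5),
            "fentanyl": str(prng.choice(["induction", "intervals", "none"])),
            "gas": str(prng.choice(["air", "NO", "neither"])),
            "decadron": bool(prng.random() < 0.3),
        }
        sync_mult = 1.0 + cfg.sync_patient_spread * (2.0 * prng.random() - 1.0)
        pa_slow = min(max(a_slow * sync_mult, 0.0), 1.0)
        pa_fast = min(max(a_fast * sync_mult, 0.0), 1.0)
        patients[pid] = []
        for e_idx, n_units in enumerate(epochs):
            eid = f"{pid}-E{e_idx + 1}"
            erng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, p_idx, e_idx))
            )
            cov = _draw_covariates(erng, patient_flags)
            master = generate_poisson_train(cfg.sync_master_rate, T, erng).spike_times
            trains = []
            epoch_units = []
            for u_idx in range(n_units):
                urng = np.random.default_rng(
                    np.random.SeedSequence(entropy=cfg.seed, spawn_key=(3, p_idx, e_idx, u_idx))
                )
                uid = f"U{unit_counter:04d}"
                unit_counter += 1
                z1 = urng.normal()
                z2 = cfg.latent_rho * z1 + math.sqrt(1 - cfg.latent_rho**2) * urng.normal()
                is_fast = stats.norm.cdf(z1) >= p_slow
                b_class = burst_names[int(np.searchsorted(burst_cuts, stats.norm.cdf(z2)))]
                if is_fast:
                    target_rate = max(
                        cfg.fast_rate_median + cfg.fast_rate_sd * urng.normal(), 2.2
                    )
                else:
                    target_rate = min(
                        cfg.slow_rate_median
                        * math.exp(cfg.slow_rate_sigma_log * urng.normal()),
                        1.9,
                    )
                b_idx = {"low": 0, "mid": 1, "high": 2}[str(b_class)]
                target_bisi = max(
                    cfg.burst_class_medians[b_idx]
                    + cfg.burst_class_sds[b_idx] * urng.normal(),
                    0.001,
                )
                target_rate = _apply_effects(cfg, cov, target_rate)

                joins = urng.random() < (pa_fast if is_fast else pa_slow)
                copy_prob = 0.0
                if joins and cfg.sync_master_rate > 0:
                    # coupling scales with the unit's rate: slow units carry
                    # few master copies, concentrating synchrony among fast units
                    copy_prob = min(
                        cfg.sync_copy_prob,
                        cfg.sync_copy_scale * target_rate / cfg.sync_master_rate,
                    )
                bg_rate = max(target_rate - copy_prob * cfg.sync_master_rate, 0.05)
                # short bursts for near-Poisson targets: rare long bursts in a
                # 300-s epoch realize the burst index too lumpily
                spb = 2.0 if target_bisi < 0.05 else 4.0
                bp = bursty_params_for(bg_rate, target_bisi, mean_spikes_per_burst=spb)
                train = generate_bursty_train(
                    bp["baseline_rate"],
                    bp["burst_rate"],
                    bp["mean_spikes_per_burst"],
                    bp["intra_burst_isi_ms"],
                    T,
                    urng,
                    unit_id=uid,
                    channel_id=int(urng.integers(1, 9)),
                    epoch_id=eid,
                )
                if copy_prob > 0:
                    copies = _copy_master(
                        master, copy_prob, cfg.sync_jitter_ms / 1000.0, T, urng
                    )
                    train = train.replace_times(
                        np.sort(np.concatenate([train.spike_times, copies]))
                    )
                trains.append(train)
                epoch_units.append(
                    {
                        "patient_id": pid,
                        "epoch_id": eid,
                        "unit_id": uid,
                        "channel_id": train.channel_id,
                        "rate_class_true": "fast" if is_fast else "slow",
                        "burst_class_true": str(b_class),
                        "target_rate": target_rate,
                        "target_bisi": target_bisi,
                        "in_network": bool(joins and copy_prob > 0),
                        "copy_prob": copy_prob,
                        "discharge": False,
                        "discharge_onset_s": np.nan,
                    }
                )
            for i in range(len(epoch_units)):
                for j in range(i + 1, len(epoch_units)):
                    pair_rows.append(
                        {
                            "patient_id": pid,
                            "epoch_id": eid,
                            "unit_a": epoch_units[i]["unit_id"],
                            "unit_b": epoch_units[j]["unit_id"],
                            "coupled_true": epoch_units[i]["in_network"]
                            and epoch_units[j]["in_network"],
                        }
                    )
            patients[pid].append(
                Epoch(eid, pid, T, trains, AnesthesiaRecord(**cov))
            )
            unit_rows.extend(epoch_units)

    units = pd.DataFrame(unit_rows)
    session = Session(patients)

    # evolving discharges: a fixed round(fraction * N) units chosen at random
    n_discharge = int(round(cfg.discharge_unit_fraction * len(units)))
    if n_discharge > 0:
        drng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(4,)))
        chosen = drng.choice(len(units), size=n_discharge, replace=False)
        by_epoch = {ep.epoch_id: ep for ep in session.iter_epochs()}
        for row_i in chosen:
            row = units.iloc[row_i]
            ep = by_epoch[row["epoch_id"]]
            onset = float(drng.uniform(0.1 * T, T - cfg.discharge_duration_s - 0.1 * T))
            for k, tr in enumerate(ep.trains):
                if tr.unit_id == row["unit_id"]:
                    ep.trains[k] = inject_discharge(
                        tr,
                        onset,
                        cfg.discharge_duration_s,
                        row["target_rate"] + cfg.discharge_extra_rate,
                        drng,
                        epoch_duration_s=T,
                        baseline_rate=row["target_rate"],
                    )
            units.loc[units.index[row_i], "discharge"] = True
            units.loc[units.index[row_i], "discharge_onset_s"] = onset

    return PopulationResult(session, units, pd.DataFrame(pair_rows), cfg)


def _apply_effects(cfg: PopulationConfig, cov: dict, rate: float) -> float:
    """Additive anesthesia effects on a unit's target rate (off by default)."""
    if not cfg.anesthesia_effects:
        return rate
    eff = cfg.anesthesia_effects
    delta = 0.0
    for name, beta in eff.items():
        v = cov.get(name)
        if isinstance(v, bool):
            delta += beta * float(v)
        elif isinstance(v, (int, float)):
            delta += beta * float(v)
    return max(rate + delta, 0.05)
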