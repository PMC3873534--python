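"""Domain types and I/O for spike-train recording sessions.

A *session* is the unit of analysis: a set of patients, each contributing two
or three 5-minute recording *epochs* obtained at successive microwire
positions, each epoch holding the sorted spike times of the single units
isolated during that epoch (up to 8 recording channels).

On disk a session is either

* a long CSV of spikes (``patient_id, epoch_id, unit_id, channel_id,
  spike_time_s``) with a JSON sidecar (``<path>.meta.json``) carrying epoch
  durations, the unit roster (so silent units survive a round trip) and
  optional anesthesia covariates, or
* a single JSON document with the same content.

Spike times are stored in seconds with microsecond (6-decimal) precision so
that the 100 us cross-channel duplicate rule survives a round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "Epoch",
    "AnesthesiaRecord",
    "Session",
    "SessionFormatError",
    "load_session",
    "write_session",
    "unit_count_table",
]

#: number of microwire recording channels available per epoch
MAX_CHANNELS = 8

#: default epoch duration in seconds (5-minute intra-operative recordings)
DEFAULT_EPOCH_DURATION_S = 300.0


class SessionFormatError(ValueError):
    """Raised when a session file fails to parse or violates an invariant."""


@dataclass(frozen=True)
class AnesthesiaRecord:
    """Anesthesia context of one epoch, covariates of the firing-rate GLM."""

    sevoflurane_pct: Optional[float] = None
    midazolam_at_induction: Optional[bool] = None
    propofol_at_induction: Optional[bool] = None
    fentanyl_use: Optional[str] = None  # {"induction", "intervals", "none"}
    temperature_c: Optional[float] = None
    gas_carrier: Optional[str] = None  # {"air", "NO", "neither"}
    decadron_use: Optional[bool] = None
    minutes_since_last_change: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sevoflurane_pct is not None and self.sevoflurane_pct < 0:
            raise ValueError("sevoflurane_pct must be >= 0")
        if (
            self.minutes_since_last_change is not None
            and self.minutes_since_last_change < 0
        ):
            raise ValueError("minutes_since_last_change must be >= 0")
        if self.fentanyl_use is not None and self.fentanyl_use not in (
            "induction",
            "intervals",
            "none",
        ):
            raise ValueError(f"invalid fentanyl_use: {self.fentanyl_use!r}")
        if self.gas_carrier is not None and self.gas_carrier not in (
            "air",
            "NO",
            "neither",
        ):
            raise ValueError(f"invalid gas_carrier: {self.gas_carrier!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpikeTrain:
    """Spike occurrence times of one sorted single unit within one epoch.

    Times are seconds relative to epoch start, non-decreasing on ingest and
    strictly increasing after duplicate removal.
    """

    unit_id: str
    channel_id: int
    spike_times: np.ndarray
    epoch_id: str

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size and not np.all(np.isfinite(t)):
            raise SessionFormatError(
                f"unit {self.unit_id}: non-finite spike time"
            )
        if t.size and t.min() < 0:
            raise SessionFormatError(
                f"unit {self.unit_id}: spike time out of range (negative)"
            )
        if not (1 <= int(self.channel_id) <= MAX_CHANNELS):
            raise SessionFormatError(
                f"unit {self.unit_id}: channel_id {self.channel_id} outside 1..{MAX_CHANNELS}"
            )
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        self.spike_times = t
        self.channel_id = int(self.channel_id)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def replace_times(self, times: np.ndarray) -> "SpikeTrain":
        return SpikeTrain(self.unit_id, self.channel_id, np.asarray(times, float), self.epoch_id)


@dataclass
class Epoch:
    """One continuous recording at a fixed microwire position."""

    epoch_id: str
    patient_id: str
    duration_s: float = DEFAULT_EPOCH_DURATION_S
    trains: list[SpikeTrain] = field(default_factory=list)
    covariates: Optional[AnesthesiaRecord] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise SessionFormatError("duration_s must be > 0")
        seen: set[str] = set()
        for tr in self.trains:
            if tr.epoch_id != self.epoch_id:
                raise SessionFormatError(
                    f"train {tr.unit_id} has epoch_id {tr.epoch_id!r}, expected {self.epoch_id!r}"
                )
            if tr.unit_id in seen:
                raise SessionFormatError(
                    f"duplicate unit_id {tr.unit_id!r} within epoch {self.epoch_id!r}"
                )
            seen.add(tr.unit_id)
            if tr.n_spikes and tr.spike_times[-1] > self.duration_s:
                raise SessionFormatError(
                    f"unit {tr.unit_id}: spike time out of range "
                    f"({tr.spike_times[-1]:.6f} s > epoch duration {self.duration_s} s)"
                )

    @property
    def n_units(self) -> int:
        return len(self.trains)


@dataclass
class Session:
    """All epochs of a recording study, grouped by patient."""

    patients: dict[str, list[Epoch]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, epochs in self.patients.items():
            seen: set[str] = set()
            for ep in epochs:
                if ep.patient_id != pid:
                    raise SessionFormatError(
                        f"epoch {ep.epoch_id!r} has patient_id {ep.patient_id!r}, expected {pid!r}"
                    )
                if ep.epoch_id in seen:
                    raise SessionFormatError(
                        f"duplicate epoch_id {ep.epoch_id!r} for patient {pid!r}"
                    )
                seen.add(ep.epoch_id)

    def iter_epochs(self) -> Iterator[Epoch]:
        for epochs in self.patients.values():
            yield from epochs

    def iter_trains(self) -> Iterator[tuple[Epoch, SpikeTrain]]:
        for ep in self.iter_epochs():
            for tr in ep.trains:
                yield ep, tr

    @property
    def n_units(self) -> int:
        return sum(ep.n_units for ep in self.iter_epochs())

    @property
    def n_epochs(self) -> int:
        return sum(len(e) for e in self.patients.values())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["patient_id", "epoch_id", "unit_id", "channel_id", "spike_time_s"]


def _epoch_meta(ep: Epoch) -> dict:
    return {
        "patient_id": ep.patient_id,
        "epoch_id": ep.epoch_id,
        "duration_s": ep.duration_s,
        "units": [
            {"unit_id": tr.unit_id, "channel_id": tr.channel_id} for tr in ep.trains
        ],
        "covariates": ep.covariates.to_dict() if ep.covariates is not None else None,
    }


def _session_to_obj(session: Session) -> dict:
    obj = {"epochs": []}
    for ep in session.iter_epochs():
        meta = _epoch_meta(ep)
        meta["spikes"] = {
            tr.unit_id: [f"{t:.6f}" for t in tr.spike_times] for tr in ep.trains
        }
        obj["epochs"].append(meta)
    return obj


def _meta_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_session(session: Session, path: str | Path, format: str = "csv") -> Path:
    """Write ``session`` to ``path``; bit-stable for a fixed session.

    ``format='csv'`` writes the spike table at ``path`` plus a
    ``<path>.meta.json`` sidecar; ``format='json'`` writes one JSON document.
    """
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(_session_to_obj(session), indent=1, sort_keys=True) + "\n"
        )
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for ep in session.iter_epochs():
        for tr in ep.trains:
            for t in tr.spike_times:
                rows.append(
                    (ep.patient_id, ep.epoch_id, tr.unit_id, tr.channel_id, f"{t:.6f}")
                )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")
    meta = {"epochs": [_epoch_meta(ep) for ep in session.iter_epochs()]}
    _meta_sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def _build_session(epoch_metas: list[dict], spikes_by_epoch: dict) -> Session:
    patients: dict[str, list[Epoch]] = {}
    for meta in epoch_metas:
        pid = str(meta["patient_id"])
        eid = str(meta["epoch_id"])
        duration = float(meta.get("duration_s", DEFAULT_EPOCH_DURATION_S))
        cov = meta.get("covariates")
        record = AnesthesiaRecord(**cov) if cov else None
        trains = []
        epoch_spikes = spikes_by_epoch.get((pid, eid), {})
        for unit in meta["units"]:
            uid = str(unit["unit_id"])
            times = np.asarray(epoch_spikes.get(uid, []), dtype=float)
            trains.append(SpikeTrain(uid, int(unit["channel_id"]), times, eid))
        # spikes for units missing from the roster are a format error
        extra = set(epoch_spikes) - {str(u["unit_id"]) for u in meta["units"]}
        if extra:
            raise SessionFormatError(
                f"spikes for unit(s) {sorted(extra)} not in roster of epoch {eid!r}"
            )
        patients.setdefault(pid, []).append(
            Epoch(eid, pid, duration, trains, record)
        )
    return Session(patients)


def load_session(path: str | Path, format: str = "csv") -> Session:
    """Load and validate a session written by :func:`write_session`.

    Tolerates unsorted spike times (sorts them) but rejects NaN, negative or
    out-of-range times and duplicate unit ids within an epoch.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"cannot parse {path}: {exc}") from exc
        spikes_by_epoch = {
            (str(m["patient_id"]), str(m["epoch_id"])): {
                uid: [float(t) for t in times]
                for uid, times in m.get("spikes", {}).items()
            }
            for m in obj["epochs"]
        }
        return _build_session(obj["epochs"], spikes_by_epoch)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    meta_path = _meta_sidecar(path)
    if not meta_path.exists():
        raise SessionFormatError(f"missing metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
        df = pd.read_csv(path, dtype={c: str for c in _CSV_COLUMNS[:3]})
    except (json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise SessionFormatError(f"cannot parse session at {path}: {exc}") from exc
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"spike CSV missing columns: {sorted(missing)}")
    spikes_by_epoch: dict[tuple[str, str], dict[str, list[float]]] = {}
    if len(df):
        times = pd.to_numeric(df["spike_time_s"], errors="coerce")
        if times.isna().any():
            raise SessionFormatError("non-numeric or NaN spike_time_s in CSV")
        for (pid, eid, uid), grp in df.assign(_t=times).groupby(
            ["patient_id", "epoch_id", "unit_id"], sort=False
        ):
            spikes_by_epoch.setdefault((pid, eid), {})[uid] = grp["_t"].tolist()
    return _build_session(meta["epochs"], spikes_by_epoch)


def unit_count_table(session: Session) -> pd.DataFrame:
    """One row per epoch with its number of sorted units.

    Totals are conserved: ``n_units.sum()`` equals the number of spike trains
    in the session.
    """
    rows = [
        (ep.patient_id, ep.epoch_id, ep.n_units) for ep in session.iter_epochs()
    ]
    return pd.DataFrame(rows, columns=["patient_id", "epoch_id", "n_units"])
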