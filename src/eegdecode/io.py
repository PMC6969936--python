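"""File formats and run configuration.

The package's native container is HDF5: a recording file holds ``data``
(channels x samples, microvolts), per-column event datasets under
``events/``, and ``fs_hz`` / ``channel_labels`` attributes; an epoch file
holds one group per epoch role with ``data``, ``times_ms`` and the label
columns.  Events are also read/written as BIDS-style ``*_events.tsv``
(onset in seconds, duration, sample, trial_type, plus the package's label
columns).  EDF recordings are read through MNE; events must come from a
sidecar TSV if the EDF carries no annotations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import ClassifierSpec, SchemeSpec
from .design import DesignSpec, VviqForm
from .preprocess import EpochSet, PreprocessConfig
from .stats import StatsConfig
from .synthetic import EVENT_COLUMNS, NoiseConfig, Recording, SimConfig

__all__ = [
    "save_recording",
    "load_recording",
    "read_recording",
    "events_to_tsv",
    "events_from_tsv",
    "save_epochs",
    "load_epochs",
    "vviq_to_frame",
    "vviq_from_frame",
    "AnalysisSpec",
    "RunConfig",
    "config_hash",
]

_STR = h5py.string_dtype(encoding="utf-8")


def save_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording to the package HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", shuffle=True)
        f.attrs["fs_hz"] = float(rec.fs_hz)
        f.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
        g = f.create_group("events")
        for col in EVENT_COLUMNS:
            vals = rec.events[col].to_numpy()
            if vals.dtype.kind in "OU":
                g.create_dataset(col, data=[str(v) for v in vals], dtype=_STR)
            else:
                g.create_dataset(col, data=vals.astype(np.int64))


def load_recording(path: str | Path) -> Recording:
    """Read a recording from the package HDF5 container."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs_hz"])
        labels = [str(c) for c in f.attrs["channel_labels"]]
        ev = {}
        for col in EVENT_COLUMNS:
            vals = f["events"][col][()]
            if vals.dtype.kind in "OS":
                vals = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                 for v in vals])
            ev[col] = vals
    return Recording(
        data=data, fs_hz=fs, channel_labels=labels, events=pd.DataFrame(ev)
    )


def events_to_tsv(events: pd.DataFrame, path: str | Path, fs_hz: float) -> None:
    """Write an event table as a BIDS-style ``*_events.tsv``."""
    out = pd.DataFrame(
        {
            "onset": events["onset_sample"] / fs_hz,
            "duration": 0.0,
            "sample": events["onset_sample"],
            "trial_type": events["epoch_role"],
        }
    )
    for col in ("stimulus_id", "category", "exemplar", "block", "trial", "stream"):
        out[col] = events[col]
    out.to_csv(path, sep="\t", index=False)


def events_from_tsv(path: str | Path, fs_hz: float | None = None) -> pd.DataFrame:
    """Read a BIDS-style events TSV back into the internal column layout."""
    df = pd.read_csv(path, sep="\t")
    if "sample" in df.columns:
        onset = df["sample"].astype(int)
    elif fs_hz is not None:
        onset = (df["onset"] * fs_hz).round().astype(int)
    else:
        raise ValueError("events TSV has no 'sample' column and no fs_hz given")
    out = pd.DataFrame({"onset_sample": onset, "epoch_role": df["trial_type"]})
    for col in ("stimulus_id", "category", "exemplar", "block", "trial", "stream"):
        out[col] = df[col] if col in df.columns else -1
    return out


def read_recording(
    path: str | Path,
    format: str = "container",
    events_tsv: str | Path | None = None,
) -> Recording:
    """Read a recording from the HDF5 container or an EDF file.

    For EDF, events are taken from the sidecar TSV; if none is given and
    the EDF carries no annotations this is an error — the pipeline cannot
    epoch without events.
    """
    if format == "container":
        rec = load_recording(path)
        if events_tsv is not None:
            rec.events = events_from_tsv(events_tsv, rec.fs_hz)
        return rec
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        if events_tsv is not None:
            events = events_from_tsv(events_tsv, fs)
        else:
            ann = raw.annotations
            if len(ann) == 0:
                raise ValueError(
                    "EDF has no annotations and no events TSV was provided"
                )
            events = pd.DataFrame(
                {
                    "onset_sample": (ann.onset * fs).round().astype(int),
                    "epoch_role": list(ann.description),
                    "stimulus_id": "",
                    "category": "",
                    "exemplar": -1,
                    "block": -1,
                    "trial": -1,
                    "stream": -1,
                }
            )
        return Recording(
            data=data, fs_hz=fs, channel_labels=list(raw.ch_names), events=events
        )
    raise ValueError(f"unknown recording format {format!r}")


def save_epochs(path: str | Path, epoch_sets: dict[str, EpochSet]) -> None:
    """Write one or more epoch sets (keyed by role) to an HDF5 file."""
    with h5py.File(path, "w") as f:
        for role, ep in epoch_sets.items():
            g = f.create_group(role)
            g.create_dataset("data", data=ep.data, compression="gzip", shuffle=True)
            g.create_dataset("times_ms", data=ep.times_ms)
            lab = g.create_group("labels")
            for col in ep.labels.columns:
                vals = ep.labels[col].to_numpy()
                if vals.dtype.kind in "OU":
                    lab.create_dataset(col, data=[str(v) for v in vals], dtype=_STR)
                else:
                    lab.create_dataset(col, data=vals)


def load_epochs(path: str | Path) -> dict[str, EpochSet]:
    """Read epoch sets back from HDF5, keyed by role."""
    out: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as f:
        for role in f:
            g = f[role]
            labels = {}
            for col in g["labels"]:
                vals = g["labels"][col][()]
                if vals.dtype.kind in "OS":
                    vals = np.array(
                        [v.decode() if isinstance(v, bytes) else str(v) for v in vals]
                    )
                labels[col] = vals
            out[role] = EpochSet(
                data=g["data"][()],
                times_ms=g["times_ms"][()],
                labels=pd.DataFrame(labels),
            )
    return out


def vviq_to_frame(forms: dict[str, VviqForm]) -> pd.DataFrame:
    """VVIQ forms as a long table (subject, administration, item, rating)."""
    rows = []
    for subject, form in forms.items():
        for adm, ratings in (
            ("eyes_open", form.eyes_open),
            ("eyes_closed", form.eyes_closed),
        ):
            for item, rating in enumerate(ratings, start=1):
                rows.append((subject, adm, item, int(rating)))
    return pd.DataFrame(rows, columns=["subject", "administration", "item", "rating"])


def vviq_from_frame(df: pd.DataFrame) -> dict[str, VviqForm]:
    """Rebuild VVIQ forms from the long-table layout."""
    forms = {}
    for subject, sub in df.groupby("subject", sort=True):
        adm = {}
        for name, rows in sub.groupby("administration"):
            adm[name] = tuple(rows.sort_values("item")["rating"].astype(int))
        forms[str(subject)] = VviqForm(
            eyes_open=adm["eyes_open"], eyes_closed=adm["eyes_closed"]
        )
    return forms


@dataclass(frozen=True)
class AnalysisSpec:
    """One decoding analysis: a scheme applied to (train, test) epoch roles.

    ``test_role`` None means within-condition cross-validation on
    ``train_role``.  ``category_subset`` restricts epochs to one category
    (required for the exemplar contrast).  ``generalize`` additionally
    computes the temporal-generalization matrix (cross analyses only).
    """

    name: str
    scheme: SchemeSpec
    train_role: str
    test_role: str | None = None
    category_subset: str | None = None
    generalize: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; JSON round-trippable and hashable."""

    design: DesignSpec = field(default_factory=DesignSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    analyses: tuple[AnalysisSpec, ...] = ()
    stats: StatsConfig = field(default_factory=StatsConfig)
    subject_perm_analyses: tuple[str, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(x):
            return tuple(x) if isinstance(x, list) else x

        design = dict(d.get("design", {}))
        if "epoch_window_ms" in design:
            design["epoch_window_ms"] = tup(design["epoch_window_ms"])
        sim = dict(d.get("sim", {}))
        if "noise" in sim:
            sim["noise"] = NoiseConfig(**sim["noise"])
        pre = dict(d.get("preprocess", {}))
        if "epoch_window_ms" in pre:
            pre["epoch_window_ms"] = tup(pre["epoch_window_ms"])
        analyses = []
        for a in d.get("analyses", []):
            a = dict(a)
            a["scheme"] = SchemeSpec(**a["scheme"])
            analyses.append(AnalysisSpec(**a))
        return cls(
            design=DesignSpec(**design),
            sim=SimConfig(**sim),
            preprocess=PreprocessConfig(**pre),
            classifier=ClassifierSpec(**d.get("classifier", {})),
            analyses=tuple(analyses),
            stats=StatsConfig(**d.get("stats", {})),
            subject_perm_analyses=tup(d.get("subject_perm_analyses", ())),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, src: str | Path) -> "RunConfig":
        """Load from a JSON file path or a JSON string."""
        text = str(src)
        if not text.lstrip().startswith("{"):
            text = Path(src).read_text()
        return cls.from_dict(json.loads(text))


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of a run configuration, for provenance tagging."""
    text = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
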