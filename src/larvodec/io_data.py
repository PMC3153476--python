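"""Trial-level spike-count data model, validation and file I/O.

A *trial* is one odor presentation to one identified olfactory sensory
neuron (OSN): the spike count in the 1-s stimulation window plus the ten
1-s pre-stimulus spontaneous counts. Because all windows are 1 s long,
counts and rates in Hz are numerically identical.

Trial tables are flat delimited text (comma by default), one row per
trial, with the ten spontaneous bins as columns ``spont_1 .. spont_10``
(most recent bin last). Fitted models are archived as versioned,
checksummed JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

N_SPONT_BINS = 10
SPONT_COLUMNS = tuple(f"spont_{i}" for i in range(1, N_SPONT_BINS + 1))
REQUIRED_COLUMNS = ("neuron_id", "odor_id", "stim_count") + SPONT_COLUMNS
OPTIONAL_COLUMNS = ("larva_id", "trial_index")

ARCHIVE_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """A trial table is missing a required column."""


class ValidationError(ValueError):
    """A trial table row violates the trial-record invariants."""


class ArchiveError(ValueError):
    """A model archive could not be loaded."""


class IntegrityError(ArchiveError):
    """Archive payload does not match its checksum."""


class VersionError(ArchiveError):
    """Archive was written with an unsupported format version."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested operation."""


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation to one OSN.

    ``stim_count`` is the number of spikes in the 1-s stimulation window;
    ``spont_bins`` are the spike counts in each of the ten 1-s bins
    immediately preceding the stimulus, ordered oldest first.
    """

    neuron_id: str
    odor_id: str
    stim_count: int
    spont_bins: tuple
    larva_id: Optional[str] = None
    trial_index: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "spont_bins", tuple(int(b) for b in self.spont_bins))
        if self.stim_count < 0:
            raise ValidationError(f"stim_count must be >= 0, got {self.stim_count}")
        if len(self.spont_bins) != N_SPONT_BINS:
            raise ValidationError(
                f"expected {N_SPONT_BINS} spontaneous bins, got {len(self.spont_bins)}"
            )
        if any(b < 0 for b in self.spont_bins):
            raise ValidationError("spontaneous bins must be >= 0")

    @property
    def spont_last(self) -> int:
        """Spontaneous count in the second immediately before stimulation."""
        return self.spont_bins[-1]


class Dataset:
    """An ordered collection of trials with its neuron and odor label sets.

    Label order follows first appearance in the trial sequence unless
    explicit orderings are supplied.
    """

    def __init__(
        self,
        trials: Iterable[TrialRecord],
        neuron_ids: Optional[Sequence[str]] = None,
        odor_ids: Optional[Sequence[str]] = None,
    ):
        self.trials = tuple(trials)
        if neuron_ids is None:
            neuron_ids = list(dict.fromkeys(t.neuron_id for t in self.trials))
        if odor_ids is None:
            odor_ids = list(dict.fromkeys(t.odor_id for t in self.trials))
        self.neuron_ids = tuple(neuron_ids)
        self.odor_ids = tuple(odor_ids)
        known_n, known_o = set(self.neuron_ids), set(self.odor_ids)
        for i, t in enumerate(self.trials):
            if t.neuron_id not in known_n:
                raise ValidationError(f"trial {i}: unknown neuron_id {t.neuron_id!r}")
            if t.odor_id not in known_o:
                raise ValidationError(f"trial {i}: unknown odor_id {t.odor_id!r}")
        index: dict = {}
        for t in self.trials:
            index.setdefault((t.neuron_id, t.odor_id), []).append(t)
        self._index = {k: tuple(v) for k, v in index.items()}

    def __len__(self) -> int:
        return len(self.trials)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.trials == other.trials
            and self.neuron_ids == other.neuron_ids
            and self.odor_ids == other.odor_ids
        )

    def trials_for(self, neuron_id: str, odor_id: str) -> tuple:
        return self._index.get((neuron_id, odor_id), ())

    def pairs(self):
        """(neuron, odor) pairs with at least one trial, in label order."""
        for n in self.neuron_ids:
            for o in self.odor_ids:
                if (n, o) in self._index:
                    yield n, o

    def subset(self, neurons=None, odors=None) -> "Dataset":
        """Restrict to the given neurons and/or odors (order preserved)."""
        keep_n = set(self.neuron_ids if neurons is None else neurons)
        keep_o = set(self.odor_ids if odors is None else odors)
        trials = [t for t in self.trials if t.neuron_id in keep_n and t.odor_id in keep_o]
        return Dataset(
            trials,
            [n for n in self.neuron_ids if n in keep_n],
            [o for o in self.odor_ids if o in keep_o],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        has_larva = any(t.larva_id is not None for t in self.trials)
        has_idx = any(t.trial_index is not None for t in self.trials)
        for t in self.trials:
            row = {"neuron_id": t.neuron_id, "odor_id": t.odor_id, "stim_count": t.stim_count}
            for c, b in zip(SPONT_COLUMNS, t.spont_bins):
                row[c] = b
            if has_larva:
                row["larva_id"] = t.larva_id
            if has_idx:
                row["trial_index"] = t.trial_index
            rows.append(row)
        columns = list(REQUIRED_COLUMNS)
        if has_larva:
            columns.append("larva_id")
        if has_idx:
            columns.append("trial_index")
        return pd.DataFrame(rows, columns=columns)


def _parse_count(value, column: str, row: int) -> int:
    try:
        f = float(str(value).strip())
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {column}={value!r} is not a number") from None
    if f != int(f):
        raise ValidationError(f"row {row}: {column}={value!r} is not an integer")
    i = int(f)
    if i < 0:
        raise ValidationError(f"row {row}: {column}={value!r} is negative")
    return i


def read_trials(path, schema: Optional[Mapping[str, str]] = None, sep: str = ",") -> Dataset:
    """Read a delimited trial table into a validated :class:`Dataset`.

    ``schema`` optionally maps canonical column names (``neuron_id``,
    ``stim_count``, ``spont_1`` ...) to the names used in the file.
    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    df = df.rename(columns={src: dst for src, dst in rename.items() if src in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown column(s): %s", ", ".join(unknown))

    trials = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        stim = _parse_count(row["stim_count"], "stim_count", pos)
        bins = tuple(_parse_count(row[c], c, pos) for c in SPONT_COLUMNS)
        larva = row["larva_id"] if "larva_id" in df.columns and row["larva_id"] != "" else None
        tidx = None
        if "trial_index" in df.columns and str(row["trial_index"]).strip() != "":
            tidx = _parse_count(row["trial_index"], "trial_index", pos)
        trials.append(
            TrialRecord(
                neuron_id=str(row["neuron_id"]),
                odor_id=str(row["odor_id"]),
                stim_count=stim,
                spont_bins=bins,
                larva_id=larva,
                trial_index=tidx,
            )
        )
    return Dataset(trials)


def write_trials(ds: Dataset, path, sep: str = ",") -> None:
    """Write ``ds`` as a delimited trial table readable by :func:`read_trials`."""
    ds.to_frame().to_csv(path, sep=sep, index=False)


def dataset_fingerprint(ds: Dataset) -> str:
    """SHA-256 over the canonical CSV rendering of the dataset."""
    return hashlib.sha256(ds.to_frame().to_csv(index=False).encode()).hexdigest()


@dataclass
class ModelArchive:
    """Serialized decoder-model parameters plus provenance metadata."""

    params: dict
    fingerprint: Optional[str] = None
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    format_version: int = ARCHIVE_FORMAT_VERSION


def _payload_checksum(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def save_model(archive: ModelArchive, path) -> None:
    """Write a model archive as checksummed, versioned JSON."""
    payload = dataclasses.asdict(archive)
    doc = {"checksum": _payload_checksum(payload), "payload": payload}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path) -> ModelArchive:
    """Load a model archive, verifying checksum and format version."""
    doc = json.loads(Path(path).read_text())
    payload = doc.get("payload")
    if payload is None or "checksum" not in doc:
        raise ArchiveError("not a model archive")
    if _payload_checksum(payload) != doc["checksum"]:
        raise IntegrityError("archive checksum mismatch; file is corrupt or was edited")
    if payload.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise VersionError(
            f"unsupported archive format version {payload.get('format_version')!r}; "
            f"this build reads version {ARCHIVE_FORMAT_VERSION}"
        )
    return ModelArchive(**payload)
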