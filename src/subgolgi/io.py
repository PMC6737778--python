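"""Reading and writing labeled protein sequences and feature tables.

Sequences arrive as FASTA (multi-line records allowed), with class labels
either embedded in the header (final pipe-separated token, e.g. ``>Q8N2|cis``)
or supplied in a sidecar two-column CSV (``id,label``). Feature tables are
plain CSV with ``id`` and ``label`` as the first two columns followed by one
column per named feature.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Recognised class labels: cis-Golgi (receiving face) vs trans-Golgi
#: (dispatching face).
LABELS = ("cis", "trans")


class SequenceError(ValueError):
    """Raised when a sequence fails validation."""


class DatasetError(ValueError):
    """Raised for malformed datasets (duplicate ids, missing labels...)."""


def validate_sequence(raw: str, policy: str = "drop_nonstandard") -> str:
    """Canonicalise a raw protein sequence.

    Parameters
    ----------
    raw:
        Sequence string; whitespace is removed and case folded to upper.
    policy:
        ``"strict"`` rejects any letter outside the 20-letter alphabet,
        reporting the offending letter and its (1-based) position.
        ``"drop_nonstandard"`` silently removes non-standard letters
        (B, J, O, U, X, Z, ``*`` ...) with a logged warning.

    Returns
    -------
    str
        The canonical uppercase sequence over ``ACDEFGHIKLMNPQRSTVWY``.
    """
    if policy not in ("strict", "drop_nonstandard"):
        raise ValueError(f"unknown validation policy: {policy!r}")
    seq = "".join(raw.split()).upper()
    if not seq:
        raise SequenceError("sequence is empty")
    if policy == "strict":
        for pos, letter in enumerate(seq, start=1):
            if letter not in _AA_SET:
                raise SequenceError(
                    f"non-standard residue {letter!r} at position {pos}"
                )
        return seq
    kept = [c for c in seq if c in _AA_SET]
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        logger.warning("dropped %d non-standard residue(s)", n_dropped)
    if not kept:
        raise SequenceError("sequence empty after dropping non-standard residues")
    return "".join(kept)


@dataclass(frozen=True)
class ProteinRecord:
    """One labeled protein sequence."""

    id: str
    sequence: str
    description: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise DatasetError(
                f"record {self.id!r}: unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )


@dataclass
class Dataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids.

    Record order is preserved from the input file: downstream jackknife
    sweeps are deterministic only relative to this ordering.
    """

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise DatasetError(f"duplicate record id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records if r.label is not None))

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]


def _split_header_token(token: str) -> tuple[str, str | None]:
    if "|" in token:
        head, _, tail = token.rpartition("|")
        return head, tail
    return token, None


def read_fasta(
    path: str | Path,
    label_source: str = "header_token",
    labels_path: str | Path | None = None,
    policy: str = "drop_nonstandard",
) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Parameters
    ----------
    path:
        FASTA file; multi-line sequences are concatenated.
    label_source:
        ``"header_token"``: label is the final pipe-separated token of the
        header id (``>prot1|cis``). ``"sidecar_table"``: labels come from
        ``labels_path``, a headered two-column CSV ``id,label``; every FASTA
        id must appear in it. ``"unlabeled"``: no labels attached.
    policy:
        Residue validation policy, see :func:`validate_sequence`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if label_source not in ("header_token", "sidecar_table", "unlabeled"):
        raise ValueError(f"unknown label_source: {label_source!r}")

    label_map: dict[str, str] = {}
    if label_source == "sidecar_table":
        if labels_path is None:
            raise ValueError("sidecar_table label_source requires labels_path")
        table = pd.read_csv(labels_path, dtype=str)
        if list(table.columns[:2]) != ["id", "label"]:
            raise DatasetError(
                f"sidecar table must have columns id,label; got {list(table.columns)}"
            )
        label_map = dict(zip(table["id"], table["label"]))

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        if label_source == "header_token":
            rec_id, label = _split_header_token(token)
            if label not in LABELS:
                raise DatasetError(
                    f"header token of {token!r} does not end in a known label"
                )
        elif label_source == "sidecar_table":
            rec_id = token
            if rec_id not in label_map:
                raise DatasetError(f"record {rec_id!r} missing from sidecar table")
            label = label_map[rec_id]
        else:
            rec_id, label = token, None
        seq = validate_sequence(str(rec.seq), policy=policy)
        records.append(
            ProteinRecord(id=rec_id, sequence=seq, description=rec.description, label=label)
        )
    return Dataset(records)


def write_fasta(dataset: Dataset, path: str | Path, label_in_header: bool = True) -> None:
    """Write a dataset as FASTA, embedding labels as ``>id|label``."""
    recs = []
    for r in dataset:
        rid = f"{r.id}|{r.label}" if (label_in_header and r.label) else r.id
        recs.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Samples x named-features matrix with an aligned optional label vector.

    The universal currency between encoding, selection, balancing and
    evaluation stages.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} ids x {len(self.feature_names)} names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names are not unique")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("matrix is unlabeled")
        return np.asarray(self.labels, dtype=object)

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        """Return a copy restricted to ``names``, in the given order."""
        index = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown feature name(s): {missing}")
        cols = [index[n] for n in names]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, cols].copy(),
            labels=list(self.labels) if self.labels is not None else None,
        )

    def select_samples(self, idx: Iterable[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx].copy(),
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels if self.labels is not None else "")
        df.insert(0, "id", self.sample_ids)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Serialise a feature matrix to CSV (columns ``id,label,<features>``).

    Values round-trip through :func:`read_feature_table` to at least 12
    significant digits (repr-precision floats are written).
    """
    matrix.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, dtype={"id": str, "label": str}, keep_default_na=False)
    if list(df.columns[:2]) != ["id", "label"]:
        raise DatasetError(
            f"feature table must start with columns id,label; got {list(df.columns[:2])}"
        )
    feature_names = list(df.columns[2:])
    labels: list[str] | None = list(df["label"])
    if all(l == "" for l in labels):
        labels = None
    return FeatureMatrix(
        sample_ids=list(df["id"]),
        feature_names=feature_names,
        values=df[feature_names].to_numpy(dtype=float),
        labels=labels,
    )
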