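"""Composition-based sequence encoders.

Two encoders turn a variable-length protein sequence into fixed-length
frequency vectors:

* **k-gapped dipeptide composition (k-gapDC)** — for every ordered residue
  pair (A1, A2), the frequency of occurrences where A1 and A2 are separated
  by k intervening residues, normalised by the number of such pairs
  (L - k - 1). A 400-entry vector; k = 2 by default. Non-adjacent pairs
  capture medium-range structure (e.g. residues hydrogen-bonded across a
  helix turn) that adjacent-dipeptide composition misses.

* **split amino acid composition (SAAC)** — residue frequencies computed
  separately on the N-terminal segment (first Xn residues), the intermediate
  block, and the C-terminal segment (last Xc residues), concatenated into a
  60-entry vector (Xn = Xc = 30 by default). Terminal segments often carry
  the signal-anchor information that determines Golgi residency.

Both are exposed as scikit-learn transformers operating on sequences of
canonical residue strings, plus plain functions for single sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMINO_ACIDS, Dataset, FeatureMatrix

_AA_INDEX = np.full(128, -1, dtype=np.int64)
for _j, _a in enumerate(AMINO_ACIDS):
    _AA_INDEX[ord(_a)] = _j


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded (too short, bad residue)."""


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder hyperparameters.

    k is the number of intervening residues in a gapped pair (pair =
    positions i and i+k+1); Xn / Xc are the terminal segment lengths in
    residues.
    """

    k: int = 2
    xn: int = 30
    xc: int = 30
    gap_convention: str = "intervening"  # or "distance": pair = (i, i+k)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.xn < 1 or self.xc < 1:
            raise ValueError("Xn and Xc must be >= 1")
        if self.gap_convention not in ("intervening", "distance"):
            raise ValueError(f"unknown gap convention: {self.gap_convention!r}")


def _seq_to_indices(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    idx = _AA_INDEX[arr]
    if np.any(idx < 0):
        bad = sequence[int(np.argmax(idx < 0))]
        raise EncodingError(f"non-canonical residue {bad!r} in sequence")
    return idx


def kgap_feature_names(k: int) -> list[str]:
    """Names ``"<A1><A2>.gap<k>"`` in A1-major order (e.g. ``FP.gap2``)."""
    return [f"{a1}{a2}.gap{k}" for a1 in AMINO_ACIDS for a2 in AMINO_ACIDS]


def saac_feature_names() -> list[str]:
    """Segment-wise residue names: Nterminal_*, InterTier_*, Cterminal_*."""
    return (
        [f"Nterminal_{a}" for a in AMINO_ACIDS]
        + [f"InterTier_{a}" for a in AMINO_ACIDS]
        + [f"Cterminal_{a}" for a in AMINO_ACIDS]
    )


def encode_kgap_dipeptide(
    sequence: str, k: int = 2, gap_convention: str = "intervening"
) -> np.ndarray:
    """k-gapped dipeptide composition of one sequence.

    Under the default ``intervening`` convention a k-gapped pair is
    (position i, position i+k+1) — k residues sit between the two members —
    and the normaliser is the pair count L - k - 1. The alternative
    ``distance`` convention pairs (i, i+k) with normaliser L - k.

    Returns a length-400 vector summing to 1.
    """
    offset = k + 1 if gap_convention == "intervening" else k
    if gap_convention == "distance" and k < 1:
        raise ValueError("distance convention requires k >= 1")
    L = len(sequence)
    if L < offset + 1:
        raise EncodingError(
            f"sequence of length {L} too short for k={k} "
            f"({gap_convention} convention needs length >= {offset + 1})"
        )
    idx = _seq_to_indices(sequence)
    pair_codes = idx[: L - offset] * 20 + idx[offset:]
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    return counts / (L - offset)


def encode_saac(sequence: str, xn: int = 30, xc: int = 30) -> np.ndarray:
    """Split amino acid composition: three 20-entry frequency blocks.

    Blocks are, in order, the N-terminal ``xn`` residues, the intermediate
    block, and the C-terminal ``xc`` residues; each block is normalised by
    its own length, so each block sums to 1 (total vector length 60).

    Requires L >= xn + xc + 1 so the intermediate block is non-empty.
    """
    L = len(sequence)
    if L < xn + xc + 1:
        raise EncodingError(
            f"sequence of length {L} too short for SAAC with Xn={xn}, Xc={xc} "
            f"(needs length >= {xn + xc + 1})"
        )
    idx = _seq_to_indices(sequence)
    blocks = [idx[:xn], idx[xn : L - xc], idx[L - xc :]]
    out = np.empty(60)
    for b, seg in enumerate(blocks):
        out[b * 20 : (b + 1) * 20] = np.bincount(seg, minlength=20) / len(seg)
    return out


class KGapDipeptideEncoder(BaseEstimator, TransformerMixin):
    """Transformer: iterable of sequences -> (n, 400) k-gapDC matrix."""

    def __init__(self, k: int = 2, gap_convention: str = "intervening"):
        self.k = k
        self.gap_convention = gap_convention

    def fit(self, X, y=None):
        self.feature_names_ = kgap_feature_names(self.k)
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack(
            [encode_kgap_dipeptide(s, self.k, self.gap_convention) for s in X]
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(kgap_feature_names(self.k), dtype=object)


class SplitCompositionEncoder(BaseEstimator, TransformerMixin):
    """Transformer: iterable of sequences -> (n, 60) SAAC matrix."""

    def __init__(self, xn: int = 30, xc: int = 30):
        self.xn = xn
        self.xc = xc

    def fit(self, X, y=None):
        self.feature_names_ = saac_feature_names()
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([encode_saac(s, self.xn, self.xc) for s in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(saac_feature_names(), dtype=object)


_PART_ENCODERS = ("kgapdc", "saac")


def encode_dataset(
    data: Dataset,
    parts: tuple[str, ...] = ("kgapdc", "saac"),
    config: EncoderConfig | None = None,
) -> FeatureMatrix:
    """Encode every record of a dataset, concatenating the requested parts.

    ``parts`` is an ordered subset of ``{"kgapdc", "saac"}``; columns appear
    in part order (400 k-gapDC columns and/or 60 SAAC columns). Labels are
    carried through. A record failing an encoder precondition aborts with an
    error naming the record id.
    """
    if config is None:
        config = EncoderConfig()
    if not parts:
        raise ValueError("at least one feature part must be requested")
    for p in parts:
        if p not in _PART_ENCODERS:
            raise ValueError(f"unknown feature part {p!r}; expected {_PART_ENCODERS}")

    names: list[str] = []
    for p in parts:
        names.extend(kgap_feature_names(config.k) if p == "kgapdc" else saac_feature_names())

    rows = []
    for rec in data:
        try:
            pieces = []
            for p in parts:
                if p == "kgapdc":
                    pieces.append(
                        encode_kgap_dipeptide(rec.sequence, config.k, config.gap_convention)
                    )
                else:
                    pieces.append(encode_saac(rec.sequence, config.xn, config.xc))
            rows.append(np.concatenate(pieces))
        except EncodingError as exc:
            raise EncodingError(f"record {rec.id!r}: {exc}") from exc

    labels = None
    if any(r.label is not None for r in data):
        labels = [r.label for r in data]
    return FeatureMatrix(
        sample_ids=data.ids,
        feature_names=names,
        values=np.vstack(rows) if rows else np.empty((0, len(names))),
        labels=labels,
    )
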