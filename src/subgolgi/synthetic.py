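"""Synthetic labeled protein datasets with plantable composition signal.

The generator emulates the shape of the curated cis/trans Golgi benchmark
sets — two classes at a ~0.44 minority/majority ratio (42 cis / 95 trans
training, 13 / 51 test), sequence lengths spanning tens to hundreds of
residues — with residues drawn i.i.d. from a background distribution
(uniform by default, keeping the ANOVA null clean) and two kinds of
plantable signal:

* **gapped-dipeptide motifs** — for records of the motif's class, each
  eligible position i is rewritten to (A1 at i, A2 at i+k+1) with
  probability ``excess_rate``, raising that class's ``A1A2.gapK`` feature;
* **terminal bias** — within a named segment, each position is rewritten to
  a given residue with probability ``excess_prob``, shifting one SAAC block.

Rewrites are applied position-by-position in order; overlapping writes
resolve last-writer-wins. Generation is O(L) per sequence and fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AMINO_ACIDS, Dataset, ProteinRecord

_AA = np.array(list(AMINO_ACIDS))
_AA_TO_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Motif:
    """A planted k-gapped residue pair enriched in one class."""

    a1: str
    a2: str
    k: int = 2
    excess_rate: float = 0.15
    label: str = "trans"

    def __post_init__(self) -> None:
        if self.a1 not in _AA_TO_IDX or self.a2 not in _AA_TO_IDX:
            raise SyntheticSpecError(f"non-canonical motif residues {self.a1}{self.a2}")
        if not 0.0 <= self.excess_rate <= 1.0:
            raise SyntheticSpecError("excess_rate must be in [0, 1]")
        if self.k < 0:
            raise SyntheticSpecError("k must be >= 0")


@dataclass(frozen=True)
class TerminalBias:
    """Extra probability of one residue inside one SAAC segment, per class."""

    segment: str  # Nterminal | InterTier | Cterminal
    residue: str
    excess_prob: float = 0.2
    label: str = "trans"

    def __post_init__(self) -> None:
        if self.segment not in ("Nterminal", "InterTier", "Cterminal"):
            raise SyntheticSpecError(f"unknown segment {self.segment!r}")
        if self.residue not in _AA_TO_IDX:
            raise SyntheticSpecError(f"non-canonical residue {self.residue!r}")
        if not 0.0 <= self.excess_prob <= 1.0:
            raise SyntheticSpecError("excess_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a two-class labeled sequence dataset.

    Defaults mirror the benchmark training composition: 42 cis / 95 trans,
    lengths uniform on [80, 600] (min must stay >= 61 so SAAC with
    Xn = Xc = 30 is defined), uniform residue background.
    """

    n_cis: int = 42
    n_trans: int = 95
    length_range: tuple[int, int] = (80, 600)
    background: tuple[float, ...] | None = None  # 20 probabilities; None=uniform
    motifs: tuple[Motif, ...] = ()
    terminal_bias: TerminalBias | None = None
    xn: int = 30
    xc: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < self.xn + self.xc + 1:
            raise SyntheticSpecError(
                f"length range {self.length_range} must satisfy "
                f"min >= {self.xn + self.xc + 1} (SAAC precondition) and min <= max"
            )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
                raise SyntheticSpecError("background must be 20 probabilities summing to 1")
        if self.n_cis < 0 or self.n_trans < 0:
            raise SyntheticSpecError("class counts must be non-negative")


def _segment_slice(segment: str, L: int, xn: int, xc: int) -> slice:
    if segment == "Nterminal":
        return slice(0, xn)
    if segment == "Cterminal":
        return slice(L - xc, L)
    return slice(xn, L - xc)


def _draw_sequence(rng: np.random.Generator, spec: SyntheticSpec, label: str) -> str:
    lo, hi = spec.length_range
    L = int(rng.integers(lo, hi + 1))
    p = (
        np.asarray(spec.background, dtype=float)
        if spec.background is not None
        else np.full(20, 0.05)
    )
    idx = rng.choice(20, size=L, p=p)
    for motif in spec.motifs:
        if motif.label != label:
            continue
        offset = motif.k + 1
        n_pos = L - offset
        if n_pos <= 0:
            continue
        hits = np.flatnonzero(rng.random(n_pos) < motif.excess_rate)
        for i in hits:  # in-order rewrites; overlaps last-writer-wins
            idx[i] = _AA_TO_IDX[motif.a1]
            idx[i + offset] = _AA_TO_IDX[motif.a2]
    if spec.terminal_bias is not None and spec.terminal_bias.label == label:
        tb = spec.terminal_bias
        seg = _segment_slice(tb.segment, L, spec.xn, spec.xc)
        seg_len = seg.stop - seg.start
        hits = np.flatnonzero(rng.random(seg_len) < tb.excess_prob) + seg.start
        idx[hits] = _AA_TO_IDX[tb.residue]
    return "".join(_AA[idx])


def generate(spec: SyntheticSpec, id_prefix: str = "") -> Dataset:
    """Draw a labeled dataset from a :class:`SyntheticSpec`.

    Record ids are ``{prefix}cis_0000`` ... / ``{prefix}trans_0000`` ...;
    the cis block precedes the trans block. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for label, count in (("cis", spec.n_cis), ("trans", spec.n_trans)):
        for i in range(count):
            records.append(
                ProteinRecord(
                    id=f"{id_prefix}{label}_{i:04d}",
                    sequence=_draw_sequence(rng, spec, label),
                    label=label,
                )
            )
    return Dataset(records)


def make_train_test_pair(
    spec: SyntheticSpec,
    test_n_cis: int = 13,
    test_n_trans: int = 51,
) -> tuple[Dataset, Dataset]:
    """Two independent draws from the same generative process.

    The training set follows ``spec``; the test set shares every generative
    parameter but its own class counts (defaults 13 cis / 51 trans) and an
    offset sub-seed. Id namespaces ``train_*`` / ``test_*`` are disjoint.
    """
    train = generate(spec, id_prefix="train_")
    test_spec = SyntheticSpec(
        n_cis=test_n_cis,
        n_trans=test_n_trans,
        length_range=spec.length_range,
        background=spec.background,
        motifs=spec.motifs,
        terminal_bias=spec.terminal_bias,
        xn=spec.xn,
        xc=spec.xc,
        seed=(spec.seed + 7919) % (2**31 - 1),
    )
    test = generate(test_spec, id_prefix="test_")
    return train, test
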