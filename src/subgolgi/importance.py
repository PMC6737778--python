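"""Physicochemical breakdown of random-forest feature importances.

Forest importances attach to encoder features (dipeptide pairs and
segment-wise residue frequencies); to read them biologically they are
re-allocated to the five Lehninger residue classes:

* aromatic — F, W, Y
* non-polar / aliphatic — G, A, V, L, I, P, M
* polar, uncharged — S, T, C, N, Q
* positively charged — K, R, H
* negatively charged — D, E

A dipeptide feature ``A1A2.gapK`` contributes half its importance to the
class of each member residue; a segment feature ``Nterminal_D`` contributes
its full importance to the residue's class and, separately, to its segment
bucket. Totals are conserved: class percentages sum to 100.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .model import TrainedModel

RESIDUE_CLASSES: dict[str, str] = {}
for _aa in "FWY":
    RESIDUE_CLASSES[_aa] = "aromatic"
for _aa in "GAVLIPM":
    RESIDUE_CLASSES[_aa] = "nonpolar_aliphatic"
for _aa in "STCNQ":
    RESIDUE_CLASSES[_aa] = "polar_uncharged"
for _aa in "KRH":
    RESIDUE_CLASSES[_aa] = "positively_charged"
for _aa in "DE":
    RESIDUE_CLASSES[_aa] = "negatively_charged"

CLASS_NAMES = (
    "aromatic",
    "nonpolar_aliphatic",
    "polar_uncharged",
    "positively_charged",
    "negatively_charged",
)
SEGMENT_NAMES = ("Nterminal", "InterTier", "Cterminal")

_DIPEPTIDE_RE = re.compile(r"^([A-Z])([A-Z])\.gap(\d+)$")
_SAAC_RE = re.compile(r"^(Nterminal|InterTier|Cterminal)_([A-Z])$")


class ImportanceError(ValueError):
    pass


def classify_residue(aa: str) -> str:
    """Lehninger physicochemical class of a canonical residue letter."""
    try:
        return RESIDUE_CLASSES[aa]
    except KeyError:
        raise ImportanceError(f"non-canonical residue {aa!r}") from None


@dataclass
class ImportanceBreakdown:
    """Importance percentages re-allocated along three axes.

    ``by_class`` sums to 100; ``by_feature_type`` (dipeptide vs segment
    composition) sums to 100; ``by_segment`` sums to the SAAC share.
    """

    by_class: dict[str, float]
    by_feature_type: dict[str, float]
    by_segment: dict[str, float]
    top_features: list[tuple[str, float]]
    cumulative_curve: list[float]


def allocate(model: TrainedModel) -> ImportanceBreakdown:
    """Distribute a model's normalised importances over residue classes,
    feature types and sequence segments.

    ``A1A2.gapK`` splits importance half to class(A1), half to class(A2);
    ``<Segment>_<AA>`` allocates fully to class(AA) and to the segment.
    Any other feature name is rejected.
    """
    by_class = {c: 0.0 for c in CLASS_NAMES}
    by_type = {"kgapdc_pct": 0.0, "saac_pct": 0.0}
    by_segment = {s: 0.0 for s in SEGMENT_NAMES}

    total = float(np.sum(model.importances))
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ImportanceError(f"model importances sum to {total}, expected 1")

    for name, imp in zip(model.feature_names, model.importances):
        pct = 100.0 * float(imp)
        m = _DIPEPTIDE_RE.match(name)
        if m:
            a1, a2 = m.group(1), m.group(2)
            by_class[classify_residue(a1)] += pct / 2.0
            by_class[classify_residue(a2)] += pct / 2.0
            by_type["kgapdc_pct"] += pct
            continue
        m = _SAAC_RE.match(name)
        if m:
            segment, aa = m.group(1), m.group(2)
            by_class[classify_residue(aa)] += pct
            by_segment[segment] += pct
            by_type["saac_pct"] += pct
            continue
        raise ImportanceError(f"unrecognised feature name pattern: {name!r}")

    order = np.argsort(-model.importances, kind="stable")
    ranked = [(model.feature_names[j], 100.0 * float(model.importances[j])) for j in order]
    cumulative = np.cumsum([pct for _, pct in ranked]).tolist()
    return ImportanceBreakdown(
        by_class=by_class,
        by_feature_type=by_type,
        by_segment=by_segment,
        top_features=ranked,
        cumulative_curve=cumulative,
    )


def top_cumulative(model: TrainedModel, fraction: float) -> list[str]:
    """Smallest prefix of the descending-importance ranking whose cumulative
    importance reaches ``fraction`` (in (0, 1])."""
    if not 0.0 < fraction <= 1.0:
        raise ImportanceError(f"fraction must be in (0, 1], got {fraction}")
    order = np.argsort(-model.importances, kind="stable")
    cum = 0.0
    out: list[str] = []
    for j in order:
        out.append(model.feature_names[j])
        cum += float(model.importances[j])
        if cum >= fraction - 1e-12:
            break
    return out
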