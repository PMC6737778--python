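from collections import Counter

import numpy as np
import pytest

from subgolgi import RfConfig, allocate, classify_residue, top_cumulative, train
from subgolgi.importance import (
    CLASS_NAMES,
    RESIDUE_CLASSES,
    ImportanceError,
)
from subgolgi.io import AMINO_ACIDS, FeatureMatrix
from subgolgi.model import TrainedModel


def model_with_importances(names, importances):
    """Build a TrainedModel whose importances are set directly (the forest
    itself is irrelevant for allocation)."""
    rng = np.random.default_rng(0)
    m = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(8)],
        feature_names=list(names),
        values=rng.random((8, len(names))),
        labels=["cis"] * 4 + ["trans"] * 4,
    )
    model = train(m, RfConfig(n_trees=5, seed=0))
    model.importances = np.asarray(importances, dtype=float)
    return model


class TestResidueClasses:
    @pytest.mark.parametrize(
        "aa, cls",
        [
            ("F", "aromatic"),
            ("W", "aromatic"),
            ("P", "nonpolar_aliphatic"),
            ("I", "nonpolar_aliphatic"),
            ("G", "nonpolar_aliphatic"),
            ("D", "negatively_charged"),
            ("K", "positively_charged"),
            ("H", "positively_charged"),
            ("S", "polar_uncharged"),
        ],
    )
    def test_known_assignments(self, aa, cls):
        assert classify_residue(aa) == cls

    def test_partition_of_the_twenty_residues(self):
        assert sorted(RESIDUE_CLASSES) == sorted(AMINO_ACIDS)
        sizes = Counter(RESIDUE_CLASSES.values())
        assert sizes == {
            "aromatic": 3,
            "nonpolar_aliphatic": 7,
            "polar_uncharged": 5,
            "positively_charged": 3,
            "negatively_charged": 2,
        }
        assert sum(sizes.values()) == 20

    def test_non_canonical_rejected(self):
        with pytest.raises(ImportanceError):
            classify_residue("X")


class TestAllocate:
    def test_dipeptide_halving_rule(self):
        model = model_with_importances(["FP.gap2"], [1.0])
        b = allocate(model)
        assert b.by_class["aromatic"] == pytest.approx(50.0)
        assert b.by_class["nonpolar_aliphatic"] == pytest.approx(50.0)
        assert b.by_feature_type["kgapdc_pct"] == pytest.approx(100.0)

    def test_same_class_dipeptide_concentrates(self):
        model = model_with_importances(["IG.gap2"], [1.0])
        assert allocate(model).by_class["nonpolar_aliphatic"] == pytest.approx(100.0)

    def test_halving_is_symmetric_in_pair_order(self):
        a = allocate(model_with_importances(["FP.gap2"], [1.0])).by_class
        b = allocate(model_with_importances(["PF.gap2"], [1.0])).by_class
        assert a == pytest.approx(b)

    def test_saac_feature_allocates_to_class_and_segment(self):
        model = model_with_importances(["Nterminal_D", "InterTier_K"], [0.6, 0.4])
        b = allocate(model)
        assert b.by_class["negatively_charged"] == pytest.approx(60.0)
        assert b.by_class["positively_charged"] == pytest.approx(40.0)
        assert b.by_segment["Nterminal"] == pytest.approx(60.0)
        assert b.by_segment["InterTier"] == pytest.approx(40.0)
        assert b.by_feature_type["saac_pct"] == pytest.approx(100.0)

    def test_unrecognised_feature_name_rejected(self):
        model = model_with_importances(["weird_feature"], [1.0])
        with pytest.raises(ImportanceError, match="weird_feature"):
            allocate(model)

    def test_mixed_model_matches_brute_force_oracle(self, rng):
        """93-feature style model: per-feature allocation recomputed naively."""
        from subgolgi import kgap_feature_names, saac_feature_names

        names = list(rng.choice(kgap_feature_names(2), 59, replace=False)) + list(
            rng.choice(saac_feature_names(), 34, replace=False)
        )
        imp = rng.random(93)
        imp /= imp.sum()
        model = model_with_importances(names, imp)
        b = allocate(model)

        expected = {c: 0.0 for c in CLASS_NAMES}
        for name, w in zip(names, imp):
            pct = 100 * w
            if ".gap" in name:
                a1, a2 = name[0], name[1]
                expected[RESIDUE_CLASSES[a1]] += pct / 2
                expected[RESIDUE_CLASSES[a2]] += pct / 2
            else:
                expected[RESIDUE_CLASSES[name.split("_")[1]]] += pct
        assert b.by_class == pytest.approx(expected)
        assert sum(b.by_class.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(b.by_feature_type.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(b.by_segment.values()) == pytest.approx(
            b.by_feature_type["saac_pct"], abs=1e-6
        )


class TestTopCumulative:
    def test_fraction_one_returns_all(self):
        model = model_with_importances(
            ["AA.gap2", "AC.gap2", "AD.gap2"], [0.5, 0.3, 0.2]
        )
        assert len(top_cumulative(model, 1.0)) == 3

    def test_uniform_importances_half(self):
        names = [f"A{a}.gap2" for a in "CDEFGHIKLM"]
        model = model_with_importances(names, [0.1] * 10)
        assert len(top_cumulative(model, 0.5)) == 5

    def test_matches_cumulative_scan_oracle(self, rng):
        names = [f"{a}A.gap2" for a in AMINO_ACIDS]
        imp = rng.random(20)
        imp /= imp.sum()
        model = model_with_importances(names, imp)
        for fraction in (0.25, 0.5, 0.9):
            got = top_cumulative(model, fraction)
            order = np.argsort(-imp, kind="stable")
            cum, k = 0.0, 0
            for j in order:
                cum += imp[j]
                k += 1
                if cum >= fraction:
                    break
            assert len(got) == k

    def test_fraction_out_of_range(self):
        model = model_with_importances(["AA.gap2"], [1.0])
        with pytest.raises(ImportanceError):
            top_cumulative(model, 0.0)
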