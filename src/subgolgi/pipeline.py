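"""Two-stage ANOVA/SMOTE/random-forest optimization pipeline.

Stage 1 ranks the 400 k-gapDC features by ANOVA F on the training set and,
for each n in 1..n_max, trains and jackknife-evaluates a forest on the
SMOTE-balanced top-n matrix (plus an independent test when a held-out set is
supplied). The winning n's features are fused with the 60 SAAC features and
the sweep repeats on the fused matrix (secondary ANOVA); the final model is
trained on the stage-2 winner's balanced matrix.

Ranking happens on the original labeled matrix *before* SMOTE, so synthetic
samples never influence selection. Note the protocol deliberately mirrors
the classical one: feature selection and balancing are applied to the full
training set before cross-validation, which leaks information across folds
and flatters jackknife scores. :func:`safe_jackknife` provides the
leakage-free alternative (per-fold ranking + per-fold SMOTE).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .balancing import SmoteConfig, smote_balance
from .evaluation import (
    ConfusionCounts,
    MetricsReport,
    compute_metrics,
    independent_test,
    jackknife,
)
from .features import EncoderConfig, encode_dataset
from .io import Dataset, FeatureMatrix
from .model import RfConfig, TrainedModel, predict, train
from .selection import AnovaTopN, rank_features, select_top

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """n_max: largest feature count in a sweep; selection_criterion picks the
    winning n by jackknife accuracy ("cv_acc") or held-out accuracy
    ("independent_acc" — optimistically biases reported held-out metrics).
    One master seed derives every stage's randomness."""

    n_max: int = 100
    selection_criterion: str = "cv_acc"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.selection_criterion not in ("cv_acc", "independent_acc"):
            raise ValueError(f"unknown criterion {self.selection_criterion!r}")


@dataclass
class SweepRecord:
    n: int
    cv_metrics: MetricsReport
    independent_metrics: MetricsReport | None
    selected_feature_names: list[str]


@dataclass
class SweepResult:
    records: list[SweepRecord]

    def best(self, criterion: str = "cv_acc") -> SweepRecord:
        """Record with the highest accuracy under ``criterion``; ties go to
        the smallest n (parsimony)."""
        def score(rec: SweepRecord) -> float:
            if criterion == "cv_acc":
                return rec.cv_metrics.acc
            if rec.independent_metrics is None:
                raise PipelineError("independent_acc criterion but no test set was swept")
            return rec.independent_metrics.acc

        best = self.records[0]
        for rec in self.records[1:]:
            if score(rec) > score(best):
                best = rec
        return best

    def to_rows(self) -> list[dict]:
        rows = []
        for r in self.records:
            row = {"n": r.n, "cv_acc": r.cv_metrics.acc, "cv_mcc": r.cv_metrics.mcc}
            if r.independent_metrics is not None:
                row["ind_acc"] = r.independent_metrics.acc
                row["ind_mcc"] = r.independent_metrics.mcc
            rows.append(row)
        return rows


def _sub_seed(master: int, *offsets: int) -> int:
    s = master
    for o in offsets:
        s = (s * 1_000_003 + o) % (2**31 - 1)
    return s


def sweep(
    train_matrix: FeatureMatrix,
    test_matrix: FeatureMatrix | None,
    config: PipelineConfig,
) -> SweepResult:
    """Top-n feature sweep: for each n, select, balance, jackknife, test.

    The ranking is computed once on the (pre-SMOTE) training matrix; the
    selected sets are therefore nested (top-1 of top-2 of ...). n_max larger
    than the feature count is clipped with a warning.
    """
    ranking = rank_features(train_matrix)
    n_max = config.n_max
    if n_max > train_matrix.n_features:
        logger.warning(
            "n_max=%d clipped to feature count %d", n_max, train_matrix.n_features
        )
        n_max = train_matrix.n_features

    records: list[SweepRecord] = []
    for n in range(1, n_max + 1):
        sel = select_top(train_matrix, ranking, n)
        balanced = smote_balance(
            sel,
            SmoteConfig(
                k_neighbors=config.smote.k_neighbors,
                seed=_sub_seed(config.seed, 1, n),
            ),
        )
        rf_cfg = RfConfig(
            n_trees=config.rf.n_trees,
            max_features=config.rf.max_features,
            seed=_sub_seed(config.seed, 2, n),
            max_depth=config.rf.max_depth,
            min_samples_leaf=config.rf.min_samples_leaf,
            criterion=config.rf.criterion,
        )
        cv = jackknife(balanced, rf_cfg)
        ind = None
        if test_matrix is not None:
            model = train(balanced, rf_cfg)
            ind = independent_test(model, test_matrix.select_features(sel.feature_names))
        records.append(
            SweepRecord(
                n=n,
                cv_metrics=cv,
                independent_metrics=ind,
                selected_feature_names=list(sel.feature_names),
            )
        )
    return SweepResult(records)


def fuse(selected: FeatureMatrix, saac_matrix: FeatureMatrix) -> FeatureMatrix:
    """Column-concatenate surviving dipeptide features with the SAAC block.

    Survivor columns come first (e.g. 59 survivors + 60 SAAC = 119 columns).
    Sample ids must align row-for-row and the name sets must be disjoint.
    """
    if selected.n_features == 0:
        raise PipelineError("empty feature selection cannot be fused")
    if selected.sample_ids != saac_matrix.sample_ids:
        raise PipelineError("sample ids of the two matrices do not align")
    overlap = set(selected.feature_names) & set(saac_matrix.feature_names)
    if overlap:
        raise PipelineError(f"feature name collision: {sorted(overlap)[:5]}")
    return FeatureMatrix(
        sample_ids=list(selected.sample_ids),
        feature_names=list(selected.feature_names) + list(saac_matrix.feature_names),
        values=np.hstack([selected.values, saac_matrix.values]),
        labels=list(selected.labels) if selected.labels is not None else None,
    )


@dataclass
class FullRunResult:
    stage1: SweepResult
    stage2: SweepResult
    final_model: TrainedModel
    final_cv: MetricsReport
    final_independent: MetricsReport | None
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "stage1": [r for r in self.stage1.to_rows()],
            "stage2": [r for r in self.stage2.to_rows()],
            "final": {
                "jackknife": self.final_cv.to_dict(),
                "independent": (
                    self.final_independent.to_dict() if self.final_independent else None
                ),
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_full(
    train_data: Dataset, test_data: Dataset | None, config: PipelineConfig
) -> FullRunResult:
    """End-to-end two-stage optimization from labeled sequence datasets."""
    enc = config.encoder
    kgap_train = encode_dataset(train_data, ("kgapdc",), enc)
    saac_train = encode_dataset(train_data, ("saac",), enc)
    kgap_test = saac_test = None
    if test_data is not None:
        kgap_test = encode_dataset(test_data, ("kgapdc",), enc)
        saac_test = encode_dataset(test_data, ("saac",), enc)

    stage1 = sweep(kgap_train, kgap_test, config)
    win1 = stage1.best(config.selection_criterion)
    survivors = win1.selected_feature_names

    fused_train = fuse(kgap_train.select_features(survivors), saac_train)
    fused_test = None
    if kgap_test is not None:
        fused_test = fuse(kgap_test.select_features(survivors), saac_test)

    stage2_cfg = PipelineConfig(
        n_max=min(config.n_max, fused_train.n_features),
        selection_criterion=config.selection_criterion,
        encoder=config.encoder,
        smote=config.smote,
        rf=config.rf,
        seed=_sub_seed(config.seed, 3),
    )
    stage2 = sweep(fused_train, fused_test, stage2_cfg)
    win2 = stage2.best(config.selection_criterion)

    final_sel = fused_train.select_features(win2.selected_feature_names)
    final_balanced = smote_balance(
        final_sel,
        SmoteConfig(
            k_neighbors=config.smote.k_neighbors, seed=_sub_seed(stage2_cfg.seed, 1, win2.n)
        ),
    )
    final_rf = RfConfig(
        n_trees=config.rf.n_trees,
        max_features=config.rf.max_features,
        seed=_sub_seed(stage2_cfg.seed, 2, win2.n),
        max_depth=config.rf.max_depth,
        min_samples_leaf=config.rf.min_samples_leaf,
        criterion=config.rf.criterion,
    )
    final_model = train(final_balanced, final_rf)
    final_ind = None
    if fused_test is not None:
        final_ind = independent_test(
            final_model, fused_test.select_features(win2.selected_feature_names)
        )

    provenance = {
        "seed": config.seed,
        "selection_criterion": config.selection_criterion,
        "encoder": asdict(config.encoder),
        "smote": asdict(config.smote),
        "rf": asdict(config.rf),
        "stage1_n": win1.n,
        "stage1_features": survivors,
        "stage2_n": win2.n,
        "stage2_features": win2.selected_feature_names,
    }
    return FullRunResult(
        stage1=stage1,
        stage2=stage2,
        final_model=final_model,
        final_cv=win2.cv_metrics,
        final_independent=final_ind,
        provenance=provenance,
    )


def safe_jackknife(
    matrix: FeatureMatrix,
    n_features: int,
    rf_config: RfConfig | None = None,
    smote: SmoteConfig | None = None,
) -> MetricsReport:
    """Leakage-free leave-one-out: rank, select and (optionally) balance
    inside every training fold, so the held-out sample never informs feature
    selection or oversampling. The honest counterpart of the classical
    select-then-cross-validate protocol; on signal-free data it stays at
    chance.
    """
    if rf_config is None:
        rf_config = RfConfig()
    y = matrix.label_array()
    preds = []
    for i in range(matrix.n_samples):
        rest = [j for j in range(matrix.n_samples) if j != i]
        fold = matrix.select_samples(rest)
        sel = AnovaTopN(n=min(n_features, fold.n_features)).fit(fold.values, fold.label_array())
        names = [fold.feature_names[j] for j in sel.selected_indices_]
        fold_sel = fold.select_features(names)
        fold_counts = [fold_sel.labels.count(c) for c in set(fold_sel.labels)]
        if smote is not None and len(fold_counts) == 2 and min(fold_counts) >= 2:
            fold_sel = smote_balance(
                fold_sel, SmoteConfig(k_neighbors=smote.k_neighbors, seed=smote.seed + i)
            )
        cfg = RfConfig(
            n_trees=rf_config.n_trees,
            max_features=rf_config.max_features,
            seed=rf_config.seed + i,
            max_depth=rf_config.max_depth,
            min_samples_leaf=rf_config.min_samples_leaf,
            criterion=rf_config.criterion,
        )
        model = train(fold_sel, cfg)
        preds.append(predict(model, matrix.select_samples([i]).select_features(names))[0])
    counts = ConfusionCounts.from_labels(y, preds)
    return compute_metrics(counts, protocol="jackknife")
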