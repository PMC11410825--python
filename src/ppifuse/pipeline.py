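"""End-to-end orchestration: features -> predictors -> fusion -> AISSO -> metrics.

The labeled pair list is split by learning percentage into a training set,
with the held-out remainder halved into validation and test (stratified by
label). All fitted artifacts -- the AC scaling statistics, the LCA cluster
index, the feature min-max normalization, both predictors, the MAPE fusion
weights and the AISSO-tuned weights -- are computed from the training and
validation splits only; test labels are touched exclusively by the final
metrics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from ppifuse.aisso import AissoConfig, AissoResult, ObjectiveSpec, optimize
from ppifuse.fusion import fuse_scores, fusion_weights, mape
from ppifuse.go_features import GoDag, LcaIndex, build_lca_index, go_feature_vector
from ppifuse.io_formats import AnnotationTable, PairList, ProteinRecord
from ppifuse.metrics import MetricsReport, classification_accuracy, regression_metrics, run_statistics
from ppifuse.neural import TrainConfig, dbn_forward, lstm_forward, train_dbn_predict, train_mrnn
from ppifuse.physchem import ACScaler, ScaleTable, ac_matrix, pair_feature
from ppifuse.semsim import cubic_map_weights, improved_semantic_similarity
from ppifuse.synthetic import SynthConfig, generate_pairs, generate_universe

log = logging.getLogger(__name__)

VALID_LEARNING_PERCENTAGES = (60, 70, 80, 90)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    learning_percentage: int = 60
    validation_fraction: float = 0.5  # of the held-out remainder
    gap_max: int = 2
    rho: float = 2.59
    e0: float = 0.7
    symmetric_denominator: bool = False
    invert_fusion: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)
    aisso: AissoConfig = field(default_factory=AissoConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        if self.learning_percentage not in VALID_LEARNING_PERCENTAGES:
            raise ValueError(
                f"learning percentage must be one of {VALID_LEARNING_PERCENTAGES}"
            )
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation fraction must be in (0, 1)")


def split_pairs(
    pairs: PairList, learning_percentage: int, validation_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (by label) train/validation/test index split.

    The training set holds ``learning_percentage`` percent of each label
    stratum; the remainder is split ``validation_fraction`` /
    (1 - validation_fraction) into validation and test.
    """
    labels = np.asarray(pairs.labels())
    train, val, test = [], [], []
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(learning_percentage / 100.0 * idx.size))
        n_val = int(round(validation_fraction * (idx.size - n_train)))
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    out = tuple(np.sort(np.concatenate(part)) for part in (train, val, test))
    if any(part.size == 0 for part in out):
        raise ValueError("empty split; increase the pair count or adjust the percentages")
    return out


class _MinMax01:
    """Column min-max normalization to [0, 1] fitted on training rows (held-out clipped)."""

    def fit(self, x: np.ndarray) -> "_MinMax01":
        self.min_ = x.min(axis=0)
        span = x.max(axis=0) - self.min_
        self.span_ = np.where(span == 0, 1.0, span)
        self.degenerate_ = span == 0
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        out = (x - self.min_) / self.span_
        out[:, self.degenerate_] = 0.0
        return np.clip(out, 0.0, 1.0)


@dataclass
class FeatureArtifacts:
    """Everything fitted while building features (train split only)."""

    scale_table: ScaleTable
    ac_scaler: ACScaler
    lca_index: LcaIndex
    minmax: _MinMax01
    namespace_weights: dict[str, np.ndarray]
    feature_matrix: np.ndarray  # (n_pairs, d), rows aligned with the pair list


def build_features(
    proteins: list[ProteinRecord],
    dag: GoDag,
    annotations: AnnotationTable,
    pairs: PairList,
    train_idx: np.ndarray,
    config: RunConfig,
    scale_table: ScaleTable | None = None,
) -> FeatureArtifacts:
    """Assemble per-pair vectors: scaled AC pair block, GO cluster block, semantic scalars."""
    scale_table = scale_table or ScaleTable.bundled()
    by_id = {p.id: p for p in proteins}
    ordered_ids = sorted(by_id)
    raw_ac = ac_matrix([by_id[i] for i in ordered_ids], scale_table, config.gap_max)
    train_pairs = [pairs[i] for i in train_idx]
    train_proteins = sorted({p.u for p in train_pairs} | {p.v for p in train_pairs})
    scaler = ACScaler().fit(raw_ac[[ordered_ids.index(i) for i in train_proteins]])
    scaled_ac = {pid: vec for pid, vec in zip(ordered_ids, scaler.transform(raw_ac))}

    index = build_lca_index(dag, train_pairs, annotations)
    ns_weights = {
        ns: cubic_map_weights(config.rho, config.e0, max(1, len(index.clusters_in(ns))))
        for ns in dag.namespaces
    }
    protein_go = {
        pid: go_feature_vector(index, dag, annotations.terms_for(pid), ())
        for pid in ordered_ids
    }

    rows = []
    for pair in pairs:
        gu = annotations.terms_for(pair.u)
        gv = annotations.terms_for(pair.v)
        go_block = go_feature_vector(index, dag, gu, gv)
        sem = []
        for ns in dag.namespaces:
            cols = index.clusters_in(ns)
            if not cols:
                sem.append(0.0)
                continue
            sem.append(
                improved_semantic_similarity(
                    protein_go[pair.u][cols],
                    protein_go[pair.v][cols],
                    ns_weights[ns][: len(cols)],
                    symmetric_denominator=config.symmetric_denominator,
                )
            )
        rows.append(
            np.concatenate([pair_feature(scaled_ac[pair.u], scaled_ac[pair.v]), go_block, sem])
        )
    matrix = np.vstack(rows)
    minmax = _MinMax01().fit(matrix[train_idx])
    return FeatureArtifacts(
        scale_table=scale_table,
        ac_scaler=scaler,
        lca_index=index,
        minmax=minmax,
        namespace_weights=ns_weights,
        feature_matrix=minmax.transform(matrix),
    )


@dataclass
class PipelineResult:
    accuracy: float
    metrics: MetricsReport
    mape_mrnn: float
    mape_dbn: float
    mape_weights: tuple[float, float]
    optimized_weights: tuple[float, float]
    aisso: AissoResult
    test_scores: dict[str, np.ndarray]
    val_scores: dict[str, np.ndarray]
    val_labels: np.ndarray
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    artifacts: FeatureArtifacts = field(repr=False, default=None)

    def summary(self) -> dict:
        """A JSON-serializable summary of the run (used for determinism checks)."""
        return {
            "accuracy": self.accuracy,
            **self.metrics.as_dict(),
            "mape_mrnn": self.mape_mrnn,
            "mape_dbn": self.mape_dbn,
            "mape_weights": list(self.mape_weights),
            "optimized_weights": list(self.optimized_weights),
            "aisso_best_value": self.aisso.best_value,
            "aisso_trace": self.aisso.trace.tolist(),
            "fused_test_scores": self.test_scores["fused"].tolist(),
        }


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(
    config: RunConfig,
    data: tuple[list[ProteinRecord], GoDag, AnnotationTable, PairList] | None = None,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> PipelineResult:
    """Execute the full prediction pipeline and report test-split metrics.

    ``splits`` overrides the internal stratified split with precomputed
    (train, validation, test) index arrays.
    """
    split_seed, rnn_seed, dbn_seed, aisso_seed, synth_seed = _derived_seeds(config.seed, 5)
    if data is None:
        synth = dataclasses.replace(config.synth, seed=synth_seed)
        log.info("generating synthetic universe (seed %d)", synth.seed)
        universe = generate_universe(synth)
        proteins, dag, annotations = universe.proteins, universe.dag, universe.annotations
        pairs = generate_pairs(universe, synth)
    else:
        proteins, dag, annotations, pairs = data

    if splits is not None:
        train_idx, val_idx, test_idx = splits
    else:
        train_idx, val_idx, test_idx = split_pairs(
            pairs, config.learning_percentage, config.validation_fraction,
            np.random.default_rng(split_seed),
        )
    log.info(
        "split %d pairs into %d train / %d validation / %d test",
        len(pairs), train_idx.size, val_idx.size, test_idx.size,
    )

    artifacts = build_features(proteins, dag, annotations, pairs, train_idx, config)
    x = artifacts.feature_matrix
    y = np.asarray(pairs.labels(), dtype=float)

    log.info("training mRNN on %d pairs (%d features)", train_idx.size, x.shape[1])
    mrnn_cfg = dataclasses.replace(config.train, seed=rnn_seed)
    mrnn_params, mrnn_trace = train_mrnn(x[train_idx], y[train_idx], mrnn_cfg)
    log.info("mRNN loss %.4f -> %.4f", mrnn_trace[0], mrnn_trace[-1])

    log.info("training DBN")
    dbn_cfg = dataclasses.replace(config.train, seed=dbn_seed)
    dbn_model, _ = train_dbn_predict(x[train_idx], y[train_idx], dbn_cfg)
    log.info("DBN loss %.4f -> %.4f", dbn_model.finetune_trace[0], dbn_model.finetune_trace[-1])

    s1_val = lstm_forward(mrnn_params, x[val_idx])
    s2_val = dbn_forward(dbn_model, x[val_idx])
    mape1 = mape(y[val_idx], s1_val)
    mape2 = mape(y[val_idx], s2_val)
    w1, w2 = fusion_weights(mape1, mape2, invert=config.invert_fusion)
    log.info("validation MAPE mRNN %.2f / DBN %.2f -> weights (%.3f, %.3f)", mape1, mape2, w1, w2)

    y_val = y[val_idx]

    def objective(w: np.ndarray) -> float:
        wn = _normalize_weights(w)
        fused = fuse_scores(s1_val, s2_val, wn[0], wn[1])
        return float(np.mean((y_val - fused) ** 2))

    aisso_cfg = dataclasses.replace(config.aisso, seed=aisso_seed, n_dim=2)
    result = optimize(ObjectiveSpec(objective), aisso_cfg, seed_solution=np.array([w1, w2]))
    wopt = _normalize_weights(result.best_position)
    log.info("AISSO best validation MSE %.5f at weights (%.3f, %.3f)", result.best_value, *wopt)

    s1_test = lstm_forward(mrnn_params, x[test_idx])
    s2_test = dbn_forward(dbn_model, x[test_idx])
    fused_test = fuse_scores(s1_test, s2_test, wopt[0], wopt[1])
    report = regression_metrics(y[test_idx], fused_test)
    accuracy = classification_accuracy(y[test_idx].astype(int), fused_test)
    log.info("test accuracy %.3f, MAE %.4f, RMSE %.4f", accuracy, report.mae, report.rmse)

    return PipelineResult(
        accuracy=accuracy,
        metrics=report,
        mape_mrnn=mape1,
        mape_dbn=mape2,
        mape_weights=(w1, w2),
        optimized_weights=(float(wopt[0]), float(wopt[1])),
        aisso=result,
        test_scores={"mrnn": s1_test, "dbn": s2_test, "fused": fused_test},
        val_scores={"mrnn": s1_val, "dbn": s2_val},
        val_labels=y_val,
        splits=(train_idx, val_idx, test_idx),
        artifacts=artifacts,
    )


def _normalize_weights(w: np.ndarray) -> np.ndarray:
    w = np.clip(np.asarray(w, dtype=float), 0.0, None)
    total = w.sum()
    if total == 0:
        return np.full_like(w, 1.0 / w.size)
    return w / total


def repeat_aisso_statistics(config: RunConfig, n_runs: int, data=None):
    """Repeat the AISSO stage with distinct seeds and summarize the final MSEs.

    The feature extraction and both predictors are trained once; only the
    optimizer is re-run against the recorded validation objective. Returns
    ``(RunStatistics, values)``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base = run_pipeline(config, data)
    s1_val, s2_val = base.val_scores["mrnn"], base.val_scores["dbn"]
    y_val = base.val_labels

    def objective(w: np.ndarray) -> float:
        wn = _normalize_weights(w)
        fused = fuse_scores(s1_val, s2_val, wn[0], wn[1])
        return float(np.mean((y_val - fused) ** 2))

    values = []
    for run_seed in _derived_seeds(config.seed, 5 + n_runs)[5:]:
        cfg = dataclasses.replace(config.aisso, seed=run_seed, n_dim=2)
        result = optimize(ObjectiveSpec(objective), cfg, seed_solution=np.array(base.mape_weights))
        values.append(result.best_value)
    return run_statistics(values), values
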