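"""Connection-weight feature attribution and top-k feature reduction.

A trained network's weights are mined for a global, per-model measure of how
much each input feature influences the output.  The output neuron is assigned
importance 1; importance is then propagated backward layer by layer,

    S_i = sum over j in N_i of |w_ij| * S_j,

where N_i are the neurons of the next layer (closer to the output) that
neuron i feeds into.  Biases are excluded.  Reaching the input layer yields
one non-negative score per feature.  Scores rank features; per-mark scores
sum each mark's 20 spatial features; the top-k reduced-model loop retrains
the network on the k highest-ranked features and tracks the validation rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import NetworkParams, TrainConfig, predict

MAX_ORACLE_PATHS = 100_000


@dataclass
class ImportanceScores:
    """Per-layer neuron importances; layer 0 is the input layer (= per-feature)."""

    per_layer: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.per_layer[-1].shape != (1,) or self.per_layer[-1][0] != 1.0:
            raise ValueError("output-layer importance must be exactly [1.0]")
        for s in self.per_layer:
            if np.any(s < 0):
                raise ValueError("importance scores must be non-negative")

    @property
    def per_feature(self) -> np.ndarray:
        return self.per_layer[0]


@dataclass
class OrderedFeatureList:
    """Feature indices in descending importance order (ties: ascending index)."""

    ranking: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.ranking.size != self.scores.size:
            raise ValueError("ranking and scores must align")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing along the ranking")

    def top_k(self, k: int) -> np.ndarray:
        if not (1 <= k <= self.ranking.size):
            raise ValueError(f"k must be in [1, {self.ranking.size}], got {k}")
        return self.ranking[:k]

    def to_dataframe(self, column_map: Sequence[tuple[str, int]] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "rank": np.arange(self.ranking.size),
            "feature": self.ranking,
            "score": self.scores,
        })
        if column_map is not None:
            df["mark"] = [column_map[i][0] for i in self.ranking]
            df["offset"] = [column_map[i][1] for i in self.ranking]
        return df


def importance_scores(params: NetworkParams) -> ImportanceScores:
    """Back-propagate absolute connection weights from the output neuron."""
    per_layer: list[np.ndarray] = [np.ones(1)]
    s = per_layer[0]
    for W in reversed(params.weights):
        s = np.abs(W) @ s
        per_layer.append(s)
    per_layer.reverse()
    return ImportanceScores(per_layer)


def path_product_oracle(params: NetworkParams) -> np.ndarray:
    """Independent per-feature scores: sum over all input->output paths of prod|w|.

    Brute-force path enumeration; refuses networks with more than
    ``MAX_ORACLE_PATHS`` paths.  Test-grade reference only.
    """
    n_paths = int(np.prod([s for s in params.layer_sizes[1:-1]])) or 1
    if n_paths * params.layer_sizes[0] > MAX_ORACLE_PATHS:
        raise ValueError("network too large for path enumeration")

    def paths_from(layer: int, neuron: int) -> float:
        if layer == len(params.layer_sizes) - 1:
            return 1.0
        W = params.weights[layer]
        return sum(
            abs(W[neuron, j]) * paths_from(layer + 1, j)
            for j in range(W.shape[1])
        )

    return np.array([paths_from(0, i) for i in range(params.layer_sizes[0])])


def rank_features(scores: ImportanceScores | np.ndarray) -> OrderedFeatureList:
    """Stable descending sort of per-feature scores; ties broken by feature index."""
    per_feature = scores.per_feature if isinstance(scores, ImportanceScores) else np.asarray(scores)
    order = np.argsort(-per_feature, kind="stable")
    return OrderedFeatureList(ranking=order, scores=per_feature[order])


def aggregate_by_mark(
    per_feature: np.ndarray,
    column_map: Sequence[tuple[str, int]],
) -> pd.Series:
    """Per-mark importance: the sum of each mark's spatial feature scores.

    Returned in first-appearance mark order.
    """
    per_feature = np.asarray(per_feature)
    if per_feature.size != len(column_map):
        raise ValueError("column_map must cover all features")
    marks = [m for m, _ in column_map]
    return pd.Series(per_feature).groupby(marks, sort=False).sum().rename("importance")


def mean_importance_over_seeds(
    train_fn: Callable[[int], NetworkParams],
    seeds: Sequence[int],
) -> np.ndarray:
    """Optional multi-restart mean of per-feature scores (rankings are seed-sensitive)."""
    scores = [importance_scores(train_fn(s)).per_feature for s in seeds]
    return np.mean(scores, axis=0)


def reduce_features(dataset, ol: OrderedFeatureList, k: int):
    """Keep the top-k ranked feature columns (original column order); labels unchanged.

    Returns (reduced LabeledDataset, retained column_map).
    """
    from .datasets import LabeledDataset  # deferred to avoid import cycle

    keep = np.sort(ol.top_k(k))
    fm = dataset.features.select_columns(keep)
    reduced = LabeledDataset(features=fm, labels=dataset.labels.copy(),
                             provenance=dataset.provenance.copy())
    return reduced, fm.column_map


def top_k_sweep(
    dataset,
    ol: OrderedFeatureList,
    k_values: Sequence[int],
    train_config: TrainConfig,
    eval_inputs,
    n_restarts: int = 1,
) -> pd.DataFrame:
    """Retrain on the top-k features for each k and record the validation rate.

    The hidden architecture of the full model (from ``train_config``) is
    reused for every reduced model.  ``eval_inputs`` is an
    ``evaluation.EvaluationInputs`` bundle of candidate locations, their full
    feature matrix (on the same scale as the training features), and the
    true-positive-marker set; evaluation picks the threshold that yields the
    bundle's target prediction count so rates are comparable across k.
    ``n_restarts`` trains that many independently initialized reduced models
    per k and keeps the one with the lowest final training error (restarts
    occasionally collapse to a dead constant output; training error alone
    identifies them).  Every (k, restart) seed derives from
    ``train_config.seed``, so the sweep is fully reproducible.
    """
    from dataclasses import replace
    from .evaluation import evaluate_at_count
    from .network import train_best

    rows = []
    for k in k_values:
        keep = np.sort(ol.top_k(k))
        cfg = replace(train_config,
                      seed=int((train_config.seed * 100003 + 31 * k) % 2**31))
        params, losses = train_best(dataset.features.X[:, keep], dataset.labels,
                                    cfg, n_restarts=n_restarts)
        scores = predict(params, eval_inputs.features.X[:, keep])
        result, threshold = evaluate_at_count(
            scores, eval_inputs.features.locations, eval_inputs.tpm,
            eval_inputs.n_predictions, radius=eval_inputs.radius,
            bin_width=eval_inputs.bin_width,
        )
        rows.append({
            "k": int(k),
            "threshold": threshold,
            "n_predictions": result.n_predictions,
            "n_validated": result.n_validated,
            "validation_rate": result.rate,
            "final_train_mse": losses[-1],
        })
    return pd.DataFrame(rows)


def export_feature_table(
    ol: OrderedFeatureList,
    column_map: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write the ordered feature list as TSV (feature, mark, offset, score, rank)."""
    ol.to_dataframe(column_map).to_csv(path, sep="\t", index=False)
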