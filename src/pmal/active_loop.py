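"""Uncertainty-driven label acquisition: score, select, reveal, retrain.

The loop treats each endpoint as its own annotation problem sharing one
molecule pool.  A round scores every unlabeled molecule of every endpoint
with the fused uncertainty, queries the top 10% (by default) of each
endpoint's current pool, reveals those labels, advances the round counter
and retrains the multitask model from scratch.  Pool updates are purely
set-theoretic: labeled gains the query set, unlabeled loses it, nothing is
ever created or destroyed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import EndpointDataset, scaffold_split
from .evaluation import r2, rmse
from .model import ModelConfig, PMALModel, train_model
from .uncertainty import score_pool

logger = logging.getLogger(__name__)

__all__ = ["ALState", "compute_budget", "rank_and_select", "update_pools",
           "run_experiment"]


@dataclass
class ALState:
    """Bookkeeping of the acquisition loop for one endpoint.

    Invariants (checked by :meth:`validate`): labeled and unlabeled are
    disjoint, and their union never changes across rounds.
    """

    labeled: list
    unlabeled: list
    round: int = 0
    history: list[tuple[int, int, tuple]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()
        self._universe = frozenset(self.labeled) | frozenset(self.unlabeled)

    def validate(self) -> None:
        overlap = set(self.labeled) & set(self.unlabeled)
        if overlap:
            raise ValueError(f"ids in both pools: {sorted(overlap)[:5]}")
        if hasattr(self, "_universe"):
            if (frozenset(self.labeled) | frozenset(self.unlabeled)) != self._universe:
                raise ValueError("pool union changed: ids were created or lost")


def compute_budget(pool_size: int, fraction: float = 0.10) -> int:
    """Per-round query budget: ceil(fraction * pool), capped at the pool."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if pool_size < 0:
        raise ValueError("pool_size must be nonnegative")
    return min(math.ceil(fraction * pool_size), pool_size)


def rank_and_select(scores: np.ndarray, ids: list, B: int) -> list:
    """Ids of the B highest-scoring pool members, ties broken by ascending
    id so selection is deterministic.  NaN scores are rejected by name."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(ids):
        raise ValueError("scores and ids must be aligned")
    bad = np.flatnonzero(np.isnan(scores))
    if bad.size:
        raise ValueError(f"NaN score for molecule {ids[bad[0]]!r}")
    if B <= 0:
        return []
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [ids[i] for i in order[:B]]


def update_pools(state: ALState, query_ids: list, task_id: int = 0) -> ALState:
    """Move the query set from unlabeled to labeled and advance the round.

    Querying an id that is not in the unlabeled pool is a double-labeling
    bug and raises.
    """
    unlabeled = set(state.unlabeled)
    stray = [q for q in query_ids if q not in unlabeled]
    if stray:
        raise ValueError(f"query ids not in the unlabeled pool: {stray[:5]}")
    new = ALState(
        labeled=list(state.labeled) + list(query_ids),
        unlabeled=[u for u in state.unlabeled if u not in set(query_ids)],
        round=state.round + 1,
        history=list(state.history) + [(state.round, task_id, tuple(query_ids))],
    )
    new._universe = state._universe
    new.validate()
    return new


def _evaluate_split(model: PMALModel, dataset: EndpointDataset,
                    test_idx: np.ndarray) -> list[dict]:
    rows = []
    for task in model.tasks:
        k = task.task_id
        labeled_test = test_idx[dataset.label_mask[test_idx, k]]
        if labeled_test.size < 2:
            continue
        graphs = [dataset.graphs[i] for i in labeled_test]
        y_true = dataset.labels[labeled_test, k]
        y_pred = model.predict_point(graphs, k)
        row = {"task": task.name, "task_id": k, "n_test": int(labeled_test.size),
               "rmse": rmse(y_true, y_pred)}
        row["r2"] = r2(y_true, y_pred) if np.ptp(y_true) > 0 else np.nan
        rows.append(row)
    return rows


def run_experiment(
    dataset: EndpointDataset,
    config: ModelConfig,
    strategy: str = "pmal",
    rounds: int = 3,
    init_fraction: float = 0.10,
    query_fraction: float = 0.10,
    seeds: tuple[int, ...] = (0, 1, 2),
    split_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the acquisition protocol on a fully labeled dataset.

    The dataset is scaffold-split 8:1:1 once; each seed then starts from a
    random ``init_fraction`` of every endpoint's training labels, runs
    ``rounds`` query rounds of ``query_fraction`` of the current unlabeled
    pool each, retraining from scratch every round, and evaluates RMSE/R^2
    on the held-out test split after every (re)training.  Queried labels
    are revealed from the dataset (a simulated annotation oracle).

    ``strategy="pmal"`` ranks by the fused uncertainty score;
    ``strategy="random"`` draws uniformly without replacement with the
    same budgets.  Returns the learning curve (one row per seed, round and
    task) and the query log (one row per queried molecule).
    """
    if strategy not in ("pmal", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    train_idx, _, test_idx = scaffold_split(dataset, seed=split_seed)
    records = []
    query_rows = []
    for seed in seeds:
        rng = np.random.default_rng((seed, 0xA11))
        # per-task pools over molecules with a train-split label
        states: dict[int, ALState] = {}
        for task in dataset.tasks:
            k = task.task_id
            candidates = [int(i) for i in train_idx if dataset.label_mask[i, k]]
            n_init = compute_budget(len(candidates), init_fraction)
            init = rng.choice(len(candidates), size=n_init, replace=False)
            init_set = {candidates[i] for i in init}
            states[k] = ALState(
                labeled=sorted(init_set),
                unlabeled=sorted(set(candidates) - init_set),
            )

        for t in range(rounds + 1):
            visible = np.zeros_like(dataset.label_mask)
            for k, st in states.items():
                visible[np.array(st.labeled, dtype=int), k] = True
            cfg_t = ModelConfig(**{**config.to_dict(),
                                   "seed": int((seed * 1000 + t) % 2**31)})
            model, _ = train_model(dataset, cfg_t, labeled_mask=visible)
            for row in _evaluate_split(model, dataset, test_idx):
                records.append({"seed": seed, "round": t,
                                "strategy": strategy,
                                "n_labeled": len(states[row["task_id"]].labeled),
                                **row})
            if t == rounds:
                break
            for task in dataset.tasks:
                k = task.task_id
                st = states[k]
                if not st.unlabeled:
                    logger.info("task %s: pool exhausted at round %d", task.name, t)
                    continue
                B = compute_budget(len(st.unlabeled), query_fraction)
                if strategy == "pmal":
                    graphs = [dataset.graphs[i] for i in st.unlabeled]
                    scores = score_pool(model, graphs, k, seed=seed)
                    query = rank_and_select(scores, st.unlabeled, B)
                else:
                    pick = rng.choice(len(st.unlabeled), size=B, replace=False)
                    query = [st.unlabeled[i] for i in pick]
                states[k] = update_pools(st, query, k)
                states[k].validate()
                query_rows.extend(
                    {"seed": seed, "round": t, "task": task.name,
                     "molecule_id": dataset.molecule_ids[q]} for q in query)
    curve = pd.DataFrame.from_records(records)
    queries = pd.DataFrame(
        query_rows, columns=["seed", "round", "task", "molecule_id"])
    return curve, queries
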