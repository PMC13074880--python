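"""Aleatoric/epistemic uncertainty decomposition and the query score.

For a regression mixture the predictive variance splits exactly (law of
total variance) into

* aleatoric  ``U_al = sum_c pi_c sigma2_c``   — within-component noise,
  the irreducible assay-variability part, and
* epistemic  ``U_ep = sum_c pi_c ||mu_c - sum_c pi_c mu_c||^2`` — spread
  of component means around the mixture mean, the reducible
  model-disagreement part.

For classification both parts are estimated by Monte Carlo: sample a
component from the mixture weights, draw the stochastic-softmax
probability, and decompose the entropy of the resulting sequence.  The
annotation-utility score fuses the two parts as
``U = alpha * U_ep + (1 - alpha) * U_al``; higher U means a more
informative candidate for labeling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

from .chem_io import MolecularGraph, TaskType
from .model import MixtureParams, PMALModel

__all__ = [
    "UncertaintyEstimate",
    "aleatoric_regression",
    "epistemic_regression",
    "classification_mc_uncertainty",
    "query_score",
    "score_pool",
]


@dataclass(frozen=True)
class UncertaintyEstimate:
    """Per-sample decomposition: aleatoric, epistemic, their fused score,
    and (classification only) the total predictive entropy."""

    aleatoric: float
    epistemic: float
    total: float | None = None
    score: float | None = None
    alpha: float | None = None

    def __post_init__(self):
        # epistemic is total - aleatoric for MC estimates; allow float dust
        if self.aleatoric < 0 or self.epistemic < -1e-9:
            raise ValueError("uncertainty components must be nonnegative")


def aleatoric_regression(params: MixtureParams) -> float:
    """Mixture-weighted average of component variances."""
    if params.means.ndim != 1:
        raise ValueError("expected regression mixture parameters")
    return float(np.sum(params.weights * params.variances))


def epistemic_regression(params: MixtureParams) -> float:
    """Mixture-weighted squared spread of component means around the
    mixture mean; zero iff all positively-weighted means coincide."""
    if params.means.ndim != 1:
        raise ValueError("expected regression mixture parameters")
    overall = np.sum(params.weights * params.means)
    return float(np.sum(params.weights * (params.means - overall) ** 2))


def _entropy(p: np.ndarray) -> np.ndarray:
    """Categorical entropy in nats along the last axis, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=-1)


def classification_mc_uncertainty(
    params: MixtureParams,
    T: int = 20,
    seed: int | np.random.Generator = 0,
    noise: str = "variance",
) -> UncertaintyEstimate:
    """Monte-Carlo entropy decomposition for a classification mixture.

    Each of the T draws samples a component from the mixture weights and a
    standard-normal noise vector, forms ``softmax(mu_c + sigma2_c * gamma)``
    and records the class probabilities p_t.  Then

    * ``U_al   = mean_t H(p_t)``      (expected entropy),
    * ``U_total = H(mean_t p_t)``      (entropy of the mean),
    * ``U_ep   = U_total - U_al``      (nonnegative by concavity of H).
    """
    if T < 1:
        raise ValueError(f"need at least one MC draw, got T={T}")
    if params.means.ndim != 2:
        raise ValueError("expected classification mixture parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    components = rng.choice(params.n_components, size=T, p=params.weights)
    gamma = rng.standard_normal((T, params.means.shape[1]))
    mu = params.means[components]
    var = params.variances[components]
    scale = var if noise == "variance" else np.sqrt(var)
    p = _softmax(mu + scale * gamma, axis=1)  # (T, n_classes)
    u_al = float(_entropy(p).mean())
    p_bar = p.mean(axis=0)
    u_total = float(_entropy(p_bar))
    u_ep = u_total - u_al
    return UncertaintyEstimate(aleatoric=u_al, epistemic=u_ep, total=u_total)


def query_score(u_ep: float, u_al: float, alpha: float = 0.75) -> float:
    """Annotation utility ``alpha * U_ep + (1 - alpha) * U_al``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return float(alpha * u_ep + (1.0 - alpha) * u_al)


def _molecule_rng(seed: int, molecule_id: str) -> np.random.Generator:
    """Order-independent per-molecule stream: the same molecule gets the
    same draws wherever it sits in the pool."""
    digest = hashlib.blake2s(molecule_id.encode(), digest_size=4).digest()
    return np.random.default_rng((seed, int.from_bytes(digest, "big") % (2**31)))


def score_pool(
    model: PMALModel,
    graphs: list[MolecularGraph],
    task_id: int,
    alpha: float | None = None,
    T: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Annotation-utility score for every molecule in an unlabeled pool.

    Regression endpoints are fully deterministic; classification endpoints
    use per-molecule seeded MC draws so scores do not depend on pool order.
    """
    alpha = model.config.alpha if alpha is None else alpha
    T = model.config.mc_samples if T is None else T
    if not graphs:
        return np.zeros(0)
    task = model.tasks[task_id]
    params_list = model.predict_mixture(graphs, task_id)
    scores = np.empty(len(graphs))
    for i, (graph, params) in enumerate(zip(graphs, params_list)):
        if task.task_type == TaskType.REGRESSION:
            u_al = aleatoric_regression(params)
            u_ep = epistemic_regression(params)
        else:
            est = classification_mc_uncertainty(
                params, T=T, seed=_molecule_rng(seed, graph.smiles),
                noise=model.config.classification_noise)
            u_al, u_ep = est.aleatoric, est.epistemic
        scores[i] = query_score(u_ep, u_al, alpha)
    return scores


def uncertainty_table(model: PMALModel, graphs: list[MolecularGraph],
                      task_id: int, alpha: float | None = None,
                      T: int | None = None, seed: int = 0):
    """Audit table: one row per molecule with u_al, u_ep and the fused
    score, as a pandas DataFrame."""
    import pandas as pd

    alpha = model.config.alpha if alpha is None else alpha
    task = model.tasks[task_id]
    rows = []
    params_list = model.predict_mixture(graphs, task_id) if graphs else []
    for graph, params in zip(graphs, params_list):
        if task.task_type == TaskType.REGRESSION:
            u_al = aleatoric_regression(params)
            u_ep = epistemic_regression(params)
        else:
            est = classification_mc_uncertainty(
                params, T=T or model.config.mc_samples,
                seed=_molecule_rng(seed, graph.smiles))
            u_al, u_ep = est.aleatoric, est.epistemic
        rows.append({"molecule_id": graph.smiles, "task_id": task_id,
                     "u_al": u_al, "u_ep": u_ep,
                     "u_score": query_score(u_ep, u_al, alpha)})
    return pd.DataFrame(rows, columns=["molecule_id", "task_id", "u_al", "u_ep", "u_score"])
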