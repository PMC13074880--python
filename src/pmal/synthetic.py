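"""Synthetic molecule pools with known multi-endpoint ground truth.

The generator emulates the structure of a multi-species acute-toxicity
collection: one shared molecule pool, many endpoints with highly
imbalanced label counts, continuous labels on the -log10(mol/kg) scale,
and heteroscedastic measurement noise.  Molecules are built
combinatorially from ring cores, linkers and substituents so the pool
spans many Bemis-Murcko scaffolds (exercising scaffold splits), and
labels are smooth functions of cheap molecular descriptors,

    y_k(x) = rho * g(d(x)) + (1 - rho) * h_k(d(x)) + eps,
    eps ~ N(0, s^2(x)),

with g a shared surface, h_k endpoint-specific, and the noise standard
deviation s(x) growing with molecule size.  Because g, h_k and s are known
exactly, every downstream stage (mean recovery, aleatoric-variance
ranking, acquisition efficiency) can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import EndpointDataset, TaskSpec, load_endpoint_table, smiles_to_graph
from .model import ModelConfig

__all__ = ["SyntheticSpec", "generate_molecules", "generate_labels",
           "make_benchmark", "write_benchmark_csv"]

# ring cores with two substitution slots ({a} prefix, {x} in-ring branch)
_CORES = (
    "{a}c1ccc({x})cc1",       # benzene
    "{a}c1ccc({x})nc1",       # pyridine
    "{a}c1ccc({x})o1",        # furan
    "{a}c1ccc({x})s1",        # thiophene
    "{a}c1ccc({x})[nH]1",     # pyrrole
    "{a}C1CCC({x})CC1",       # cyclohexane
    "{a}C1CCC({x})C1",        # cyclopentane
)
# second rings (ring-closure index 2) appended behind a linker
_SECOND_RINGS = (
    "c2ccc({b})cc2",
    "c2ccc({b})nc2",
    "c2ccc({b})o2",
    "c2ccc({b})s2",
    "C2CCC({b})CC2",
    "C2CCC({b})C2",
)
_LINKERS = ("", "C", "CC", "CCC", "O", "CO", "OC", "CC(=O)")
_SUBSTITUENTS = ("", "C", "CC", "CCC", "CCCC", "O", "OC", "N", "NC",
                 "Cl", "F", "Br", "C(C)C", "CO", "C#N", "C(=O)O", "C(=O)C")


@dataclass
class SyntheticSpec:
    """Conditions of one synthetic study."""

    n_molecules: int = 300
    n_tasks: int = 2
    label_fractions: tuple[float, ...] = (1.0, 0.2)
    task_correlation: float = 0.5
    noise_sd_range: tuple[float, float] = (0.2, 0.6)
    base_level: float = 2.5
    seed: int = 0
    noise_seed: int | None = None  # defaults to seed; lets replicates share surfaces

    def __post_init__(self):
        if len(self.label_fractions) != self.n_tasks:
            raise ValueError("need one label fraction per task")
        if not all(0.0 < f <= 1.0 for f in self.label_fractions):
            raise ValueError("label fractions must lie in (0, 1]")
        if not 0.0 <= self.task_correlation <= 1.0:
            raise ValueError("task correlation must lie in [0, 1]")


def _scaffold_recipes() -> list[tuple[str, bool]]:
    """All (template, has_b_slot) recipes: single rings plus linked pairs."""
    recipes = [(core, False) for core in _CORES]
    for core in _CORES:
        for linker in _LINKERS:
            for second in _SECOND_RINGS:
                recipes.append((core.replace("{x}", linker + second), True))
    return recipes


def generate_molecules(n: int, seed: int = 0) -> list[str]:
    """``n`` unique, canonical, parseable SMILES spanning many scaffolds.

    Scaffold recipes are visited round-robin in a seeded shuffle and
    decorated with random substituents, so the pool covers at least
    ~min(n, hundreds) of distinct Bemis-Murcko scaffolds.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    recipes = _scaffold_recipes()
    order = rng.permutation(len(recipes))
    smiles: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(smiles) < n and attempts < 200 * n:
        attempts += 1
        template, has_b = recipes[order[attempts % len(recipes)]]
        a = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        if has_b:
            b = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            cand = template.format(a=a, b=b).replace("()", "")
        else:
            # in-ring branch slot must not be empty
            cand = template.format(a=a, x=_SUBSTITUENTS[rng.integers(1, len(_SUBSTITUENTS))])
        mol = Chem.MolFromSmiles(cand)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        smiles.append(canonical)
    if len(smiles) < n:
        raise RuntimeError(f"could only generate {len(smiles)} of {n} molecules")
    return smiles


def _descriptors(smiles: str) -> np.ndarray:
    """Cheap deterministic descriptor vector driving the label surfaces."""
    mol = Chem.MolFromSmiles(smiles)
    atoms = list(mol.GetAtoms())
    n_heavy = len(atoms)
    n_rings = mol.GetRingInfo().NumRings()
    counts = {"N": 0, "O": 0, "S": 0}
    n_halogen = n_arom = n_branch = 0
    for at in atoms:
        sym = at.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        if sym in ("F", "Cl", "Br", "I"):
            n_halogen += 1
        n_arom += at.GetIsAromatic()
        n_branch += at.GetDegree() >= 3
    return np.array([
        n_heavy / 20.0,
        n_rings / 3.0,
        (counts["N"] + counts["O"] + counts["S"] + n_halogen) / max(n_heavy, 1),
        n_arom / max(n_heavy, 1),
        counts["N"] / 4.0,
        counts["O"] / 4.0,
        n_halogen / 4.0,
        n_branch / 5.0,
    ])


@dataclass
class GroundTruth:
    """Noise-free label surfaces and the noise variance of each molecule."""

    f: np.ndarray            # (n, K) noiseless endpoint values
    noise_sd: np.ndarray     # (n,) s(x)
    descriptors: np.ndarray  # (n, d)

    @property
    def noise_var(self) -> np.ndarray:
        return self.noise_sd**2

    def rmse_floor(self) -> float:
        """Irreducible test RMSE of a perfect mean predictor."""
        return float(np.sqrt(np.mean(self.noise_sd**2)))


def _smooth_surface(D: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random smooth bounded function of the descriptors.

    A random shallow tanh expansion with moderately high input frequency:
    rich enough that fitting it needs substantially more labels than the
    initial annotation budget provides, so acquisition order matters.
    """
    w1 = rng.normal(0.0, 3.0, size=(D.shape[1], 8))
    b1 = rng.normal(0.0, 1.0, size=8)
    w2 = rng.normal(0.0, 0.6, size=8)
    return np.tanh(D @ w1 + b1) @ w2


def generate_labels(
    molecules: list[str], spec: SyntheticSpec
) -> tuple[EndpointDataset, GroundTruth]:
    """Multi-endpoint labels with known truth for a molecule list.

    Endpoint surfaces mix a shared and an endpoint-specific smooth
    function of the descriptors with weight ``task_correlation``; noise is
    Gaussian with a standard deviation that interpolates linearly in
    heavy-atom count between the configured bounds.  Label masks retain
    exactly round(fraction * n) molecules per endpoint.
    """
    rng = np.random.default_rng(spec.seed)
    noise_rng = np.random.default_rng(
        (spec.seed if spec.noise_seed is None else spec.noise_seed, 0xE0))
    D = np.stack([_descriptors(s) for s in molecules])
    n = len(molecules)
    rho = spec.task_correlation

    shared = _smooth_surface(D, rng)
    f = np.empty((n, spec.n_tasks))
    for k in range(spec.n_tasks):
        f[:, k] = spec.base_level + rho * shared + (1.0 - rho) * _smooth_surface(D, rng)

    size = D[:, 0]
    lo, hi = size.min(), size.max()
    rel = (size - lo) / (hi - lo) if hi > lo else np.zeros(n)
    s_lo, s_hi = spec.noise_sd_range
    noise_sd = s_lo + (s_hi - s_lo) * rel

    labels = f + noise_rng.normal(size=(n, spec.n_tasks)) * noise_sd[:, None]
    mask = np.zeros((n, spec.n_tasks), dtype=bool)
    for k, frac in enumerate(spec.label_fractions):
        keep = rng.choice(n, size=int(round(frac * n)), replace=False)
        mask[keep, k] = True

    graphs = [smiles_to_graph(s) for s in molecules]
    tasks = [TaskSpec(k, f"endpoint_{k}") for k in range(spec.n_tasks)]
    dataset = EndpointDataset(
        molecule_ids=list(molecules), graphs=graphs,
        labels=np.where(mask, labels, np.nan), label_mask=mask, tasks=tasks,
    )
    return dataset, GroundTruth(f=f, noise_sd=noise_sd, descriptors=D)


_PRESETS = {
    "small": dict(n_molecules=300, n_tasks=2, label_fractions=(1.0, 0.2)),
    "medium": dict(n_molecules=2000, n_tasks=5,
                   label_fractions=(1.0, 0.6, 0.3, 0.15, 0.08)),
}

_PRESET_CONFIGS = {
    "small": dict(n_tasks=2, n_layers=2, hidden_dim=64, epochs=30),
    "medium": dict(n_tasks=5),  # protocol defaults: L=3, 128-dim, 50 epochs
}


def make_benchmark(preset: str = "small", seed: int = 0
                   ) -> tuple[EndpointDataset, GroundTruth, ModelConfig]:
    """A ready-to-run benchmark: dataset, ground truth and a model config.

    ``small`` (300 molecules, 2 endpoints) is sized for unit tests;
    ``medium`` (2000 molecules, 5 imbalanced endpoints) is sized for
    acquisition-efficiency studies on one CPU.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    spec = SyntheticSpec(seed=seed, **_PRESETS[preset])
    molecules = generate_molecules(spec.n_molecules, seed=seed)
    dataset, truth = generate_labels(molecules, spec)
    config = ModelConfig(seed=seed, **_PRESET_CONFIGS[preset])
    return dataset, truth, config


def write_benchmark_csv(dataset: EndpointDataset, truth: GroundTruth,
                        out_dir: str | Path) -> tuple[Path, Path]:
    """Write the dataset in the CSV dialect ``load_endpoint_table`` reads,
    with the ground truth alongside as ``truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [t.name for t in dataset.tasks]
    frame = pd.DataFrame(dataset.labels, columns=names)
    frame.insert(0, "smiles", dataset.molecule_ids)
    data_path = out_dir / "data.csv"
    frame.to_csv(data_path, index=False)

    truth_frame = pd.DataFrame(truth.f, columns=[f"f_{n}" for n in names])
    truth_frame.insert(0, "smiles", dataset.molecule_ids)
    truth_frame["noise_sd"] = truth.noise_sd
    truth_path = out_dir / "truth.csv"
    truth_frame.to_csv(truth_path, index=False)
    return data_path, truth_path
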