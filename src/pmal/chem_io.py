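"""Molecule I/O: SMILES parsing, atom featurization, dose transforms, scaffold splits.

Molecules are handled as undirected heavy-atom graphs (hydrogens implicit).
Each atom carries a 96-dimensional feature vector laid out as four one-hot
blocks plus a flag:

======================  =====  ==========================================
block                   width  encoding
======================  =====  ==========================================
element                 44     43 named elements + final "other" slot
heavy-atom degree       17     0..16, values above 16 clamp to the last slot
implicit hydrogen count 17     0..16, clamped
total valence           17     0..16, clamped
aromaticity             1      binary flag
======================  =====  ==========================================

Dose labels are stored as -log10(dose in mol/kg), so larger values mean a
smaller toxic dose, i.e. a more toxic compound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Elements covered by the one-hot block, chosen to span organic chemistry,
#: halogens and the metals common in toxicology screening sets.  Anything
#: else maps to the trailing "other" slot, so exotic elements never crash
#: the featurizer.
ELEMENT_VOCABULARY: tuple[str, ...] = (
    "H", "B", "C", "N", "O", "F", "Na", "Mg", "Al", "Si",
    "P", "S", "Cl", "K", "Ca", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Zr",
    "Mo", "Pd", "Ag", "Cd", "Sn", "Sb", "Te", "I", "Ba", "Pt",
    "Au", "Hg", "Pb",
)

N_ELEMENT_SLOTS = 44  # 43 named + 1 "other"
N_COUNT_SLOTS = 17    # degree / implicit H / valence, each 0..16 clamped
FEATURE_DIM = N_ELEMENT_SLOTS + 3 * N_COUNT_SLOTS + 1  # = 96

_ELEMENT_INDEX = {symbol: i for i, symbol in enumerate(ELEMENT_VOCABULARY)}


class TaskType(str, Enum):
    REGRESSION = "regression"
    CLASSIFICATION = "classification"


@dataclass(frozen=True)
class TaskSpec:
    """One prediction endpoint: a (species, route, metric) combination."""

    task_id: int
    name: str
    task_type: TaskType = TaskType.REGRESSION


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph with featurized nodes.

    ``edges`` stores each bond once as an (i, j) pair with i < j; consumers
    that need a symmetric adjacency add the reversed pairs themselves.
    """

    smiles: str
    node_features: np.ndarray  # (n_atoms, 96)
    edges: list[tuple[int, int]]
    n_atoms: int

    def validate(self) -> None:
        if self.node_features.shape != (self.n_atoms, FEATURE_DIM):
            raise ValueError(
                f"node feature matrix has shape {self.node_features.shape}, "
                f"expected ({self.n_atoms}, {FEATURE_DIM})"
            )
        seen = set()
        for i, j in self.edges:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"edge ({i}, {j}) out of range for {self.n_atoms} atoms")
            if i == j:
                raise ValueError(f"self-edge on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)


@dataclass
class EndpointDataset:
    """A molecule pool with per-endpoint labels and missingness masks.

    ``labels`` is (n_molecules, K) in -log10(mol/kg); entries where
    ``label_mask`` is False are meaningless placeholders (NaN).  Column
    label counts may differ wildly: endpoints are imbalanced by nature.
    """

    molecule_ids: list[str]
    graphs: list[MolecularGraph]
    labels: np.ndarray
    label_mask: np.ndarray
    tasks: list[TaskSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, k = self.labels.shape
        if len(self.molecule_ids) != n or len(self.graphs) != n:
            raise ValueError("molecule_ids, graphs and labels are inconsistent")
        if self.label_mask.shape != (n, k):
            raise ValueError("label_mask shape must match labels")
        if not np.all(np.isfinite(self.labels[self.label_mask])):
            raise ValueError("labels must be finite wherever the mask is set")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def subset(self, indices: np.ndarray | list[int]) -> "EndpointDataset":
        idx = np.asarray(indices, dtype=int)
        return EndpointDataset(
            molecule_ids=[self.molecule_ids[i] for i in idx],
            graphs=[self.graphs[i] for i in idx],
            labels=self.labels[idx],
            label_mask=self.label_mask[idx],
            tasks=self.tasks,
        )


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"could not parse SMILES: {smiles!r}")
        self.smiles = smiles


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def featurize_atom(
    symbol: str,
    degree: int,
    implicit_h: int,
    valence: int,
    aromatic: bool,
) -> np.ndarray:
    """Encode one atom as the 96-dimensional block vector.

    Unknown element symbols land in the final "other" slot of the element
    block; degree / hydrogen / valence counts above 16 clamp to the last
    slot of their blocks.  Negative counts are invalid.
    """
    if min(degree, implicit_h, valence) < 0:
        raise ValueError(
            f"atom counts must be nonnegative, got degree={degree}, "
            f"implicit_h={implicit_h}, valence={valence}"
        )
    element_idx = _ELEMENT_INDEX.get(symbol, N_ELEMENT_SLOTS - 1)
    clamp = N_COUNT_SLOTS - 1
    return np.concatenate(
        [
            _one_hot(element_idx, N_ELEMENT_SLOTS),
            _one_hot(min(degree, clamp), N_COUNT_SLOTS),
            _one_hot(min(implicit_h, clamp), N_COUNT_SLOTS),
            _one_hot(min(valence, clamp), N_COUNT_SLOTS),
            np.array([1.0 if aromatic else 0.0]),
        ]
    )


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    The SMILES is canonicalized, so two encodings of the same molecule
    yield identical graphs.  Raises :class:`SmilesParseError` on invalid
    input and on molecules with no heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    features = np.stack(
        [
            featurize_atom(
                atom.GetSymbol(),
                atom.GetDegree(),
                atom.GetNumImplicitHs(),
                atom.GetTotalValence(),
                atom.GetIsAromatic(),
            )
            for atom in mol.GetAtoms()
        ]
    )
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
    graph = MolecularGraph(
        smiles=canonical,
        node_features=features,
        edges=sorted(edges),
        n_atoms=mol.GetNumAtoms(),
    )
    graph.validate()
    return graph


def transform_dose(value: float | np.ndarray, direction: str = "forward", base: float = 10.0):
    """Convert between dose in mol/kg and the negative-log scale.

    ``forward`` maps dose -> -log10(dose); ``inverse`` maps back.  On the
    transformed scale higher values mean greater toxicity.
    """
    arr = np.asarray(value, dtype=float)
    if direction == "forward":
        if np.any(arr <= 0):
            raise ValueError("dose must be strictly positive")
        out = -np.log(arr) / np.log(base)
    elif direction == "inverse":
        out = np.power(base, -arr)
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    return out.item() if np.isscalar(value) or arr.ndim == 0 else out


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES (empty string for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def scaffold_split(
    dataset: EndpointDataset,
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split molecule indices into train/validation/test by Murcko scaffold.

    Scaffold groups are atomic: no scaffold spans two sets, enforcing
    structural independence between splits.  Groups are sorted by
    descending size (seeded shuffle breaks exact ties) and each group goes
    to the set currently furthest below its target fraction, so set sizes
    track the requested ratios as closely as whole groups allow.
    """
    if dataset.n_molecules == 0:
        raise ValueError("cannot split an empty dataset")
    weights = np.asarray(ratios, dtype=float)
    if weights.shape != (3,) or np.any(weights < 0) or weights.sum() == 0:
        raise ValueError(f"ratios must be three nonnegative weights, got {ratios}")
    fractions = weights / weights.sum()

    groups: dict[str, list[int]] = {}
    for i, graph in enumerate(dataset.graphs):
        groups.setdefault(murcko_scaffold(graph.smiles), []).append(i)
    if len(groups) < 3:
        warnings.warn(
            f"only {len(groups)} scaffold group(s) for 3 sets; some splits will be empty",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    keys = list(groups)
    order = rng.permutation(len(keys))
    ranked = sorted(order, key=lambda j: (-len(groups[keys[j]]), j))

    n_total = dataset.n_molecules
    sets: list[list[int]] = [[], [], []]
    for j in ranked:
        members = groups[keys[j]]
        # assign to the set with the largest deficit w.r.t. its target size
        deficits = [fractions[s] * n_total - len(sets[s]) for s in range(3)]
        target = int(np.argmax(deficits))
        sets[target].extend(members)
    return tuple(np.array(sorted(s), dtype=int) for s in sets)


def load_endpoint_table(path, task_types: dict[str, TaskType] | None = None) -> EndpointDataset:
    """Read a molecule table (``smiles`` column + one numeric column per
    endpoint) into an :class:`EndpointDataset`.

    Empty cells mark missing labels.  Rows whose SMILES fails to parse are
    dropped with a logged count; a file where nothing parses yields an
    empty dataset and a warning.
    """
    frame = pd.read_csv(path)
    if "smiles" not in frame.columns:
        raise ValueError(f"{path}: expected a 'smiles' column, found {list(frame.columns)}")
    endpoint_cols = [c for c in frame.columns if c != "smiles"]
    if not endpoint_cols:
        raise ValueError(f"{path}: no endpoint columns found")

    task_types = task_types or {}
    tasks = [
        TaskSpec(task_id=k, name=name, task_type=task_types.get(name, TaskType.REGRESSION))
        for k, name in enumerate(endpoint_cols)
    ]

    ids, graphs, rows = [], [], []
    n_dropped = 0
    for _, row in frame.iterrows():
        try:
            graph = smiles_to_graph(str(row["smiles"]))
        except SmilesParseError:
            n_dropped += 1
            continue
        ids.append(graph.smiles)
        graphs.append(graph)
        rows.append([row[c] for c in endpoint_cols])
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with unparseable SMILES", path, n_dropped)
    if not graphs:
        warnings.warn(f"{path}: no parseable molecules", stacklevel=2)

    labels = np.asarray(rows, dtype=float).reshape(len(graphs), len(endpoint_cols))
    mask = np.isfinite(labels)
    labels = np.where(mask, labels, np.nan)
    return EndpointDataset(
        molecule_ids=ids, graphs=graphs, labels=labels, label_mask=mask, tasks=tasks
    )
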