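"""Molecular graphs, graph powers and normalized adjacency for the drug encoder.

A drug SMILES is parsed into a graph over heavy atoms: hydrogens stay
implicit and enter only through the per-atom hydrogen-count feature.
Each atom is described by five standard descriptors — one-hot element
symbol, one-hot heavy-atom degree, one-hot total hydrogen count, one-hot
implicit valence and an aromaticity flag — stacked into a fixed-width
binary feature vector, so every molecule shares one feature layout.

The encoder consumes the k-th graph powers of the adjacency (two atoms
adjacent in A^k iff their shortest-path distance is between 1 and k),
each degree-normalized as D^{-1/2} (A + I) D^{-1/2} after self-loop
augmentation.  The maximum exponent is fixed at 3: molecular graphs are
small and almost all chemically meaningful shortest paths are <= 3 bonds,
so higher powers add little beyond cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

MAX_POWER = 3

# Element vocabulary for the one-hot symbol feature.  Ordered, with a
# trailing "other" bucket, so the feature column layout is stable.
DEFAULT_ELEMENTS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca",
    "Fe", "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag",
    "Pd", "Co", "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni",
    "Cd", "In", "Mn", "Zr", "Cr", "Pt", "Hg", "Pb",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class AtomFeatureSpec:
    """Layout of the per-atom feature vector.

    The five descriptor groups are concatenated in a fixed order:
    element symbol one-hot (with an "other" bucket), heavy-atom degree
    one-hot over 0..max_degree, total hydrogen count one-hot over
    0..max_hydrogens, implicit valence one-hot over 0..max_valence, and
    a single aromaticity flag.
    """

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    max_degree: int = 10
    max_hydrogens: int = 10
    max_valence: int = 10

    @property
    def width(self) -> int:
        return (len(self.elements) + 1 + (self.max_degree + 1)
                + (self.max_hydrogens + 1) + (self.max_valence + 1) + 1)

    def featurize_atom(self, atom: Chem.Atom) -> np.ndarray:
        vec = np.zeros(self.width)
        offset = 0
        symbol = atom.GetSymbol()
        try:
            pos = self.elements.index(symbol)
        except ValueError:
            pos = len(self.elements)  # "other" bucket
        vec[offset + pos] = 1.0
        offset += len(self.elements) + 1

        degree = min(atom.GetDegree(), self.max_degree)
        vec[offset + degree] = 1.0
        offset += self.max_degree + 1

        n_h = min(atom.GetTotalNumHs(), self.max_hydrogens)
        vec[offset + n_h] = 1.0
        offset += self.max_hydrogens + 1

        valence = min(atom.GetImplicitValence(), self.max_valence)
        vec[offset + valence] = 1.0
        offset += self.max_valence + 1

        vec[offset] = float(atom.GetIsAromatic())
        return vec


DEFAULT_FEATURE_SPEC = AtomFeatureSpec()


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one drug molecule.

    adjacency is symmetric binary with zero diagonal; entry (u, v) is 1
    iff a covalent bond joins atoms u and v (aromatic bonds included as
    ordinary edges — bond order is not encoded).
    """

    smiles: str
    node_features: np.ndarray  # (N, C)
    adjacency: np.ndarray      # (N, N)

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class PowerGraphSet:
    """Normalized adjacency of the graph powers A, A^2, A^3 (self-loops on)."""

    a1_norm: np.ndarray
    a2_norm: np.ndarray
    a3_norm: np.ndarray

    def as_dict(self) -> dict[int, np.ndarray]:
        return {1: self.a1_norm, 2: self.a2_norm, 3: self.a3_norm}


def smiles_to_graph(smiles: str,
                    feature_spec: AtomFeatureSpec = DEFAULT_FEATURE_SPEC,
                    ) -> MolecularGraph:
    """Parse a SMILES string into a MolecularGraph over heavy atoms."""
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"molecule has no heavy atoms: {smiles!r}")

    features = np.stack([feature_spec.featurize_atom(a) for a in mol.GetAtoms()])
    adjacency = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = 1.0
        adjacency[j, i] = 1.0
    return MolecularGraph(smiles=smiles, node_features=features,
                          adjacency=adjacency)


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency diagonal must be zero")
    return adjacency


def graph_power(adjacency: np.ndarray, k: int) -> np.ndarray:
    """Adjacency of the k-th graph power: (u, v) adjacent iff their
    shortest-path distance in the input graph is at least 1 and at most k.

    Computed by boolean products of (A + I): connectivity only, never
    walk counts.  k = 1 returns the input unchanged.
    """
    adjacency = _check_adjacency(adjacency)
    if k not in (1, 2, 3):
        raise ValueError(f"power exponent must be in {{1, 2, 3}}, got {k}")
    if k == 1:
        return adjacency.copy()
    n = adjacency.shape[0]
    reach = (adjacency + np.eye(n)) > 0
    out = reach
    for _ in range(k - 1):
        out = (out.astype(float) @ reach.astype(float)) > 0
    power = out.astype(float)
    np.fill_diagonal(power, 0.0)
    return power


def normalize_adjacency(adjacency: np.ndarray,
                        add_self_loops: bool = True) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}.

    With add_self_loops on (the form the encoder uses), the identity is
    added first so each node keeps its own features in the propagation.
    Degree-0 rows (possible only with self-loops off) map to zero rather
    than dividing by zero.
    """
    adjacency = _check_adjacency(adjacency)
    a_hat = adjacency + np.eye(adjacency.shape[0]) if add_self_loops else adjacency
    degrees = a_hat.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(degrees > 0, degrees ** -0.5, 0.0)
    return d_inv_sqrt[:, None] * a_hat * d_inv_sqrt[None, :]


def build_power_graph_set(graph: MolecularGraph) -> PowerGraphSet:
    """Normalized adjacency (self-loops on) of A, A^2, A^3 for one molecule."""
    normed = [normalize_adjacency(graph_power(graph.adjacency, k),
                                  add_self_loops=True)
              for k in (1, 2, 3)]
    return PowerGraphSet(*normed)
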