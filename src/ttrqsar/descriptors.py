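"""Native computation of the seven modelling descriptors.

The classification model uses GATS3e, ATSC6p, GATS8m and MIC2; the regression
model uses piPC5, GGI9 and AATSC0e.  All seven are 2D (topological)
descriptors computed from the molecular graph:

* ATSC / AATSC — centered (and averaged) Broto-Moreau autocorrelations of an
  atomic property at a topological lag;
* GATS — Geary autocorrelation coefficients;
* MIC — mass-weighted (modified) information content over neighborhood-
  symmetry atom classes;
* piPC — natural-log conventional-bond-order path counts;
* GGI — Galvez topological charge indices.

Conventions follow the reference 2D descriptor software: autocorrelations and
information content are computed on the hydrogen-explicit graph with aromatic
bonds at order 1.5; path counts and topological charge indices use the
hydrogen-suppressed heavy-atom graph.  Atomic property weights (mass,
Sanderson electronegativity, atomic polarizability in Å^3) come from the
bundled element table below.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from rdkit import Chem

from .chem_io import SmilesParseError

logger = logging.getLogger("ttrqsar")

MODEL_DESCRIPTORS = ("GATS3e", "ATSC6p", "GATS8m", "MIC2", "piPC5", "GGI9", "AATSC0e")

# Element property table, version 1: (atomic mass, Sanderson
# electronegativity, atomic polarizability / Å^3).  Sanderson (not Pauling)
# electronegativities and unscaled polarizabilities are the 2D-autocorrelation
# weighting convention of the reference descriptor software; pinned for
# reproducibility of descriptor outputs.
ELEMENT_TABLE_VERSION = 1
ELEMENT_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "H": (1.008, 2.592, 0.667),
    "B": (10.811, 2.275, 3.030),
    "C": (12.011, 2.746, 1.760),
    "N": (14.007, 3.194, 1.100),
    "O": (15.999, 3.654, 0.802),
    "F": (18.998, 4.000, 0.557),
    "Si": (28.086, 2.138, 5.380),
    "P": (30.974, 2.515, 3.630),
    "S": (32.060, 2.957, 2.900),
    "Cl": (35.453, 3.475, 2.180),
    "Br": (79.904, 3.219, 3.050),
    "I": (126.904, 2.778, 5.350),
}

_PROP_INDEX = {"m": 0, "e": 1, "p": 2}


@dataclass
class MolecularGraph:
    """Hydrogen-explicit (or heavy-atom) molecular graph with property weights."""

    elements: list[str]
    bonds: list[tuple[int, int, float]]  # (i, j, conventional bond order)
    explicit_hydrogens: bool = True
    _dist: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def weights(self, prop: str) -> np.ndarray:
        """Atomic property vector; prop in {'m', 'e', 'p'}."""
        idx = _PROP_INDEX[prop]
        return np.array([ELEMENT_PROPERTIES[el][idx] for el in self.elements])

    def adjacency(self, bond_order_weighted: bool = False) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, order in self.bonds:
            a[i, j] = a[j, i] = order if bond_order_weighted else 1.0
        return a

    def distance_matrix(self) -> np.ndarray:
        """Topological (bond-count) distance matrix; np.inf between components."""
        if self._dist is None:
            self._dist = shortest_path(self.adjacency(), method="D", unweighted=True)
        return self._dist

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out


def build_graph(smiles: str, explicit_hydrogens: bool = True) -> MolecularGraph:
    """Build a :class:`MolecularGraph` from SMILES.

    Hydrogens are made explicit by default; aromatic bonds get conventional
    order 1.5.  With ``explicit_hydrogens=False`` the hydrogen-suppressed
    heavy-atom graph is returned.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if explicit_hydrogens:
        mol = Chem.AddHs(mol)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    for el in elements:
        if el not in ELEMENT_PROPERTIES:
            raise ValueError(f"no property data for element {el!r}")
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            order = 1.5
        else:
            order = float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(elements, bonds, explicit_hydrogens)


# ---------------------------------------------------------------------------
# Autocorrelation descriptors


def atsc(graph: MolecularGraph, lag: int, prop: str) -> float:
    """Centered Broto-Moreau autocorrelation at topological lag ``lag``.

    ATSC_d = sum over unordered atom pairs {i, j} at distance d of
    (w_i - w̄)(w_j - w̄); ATSC_0 = sum_i (w_i - w̄)^2.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    w = graph.weights(prop)
    if np.all(w == w[0]):  # homoatomic: centered weights vanish exactly
        return 0.0
    wc = w - w.mean()
    if lag == 0:
        return float(np.sum(wc**2))
    d = graph.distance_matrix()
    iu = np.triu_indices(graph.n_atoms, k=1)
    mask = d[iu] == lag
    return float(np.sum(wc[iu[0][mask]] * wc[iu[1][mask]]))


def _pair_count(graph: MolecularGraph, lag: int) -> int:
    """Number of unordered atom pairs at topological distance ``lag``."""
    d = graph.distance_matrix()
    iu = np.triu_indices(graph.n_atoms, k=1)
    return int(np.sum(d[iu] == lag))


def aatsc(graph: MolecularGraph, lag: int, prop: str) -> float:
    """Averaged centered autocorrelation: ATSC divided by the term count.

    AATSC_0 is the population variance of the atomic property; for d > 0 the
    divisor is the number of atom pairs at distance d (0 by convention when
    there is no such pair).
    """
    if lag == 0:
        return atsc(graph, 0, prop) / graph.n_atoms
    count = _pair_count(graph, lag)
    if count == 0:
        logger.debug("AATSC%d: no atom pair at lag %d; returning 0", lag, lag)
        return 0.0
    return atsc(graph, lag, prop) / count


def gats(
    graph: MolecularGraph, lag: int, prop: str, degenerate_value: float = 0.0
) -> float:
    """Geary autocorrelation coefficient at topological lag ``lag``.

    numerator = [sum over ordered pairs (i, j) at distance d of
    (w_i - w_j)^2] / (2 Δ_d), with Δ_d the ordered-pair count; denominator is
    the sample variance sum_i (w_i - w̄)^2 / (n - 1).  A homoatomic graph has
    zero denominator and returns ``degenerate_value`` (default 0, logged).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if graph.n_atoms < 2:
        raise ValueError("GATS needs at least 2 atoms")
    w = graph.weights(prop)
    denom = float(np.sum((w - w.mean()) ** 2)) / (graph.n_atoms - 1)
    if np.all(w == w[0]) or denom == 0.0:
        logger.debug("GATS%d: homoatomic graph, degenerate denominator", lag)
        return degenerate_value
    d = graph.distance_matrix()
    mask = d == lag  # ordered pairs (symmetric mask, diagonal never == lag>=1)
    delta = int(mask.sum())
    if delta == 0:
        return 0.0
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = float(diff2[mask].sum()) / (2 * delta)
    return num / denom


# ---------------------------------------------------------------------------
# Information content


def _symmetry_classes(graph: MolecularGraph, order: int) -> list[int]:
    """Partition atoms by iterated neighborhood symmetry.

    Radius-0 classes split by element; each refinement step appends the
    sorted multiset of (bond order, neighbor class) signatures, so after
    ``order`` iterations two atoms share a class iff their rooted
    neighborhoods of that radius match.
    """
    labels: list = list(graph.elements)
    for _ in range(order):
        new = []
        for i in range(graph.n_atoms):
            env = sorted((o, labels[j]) for j, o in graph.neighbors(i))
            new.append((labels[i], tuple(env)))
        labels = new
    canon: dict = {}
    out = []
    for lab in labels:
        if lab not in canon:
            canon[lab] = len(canon)
        out.append(canon[lab])
    return out


def mic(graph: MolecularGraph, order: int) -> float:
    """Modified (mass-weighted) information content of neighborhood symmetry.

    Atoms are partitioned into equivalence classes of the given symmetry
    order; the Shannon information content (bits) weights each atom's term by
    its atomic mass: MIC = -sum_g (M_g / M) * log2(n_g / n), with M_g and n_g
    the mass and atom count of class g.  A single-class partition gives 0.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    classes = _symmetry_classes(graph, order)
    masses = graph.weights("m")
    total_mass = float(masses.sum())
    n = graph.n_atoms
    value = 0.0
    for g in set(classes):
        members = [i for i, c in enumerate(classes) if c == g]
        mg = float(masses[members].sum())
        pg = len(members) / n
        value -= (mg / total_mass) * math.log2(pg)
    return value


# ---------------------------------------------------------------------------
# Path counts and topological charge


def _count_paths(graph: MolecularGraph, order: int) -> float:
    """Sum of bond-order products over all simple paths of ``order`` bonds.

    Exhaustive DFS; each undirected path is enumerated from both ends, so the
    ordered total is halved.
    """
    adj: list[list[tuple[int, float]]] = [[] for _ in range(graph.n_atoms)]
    for i, j, o in graph.bonds:
        adj[i].append((j, o))
        adj[j].append((i, o))
    total = 0.0

    def dfs(node: int, remaining: int, weight: float, visited: list[bool]):
        nonlocal total
        if remaining == 0:
            total += weight
            return
        for nxt, o in adj[node]:
            if not visited[nxt]:
                visited[nxt] = True
                dfs(nxt, remaining - 1, weight * o, visited)
                visited[nxt] = False

    for start in range(graph.n_atoms):
        visited = [False] * graph.n_atoms
        visited[start] = True
        dfs(start, order, 1.0, visited)
    return total / 2.0


def pipc(graph: MolecularGraph, order: int) -> float:
    """Conventional bond order ID number: ln(1 + weighted path count).

    Simple paths of exactly ``order`` bonds are enumerated on the graph; a
    path's weight is the product of the conventional bond orders along it.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return math.log1p(_count_paths(graph, order))


def ggi(graph: MolecularGraph, order: int, bond_order_weighted: bool = False) -> float:
    """Galvez topological charge index of the given order.

    M = A · D*, with A the adjacency matrix (binary, the original Galvez
    convention; optionally bond-order weighted) and D* the inverse-square
    topological distance matrix (off-diagonal 1/d^2, zero diagonal).  The
    charge term CT_ij = M_ij - M_ji; GGI_k sums |CT_ij| over unordered pairs
    at topological distance k.  Returns 0 when the graph diameter is below
    ``order``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    d = graph.distance_matrix()
    finite = np.where(np.isfinite(d) & (d > 0), d, np.inf)
    dstar = np.zeros_like(d)
    np.divide(1.0, finite**2, out=dstar, where=np.isfinite(finite))
    a = graph.adjacency(bond_order_weighted=bond_order_weighted)
    m = a @ dstar
    ct = m - m.T
    iu = np.triu_indices(graph.n_atoms, k=1)
    mask = d[iu] == order
    return float(np.sum(np.abs(ct[iu[0][mask], iu[1][mask]])))


# ---------------------------------------------------------------------------
# Model descriptor vector and matrix filtering


def compute_model_descriptors(smiles: str) -> dict[str, float]:
    """The seven model descriptors for one molecule, by name.

    Autocorrelations and MIC are computed on the hydrogen-explicit graph;
    piPC5 and GGI9 on the heavy-atom graph (reference-software convention).
    """
    g_h = build_graph(smiles, explicit_hydrogens=True)
    g_heavy = build_graph(smiles, explicit_hydrogens=False)
    values = {
        "GATS3e": gats(g_h, 3, "e"),
        "ATSC6p": atsc(g_h, 6, "p"),
        "GATS8m": gats(g_h, 8, "m"),
        "MIC2": mic(g_h, 2),
        "piPC5": pipc(g_heavy, 5),
        "GGI9": ggi(g_heavy, 9),
        "AATSC0e": aatsc(g_h, 0, "e"),
    }
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite descriptor {name} for {smiles!r}")
    return values


def descriptor_matrix(
    smiles_list: Sequence[str], ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Seven-column native descriptor matrix for a batch of molecules."""
    ids = list(ids) if ids is not None else [f"mol{i+1}" for i in range(len(smiles_list))]
    rows = [compute_model_descriptors(s) for s in smiles_list]
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=MODEL_DESCRIPTORS)


def filter_descriptors(
    matrix: pd.DataFrame,
    constancy_frac: float = 0.8,
    corr_max: float = 0.95,
    range_decades: float = 2.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Remove useless/redundant descriptor columns.

    Drops, in order: (a) near-constant columns whose modal value covers more
    than ``constancy_frac`` of the compounds; (b) columns whose absolute span
    (max - min) exceeds 10**range_decades; (c) from each pair with
    |Pearson r| > corr_max, the member later in alphabetical order.  Returns
    the filtered matrix and a removal log of (name, reason) pairs.
    """
    if matrix.isna().any().any():
        raise ValueError("descriptor matrix contains missing values")
    removed: list[tuple[str, str]] = []
    keep = list(matrix.columns)

    for name in list(keep):
        col = matrix[name]
        modal_frac = col.value_counts().iloc[0] / len(col)
        if modal_frac > constancy_frac:
            removed.append((name, "low_variance"))
            keep.remove(name)

    for name in list(keep):
        col = matrix[name]
        if (col.max() - col.min()) > 10.0**range_decades:
            removed.append((name, "wide_range"))
            keep.remove(name)

    ordered = sorted(keep)
    if len(ordered) > 1:
        corr = matrix[ordered].corr().abs()
        dropped: set[str] = set()
        for i, a in enumerate(ordered):
            if a in dropped:
                continue
            for b in ordered[i + 1 :]:
                if b in dropped:
                    continue
                if corr.loc[a, b] > corr_max:
                    dropped.add(b)
                    removed.append((b, "correlation"))
        keep = [c for c in keep if c not in dropped]

    if not keep:
        logger.warning("descriptor filtering removed every column")
    return matrix[keep], removed
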