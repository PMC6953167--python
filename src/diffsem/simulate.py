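"""Synthetic paired-GRN generator with full ground truth.

Produces two structurally similar gene regulatory networks (condition 1 and
condition 2), cis-eQTL perturbation effects, F2-cross genotypes and noisy
expression data satisfying the SEM  Y = Y B + X F + E  exactly.  The second
network is derived from the first by rewiring a small fraction of edges and
re-drawing the weights of a matching number of shared edges, so that the
differential network dB = B(1) - B(2) is sparse and fully known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "GRNAdjacency",
    "GRNWeights",
    "EQTLMap",
    "PairedDataset",
    "GroundTruth",
    "generate_adjacency",
    "perturb_adjacency",
    "weights_from_adjacency",
    "derive_condition2_weights",
    "simulate_genotypes",
    "build_eqtl_effects",
    "simulate_expression",
    "simulate_paired_dataset",
]

#: reject (I - B) whose condition number exceeds this and re-draw weights
MAX_CONDITION_NUMBER = 1e8


@dataclass
class GRNAdjacency:
    """Binary directed-network topology.

    ``entries[i, j] = 1`` means gene ``i`` regulates gene ``j``.  For a DAG
    the node permutation ``order`` (generation order, edges always point
    from earlier to later positions) is retained so that later edge
    rewiring can stay acyclic.
    """

    entries: np.ndarray
    kind: str  # "dag" or "dcg"
    order: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.entries.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.entries.sum())

    def is_acyclic(self) -> bool:
        g = nx.from_numpy_array(self.entries, create_using=nx.DiGraph)
        return nx.is_directed_acyclic_graph(g)


@dataclass
class GRNWeights:
    """Real regulatory-effect matrix sharing the support of an adjacency.

    Every nonzero effect has magnitude in (0.5, 1); the diagonal is zero
    (genes do not regulate themselves).
    """

    entries: np.ndarray
    adjacency: GRNAdjacency

    @property
    def p(self) -> int:
        return self.entries.shape[0]


@dataclass
class EQTLMap:
    """cis-eQTL effect matrix F (q x p) and per-gene support sets.

    Each eQTL (row) perturbs exactly one gene; each gene (column) is
    perturbed by at least one eQTL, which makes directed edges identifiable
    even in cyclic networks.  ``supports[i]`` lists the eQTL row indices
    feeding gene ``i``.
    """

    effects: np.ndarray
    supports: list[np.ndarray]

    @property
    def q(self) -> int:
        return self.effects.shape[0]

    @property
    def p(self) -> int:
        return self.effects.shape[1]


@dataclass
class PairedDataset:
    """Expression and genotype matrices for the two conditions.

    Both conditions observe the same genes and eQTLs on equally sized,
    independent cohorts (samples as rows).  Genotypes are coded {1, 2, 3}.
    """

    Y1: np.ndarray
    Y2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    supports: list[np.ndarray]
    gene_labels: list[str] = field(default_factory=list)
    eqtl_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.Y1.shape[0] != self.Y2.shape[0]:
            raise ValueError(
                "paired sample size: both conditions must have the same "
                f"number of samples (got {self.Y1.shape[0]} and {self.Y2.shape[0]})"
            )
        if not self.gene_labels:
            self.gene_labels = [f"G{i + 1}" for i in range(self.p)]
        if not self.eqtl_labels:
            self.eqtl_labels = [f"E{k + 1}" for k in range(self.q)]

    @property
    def n(self) -> int:
        return self.Y1.shape[0]

    @property
    def p(self) -> int:
        return self.Y1.shape[1]

    @property
    def q(self) -> int:
        return self.X1.shape[1]


@dataclass
class GroundTruth:
    """Everything the simulator knows: true weights, eQTL map, noise level,
    and the exact differential support (entries where B(1) != B(2))."""

    B1: GRNWeights
    B2: GRNWeights
    F: EQTLMap
    delta_support: set[tuple[int, int]]
    sigma2: float
    reweighted: list[tuple[int, int]] = field(default_factory=list)
    removed: list[tuple[int, int]] = field(default_factory=list)
    added: list[tuple[int, int]] = field(default_factory=list)

    @property
    def delta(self) -> np.ndarray:
        return self.B1.entries - self.B2.entries


def _dag_candidate_cells(order: np.ndarray) -> np.ndarray:
    """All (i, j) cells consistent with a topological order (edge i -> j
    allowed iff i precedes j)."""
    p = len(order)
    pos = np.empty(p, dtype=int)
    pos[order] = np.arange(p)
    cells = [
        (i, j)
        for i in range(p)
        for j in range(p)
        if i != j and pos[i] < pos[j]
    ]
    return np.asarray(cells, dtype=int)


def generate_adjacency(
    p: int, n_e: float, kind: str, rng: np.random.Generator
) -> GRNAdjacency:
    """Generate a random directed network with ``n_e * p`` edges.

    DAG mode draws a uniform node permutation and places the edges
    uniformly among the cells of the induced strict upper triangle, which
    guarantees acyclicity.  DCG mode places edges uniformly among all
    off-diagonal cells and redraws until at least one directed cycle is
    present.

    Parameters
    ----------
    p : number of genes (>= 2)
    n_e : average number of edges per node
    kind : "dag" or "dcg"
    rng : seeded numpy Generator
    """
    kind = kind.lower()
    if kind not in ("dag", "dcg"):
        raise ValueError(f"kind must be 'dag' or 'dcg', got {kind!r}")
    if p < 2:
        raise ValueError("p must be >= 2")
    if n_e < 1:
        raise ValueError("n_e must be >= 1")
    n_edges = int(round(n_e * p))
    if n_edges > p * (p - 1):
        raise ValueError(
            f"requested {n_edges} edges but only {p * (p - 1)} off-diagonal "
            "cells exist"
        )
    if kind == "dag":
        max_dag = p * (p - 1) // 2
        n_edges = min(n_edges, max_dag)
        order = rng.permutation(p)
        cells = _dag_candidate_cells(order)
        chosen = cells[rng.choice(len(cells), size=n_edges, replace=False)]
        A = np.zeros((p, p), dtype=np.int8)
        A[chosen[:, 0], chosen[:, 1]] = 1
        return GRNAdjacency(entries=A, kind="dag", order=order)

    off_diag = np.asarray(
        [(i, j) for i in range(p) for j in range(p) if i != j], dtype=int
    )
    for _ in range(1000):
        chosen = off_diag[rng.choice(len(off_diag), size=n_edges, replace=False)]
        A = np.zeros((p, p), dtype=np.int8)
        A[chosen[:, 0], chosen[:, 1]] = 1
        adj = GRNAdjacency(entries=A, kind="dcg")
        if not adj.is_acyclic():
            return adj
    raise RuntimeError(
        "could not generate a cyclic topology; increase n_e or p"
    )


def _perturbation_size(n_nonzero: int, change_fraction: float) -> int:
    """Number of cells to flip: the change fraction of the edge count,
    rounded to the nearest even integer with a floor of 2 so that deletions
    and additions can be balanced."""
    if change_fraction == 0:
        return 0
    return max(2, 2 * int(round(change_fraction * n_nonzero / 2)))


def perturb_adjacency(
    A1: GRNAdjacency, change_fraction: float, rng: np.random.Generator
) -> tuple[GRNAdjacency, list[tuple[int, int]], list[tuple[int, int]]]:
    """Rewire a small fraction of the network, preserving the edge count.

    ``n_d`` cells change state, half 1->0 (deletions) and half 0->1
    (additions).  In DAG mode additions are only placed at cells consistent
    with the original topological order, so the result stays acyclic.

    Returns the perturbed adjacency plus the deleted and added cell lists.
    """
    nnz = A1.n_edges
    if change_fraction > 0 and nnz < 2:
        raise ValueError("need at least 2 edges to perturb")
    n_d = _perturbation_size(nnz, change_fraction)
    A2 = A1.entries.copy()
    if n_d == 0:
        return GRNAdjacency(A2, A1.kind, A1.order), [], []
    n_c = n_d // 2

    edges = np.argwhere(A1.entries == 1)
    del_idx = rng.choice(len(edges), size=n_c, replace=False)
    removed = [tuple(e) for e in edges[del_idx]]

    if A1.kind == "dag":
        if A1.order is None:
            order = np.asarray(
                list(
                    nx.topological_sort(
                        nx.from_numpy_array(A1.entries, create_using=nx.DiGraph)
                    )
                )
            )
        else:
            order = A1.order
        candidates = _dag_candidate_cells(order)
    else:
        p = A1.p
        candidates = np.asarray(
            [(i, j) for i in range(p) for j in range(p) if i != j], dtype=int
        )
    free = candidates[A1.entries[candidates[:, 0], candidates[:, 1]] == 0]
    if len(free) < n_c:
        raise ValueError(
            f"cannot add {n_c} edges: only {len(free)} legal empty cells"
        )
    add_idx = rng.choice(len(free), size=n_c, replace=False)
    added = [tuple(c) for c in free[add_idx]]

    for i, j in removed:
        A2[i, j] = 0
    for i, j in added:
        A2[i, j] = 1
    return GRNAdjacency(A2, A1.kind, A1.order), removed, added


def _draw_weights(size: int, rng: np.random.Generator) -> np.ndarray:
    """Effects with magnitude Uniform(0.5, 1) and random sign, i.e. draws
    from the uniform distribution on (-1, -0.5) U (0.5, 1)."""
    mag = rng.uniform(0.5, 1.0, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return sign * mag


def weights_from_adjacency(
    A: GRNAdjacency, rng: np.random.Generator
) -> GRNWeights:
    """Assign each edge an independent weight drawn uniformly from
    (-1, -0.5) U (0.5, 1); non-edges stay exactly zero."""
    B = np.zeros(A.entries.shape, dtype=float)
    idx = np.argwhere(A.entries == 1)
    if len(idx):
        B[idx[:, 0], idx[:, 1]] = _draw_weights(len(idx), rng)
    return GRNWeights(entries=B, adjacency=A)


def derive_condition2_weights(
    A2: GRNAdjacency,
    B1: GRNWeights,
    n_c: int,
    rng: np.random.Generator,
) -> tuple[GRNWeights, list[tuple[int, int]]]:
    """Build the condition-2 weights from the rewired topology.

    Cells absent from ``A2`` are zero; newly added edges get fresh draws;
    among the edges shared with condition 1, ``n_c`` randomly selected
    entries are re-drawn (producing weight-only differential edges) and all
    the rest copy condition 1 exactly.

    Returns the weights and the list of re-weighted shared cells.
    """
    shared = np.argwhere((A2.entries == 1) & (B1.entries != 0))
    if n_c > len(shared):
        raise ValueError(
            f"n_c={n_c} exceeds the number of shared edges ({len(shared)})"
        )
    B2 = np.where(A2.entries == 1, B1.entries, 0.0)
    new_edges = np.argwhere((A2.entries == 1) & (B1.entries == 0))
    if len(new_edges):
        B2[new_edges[:, 0], new_edges[:, 1]] = _draw_weights(len(new_edges), rng)
    reweighted: list[tuple[int, int]] = []
    if n_c > 0:
        sel = rng.choice(len(shared), size=n_c, replace=False)
        cells = shared[sel]
        B2[cells[:, 0], cells[:, 1]] = _draw_weights(n_c, rng)
        reweighted = [tuple(c) for c in cells]
    return GRNWeights(entries=B2, adjacency=A2), reweighted


def simulate_genotypes(n: int, q: int, rng: np.random.Generator) -> np.ndarray:
    """F2-cross genotypes: i.i.d. draws from {1, 2, 3} with probabilities
    (0.25, 0.5, 0.25) — the 1:2:1 segregation of a biallelic locus."""
    if n < 1 or q < 1:
        raise ValueError("n and q must be >= 1")
    return rng.choice([1, 2, 3], size=(n, q), p=[0.25, 0.5, 0.25]).astype(float)


def build_eqtl_effects(p: int, rng: np.random.Generator) -> EQTLMap:
    """Two unit-effect cis-eQTLs per gene.

    F (2p x p) is a random row permutation of two stacked p-dimensional
    identity matrices: every eQTL feeds exactly one gene and every gene has
    exactly two eQTLs.  The same map is used for both conditions.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    stacked = np.vstack([np.eye(p), np.eye(p)])
    perm = rng.permutation(2 * p)
    F = stacked[perm]
    supports = [np.flatnonzero(F[:, i]) for i in range(p)]
    return EQTLMap(effects=F, supports=supports)


def simulate_expression(
    B: GRNWeights,
    F: EQTLMap,
    X: np.ndarray,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Solve the SEM for expression:  Y = (X F + E) (I - B)^-1.

    E is i.i.d. Normal(0, sigma2).  With sigma2 = 0 the identity
    Y = Y B + X F holds to machine precision.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    p = B.p
    IminusB = np.eye(p) - B.entries
    if np.linalg.cond(IminusB) > MAX_CONDITION_NUMBER:
        raise np.linalg.LinAlgError(
            "(I - B) is numerically singular; re-draw the network weights"
        )
    E = rng.normal(0.0, np.sqrt(sigma2), size=(X.shape[0], p))
    # Y (I - B) = X F + E  =>  solve the transposed system
    return np.linalg.solve(IminusB.T, (X @ F.effects + E).T).T


def simulate_paired_dataset(
    p: int,
    n: int,
    n_e: float,
    sigma2: float,
    kind: str = "dag",
    change_fraction: float = 0.10,
    rng: np.random.Generator | None = None,
) -> tuple[PairedDataset, GroundTruth]:
    """Full paired-study simulation with ground truth.

    Draws the condition-1 topology and weights, rewires ~``change_fraction``
    of the edges and re-draws as many shared-edge weights to get condition
    2, builds the two-eQTLs-per-gene perturbation map, simulates
    independent genotype cohorts for the two conditions and solves each SEM
    for expression.  Weight draws whose (I - B) is ill-conditioned are
    rejected and re-drawn.
    """
    if rng is None:
        rng = np.random.default_rng()
    A1 = generate_adjacency(p, n_e, kind, rng)
    A2, removed, added = perturb_adjacency(A1, change_fraction, rng)
    n_c = len(removed)
    for _ in range(100):
        B1 = weights_from_adjacency(A1, rng)
        B2, reweighted = derive_condition2_weights(A2, B1, n_c, rng)
        conds = [
            np.linalg.cond(np.eye(p) - B.entries) for B in (B1, B2)
        ]
        if max(conds) <= MAX_CONDITION_NUMBER:
            break
    else:
        raise RuntimeError("could not draw well-conditioned network weights")
    F = build_eqtl_effects(p, rng)
    q = F.q
    X1 = simulate_genotypes(n, q, rng)
    X2 = simulate_genotypes(n, q, rng)
    Y1 = simulate_expression(B1, F, X1, sigma2, rng)
    Y2 = simulate_expression(B2, F, X2, sigma2, rng)
    data = PairedDataset(Y1=Y1, Y2=Y2, X1=X1, X2=X2, supports=F.supports)
    diff = np.argwhere(B1.entries != B2.entries)
    truth = GroundTruth(
        B1=B1,
        B2=B2,
        F=F,
        delta_support={tuple(c) for c in diff},
        sigma2=sigma2,
        reweighted=reweighted,
        removed=removed,
        added=added,
    )
    return data, truth
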