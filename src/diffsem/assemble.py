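"""From posterior means to sparse networks and the differential GRN.

The shrinkage prior does not produce exact zeros, so point estimates are
sparsified with a preset threshold t (entries with |value| > t are kept,
default t = 0.2).  The differential network is the entrywise difference of
the two thresholded networks.  For noisy real cohorts, two extra filters
are provided: a relative-magnitude significance criterion for differential
edges and a bootstrap stability rule (edges detected in more than
``keep_count`` of ``n_boot`` resamples are retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from diffsem.simulate import PairedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "threshold_network",
    "differential_network",
    "significant_differential",
    "bootstrap_stability",
    "assemble_result",
    "edges_to_frame",
]

DEFAULT_THRESHOLD = 0.2


@dataclass
class DifferentialResult:
    """Thresholded networks for both conditions and their difference."""

    B1_sparse: np.ndarray
    B2_sparse: np.ndarray
    delta: np.ndarray
    edges1: set[tuple[int, int]]
    edges2: set[tuple[int, int]]
    delta_edges: set[tuple[int, int]]
    significant_delta: set[tuple[int, int]]
    threshold: float
    bootstrap_freq: dict[tuple[int, int], int] = field(default_factory=dict)


def threshold_network(Bhat: np.ndarray, t: float) -> np.ndarray:
    """Keep entries with |value| strictly greater than ``t`` verbatim and
    zero out everything else."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    Bhat = np.asarray(Bhat, dtype=float)
    return np.where(np.abs(Bhat) > t, Bhat, 0.0)


def _support(B: np.ndarray) -> set[tuple[int, int]]:
    return {tuple(c) for c in np.argwhere(B != 0)}


def differential_network(
    B1_sparse: np.ndarray, B2_sparse: np.ndarray, t: float = 0.0
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Entrywise difference of the two thresholded networks, itself
    sparsified at ``t``, and the set of its nonzero cells.

    Sampling noise leaves a small nonzero difference at every edge the two
    conditions share, so the difference matrix needs the same |value| > t
    selection as the individual networks to have a meaningful support;
    ``t=0`` keeps the raw difference.
    """
    if B1_sparse.shape != B2_sparse.shape:
        raise ValueError(
            f"shape mismatch: {B1_sparse.shape} vs {B2_sparse.shape}"
        )
    delta = threshold_network(B1_sparse - B2_sparse, t)
    return delta, _support(delta)


def significant_differential(
    B1_sparse: np.ndarray, B2_sparse: np.ndarray, divisor: float = 5.0
) -> set[tuple[int, int]]:
    """Differential edges whose change is large relative to the effect.

    Cell (i, j) is kept iff |B1_ij - B2_ij| > min(|B1_ij|, |B2_ij|) /
    divisor (strict).  An edge present in only one condition always passes
    (the minimum is zero).
    """
    diff = np.abs(B1_sparse - B2_sparse)
    bound = np.minimum(np.abs(B1_sparse), np.abs(B2_sparse)) / divisor
    mask = diff > bound
    return {tuple(c) for c in np.argwhere(mask)}


def _default_edge_detector(
    data: PairedDataset,
    hp,
    t: float,
    mode: str,
    rng: np.random.Generator,
) -> set[tuple[int, int]]:
    from diffsem.gibbs import infer_all_genes

    post = infer_all_genes(data, hp, rng)
    B1s = threshold_network(np.nan_to_num(post.B1), t)
    B2s = threshold_network(np.nan_to_num(post.B2), t)
    if mode == "differential":
        _, delta_edges = differential_network(B1s, B2s, t)
        return delta_edges & significant_differential(B1s, B2s)
    return _support(B1s) | _support(B2s)


def bootstrap_stability(
    data: PairedDataset,
    hp=None,
    n_boot: int = 100,
    keep_count: int = 80,
    rng: np.random.Generator | None = None,
    mode: str = "network",
    t: float = DEFAULT_THRESHOLD,
    edge_detector: Callable | None = None,
    paired: bool = False,
) -> tuple[set[tuple[int, int]], dict[tuple[int, int], int]]:
    """Bootstrap edge-stability selection.

    Individuals are resampled with replacement (independently within each
    condition unless ``paired``), the full inference + thresholding (and,
    in ``mode="differential"``, the significance criterion) is re-run on
    each resample, and an edge is stable iff detected strictly more than
    ``keep_count`` times out of ``n_boot``.

    ``edge_detector(data, hp, t, mode, rng) -> edge set`` can replace the
    default full inference, e.g. for testing the counting rule in
    isolation.
    """
    if rng is None:
        rng = np.random.default_rng()
    if edge_detector is None:
        edge_detector = _default_edge_detector
    n = data.n
    counts: dict[tuple[int, int], int] = {}
    for b in range(n_boot):
        idx1 = rng.integers(0, n, size=n)
        idx2 = idx1 if paired else rng.integers(0, n, size=n)
        resampled = PairedDataset(
            Y1=data.Y1[idx1],
            Y2=data.Y2[idx2],
            X1=data.X1[idx1],
            X2=data.X2[idx2],
            supports=data.supports,
            gene_labels=data.gene_labels,
            eqtl_labels=data.eqtl_labels,
        )
        try:
            edges = edge_detector(resampled, hp, t, mode, rng)
        except Exception as exc:  # noqa: BLE001 - count as non-detection
            logger.warning("bootstrap %d failed, counted as no edges: %s", b, exc)
            continue
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
    stable = {e for e, c in counts.items() if c > keep_count}
    return stable, counts


def assemble_result(
    B1_hat: np.ndarray,
    B2_hat: np.ndarray,
    t: float = DEFAULT_THRESHOLD,
    divisor: float = 5.0,
) -> DifferentialResult:
    """Threshold both estimated networks, form the differential network and
    apply the relative-magnitude significance filter."""
    B1s = threshold_network(B1_hat, t)
    B2s = threshold_network(B2_hat, t)
    delta, delta_edges = differential_network(B1s, B2s, t)
    sig = significant_differential(B1s, B2s, divisor) & delta_edges
    return DifferentialResult(
        B1_sparse=B1s,
        B2_sparse=B2s,
        delta=delta,
        edges1=_support(B1s),
        edges2=_support(B2s),
        delta_edges=delta_edges,
        significant_delta=sig,
        threshold=t,
    )


def edges_to_frame(
    result: DifferentialResult,
    gene_labels: list[str] | None = None,
    ci: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Tidy edge table: one row per cell that is nonzero in either
    condition, with weights, delta, optional credible bounds and bootstrap
    frequency."""
    cells = sorted(result.edges1 | result.edges2 | result.delta_edges)
    rows = []
    for i, j in cells:
        row = {
            "source": gene_labels[i] if gene_labels else i,
            "target": gene_labels[j] if gene_labels else j,
            "weight_cond1": result.B1_sparse[i, j],
            "weight_cond2": result.B2_sparse[i, j],
            "delta": result.delta[i, j],
            "significant": (i, j) in result.significant_delta,
        }
        if ci is not None:
            for key, M in ci.items():
                row[key] = M[i, j]
        if result.bootstrap_freq:
            row["bootstrap_freq"] = result.bootstrap_freq.get((i, j), 0)
        rows.append(row)
    return pd.DataFrame(rows)
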