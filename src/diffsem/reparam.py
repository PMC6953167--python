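"""Per-gene split of the paired SEMs and the integrated regression design.

For gene ``i`` under condition ``k`` the SEM column reads

    y_i(k) = Y_-i(k) b_i(k) + X_Si(k) f_i(k) + e_i(k),

where Y_-i drops gene i's own column (no self-loops) and X_Si keeps only
the cis-eQTLs known to feed gene i.  The two conditions are merged into a
single regression by summing the responses and concatenating the designs:

    y_i = y_i(1) + y_i(2),   W_i = [W_i(1), W_i(2)],
    beta_i = [beta_i(1); beta_i(2)]  (length 2 p_i, p_i = p - 1 + q_i),

so that the fused prior can shrink both beta_i and the per-coordinate
differences beta_i(2) - beta_i(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from diffsem.simulate import PairedDataset

__all__ = [
    "SubproblemDesign",
    "split_gene",
    "build_subproblem",
    "extract_network_column",
]


@dataclass
class SubproblemDesign:
    """The integrated per-gene regression y = W beta + e.

    Columns 0..p_i-1 are the condition-1 regressors (the other genes'
    expression in original gene order, then gene i's eQTL genotypes);
    columns p_i..2p_i-1 repeat the same internal order for condition 2.
    ``column_labels`` records the (condition, regressor) pair behind every
    column.
    """

    gene_index: int
    y: np.ndarray
    W: np.ndarray
    p_i: int
    q_i: int
    column_labels: list[tuple[int, str]]

    @property
    def n(self) -> int:
        return self.W.shape[0]


def split_gene(
    data: PairedDataset, i: int, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (y_i, Y_-i, X_Si) for gene ``i`` (0-based) and condition
    ``k`` in {1, 2}.

    Y_-i preserves the original gene order; X_Si holds the genotype
    columns of gene i's cis-eQTL support.
    """
    if not 0 <= i < data.p:
        raise IndexError(f"gene index {i} out of range [0, {data.p})")
    if k not in (1, 2):
        raise ValueError("condition k must be 1 or 2")
    Y = data.Y1 if k == 1 else data.Y2
    X = data.X1 if k == 1 else data.X2
    support = np.asarray(data.supports[i])
    if support.size == 0:
        raise ValueError(
            f"gene {i} has no cis-eQTL support; at least one unique "
            "cis-eQTL per gene is required for identifiability"
        )
    y_i = Y[:, i]
    Y_minus = np.delete(Y, i, axis=1)
    X_S = X[:, support]
    return y_i, Y_minus, X_S


def build_subproblem(data: PairedDataset, i: int) -> SubproblemDesign:
    """Assemble the integrated design for gene ``i``.

    The response is the elementwise sum of the two condition responses and
    the design the horizontal concatenation of the two condition designs;
    requires equal per-condition sample sizes.
    """
    y1, Ym1, XS1 = split_gene(data, i, 1)
    y2, Ym2, XS2 = split_gene(data, i, 2)
    if len(y1) != len(y2):
        raise ValueError(
            "paired sample size: the integrated model requires equal "
            "sample sizes in the two conditions"
        )
    W1 = np.hstack([Ym1, XS1])
    W2 = np.hstack([Ym2, XS2])
    q_i = XS1.shape[1]
    p_i = data.p - 1 + q_i
    gene_names = [g for j, g in enumerate(data.gene_labels) if j != i]
    eqtl_names = [data.eqtl_labels[s] for s in data.supports[i]]
    labels = [(1, name) for name in gene_names + eqtl_names]
    labels += [(2, name) for name in gene_names + eqtl_names]
    return SubproblemDesign(
        gene_index=i,
        y=y1 + y2,
        W=np.hstack([W1, W2]),
        p_i=p_i,
        q_i=q_i,
        column_labels=labels,
    )


def extract_network_column(
    beta_hat: np.ndarray, i: int, p: int, q_i: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unpack a 2 p_i coefficient vector into the per-condition network and
    eQTL effect blocks (b_1, b_2, f_1, f_2).

    Inverse of the packing used by :func:`build_subproblem`; ``b_k`` has
    length p - 1 (gene i's structural zero is NOT reinserted here, use
    :func:`insert_structural_zero`).
    """
    p_i = p - 1 + q_i
    beta_hat = np.asarray(beta_hat)
    if beta_hat.shape[-1] != 2 * p_i:
        raise ValueError(
            f"coefficient vector of length {beta_hat.shape[-1]} does not "
            f"match 2*p_i = {2 * p_i}"
        )
    b1 = beta_hat[..., : p - 1]
    f1 = beta_hat[..., p - 1 : p_i]
    b2 = beta_hat[..., p_i : p_i + p - 1]
    f2 = beta_hat[..., p_i + p - 1 :]
    return b1, b2, f1, f2


def insert_structural_zero(b: np.ndarray, i: int) -> np.ndarray:
    """Re-insert the zero diagonal entry: lift a (p-1)-vector of effects on
    gene ``i`` to a p-vector with 0 at position ``i``."""
    return np.insert(np.asarray(b, dtype=float), i, 0.0, axis=-1)
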