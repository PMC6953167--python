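"""Power-of-detection / false-discovery-rate evaluation against ground truth.

Support-recovery metrics in the convention standard for sparse-SEM network
inference: PD (power of detection) is the fraction of true edges recovered
and FDR the fraction of reported edges that are false.  The paired metrics
pool true/false positives over both conditions' off-diagonal entries; the
differential metrics compare the support of the estimated dB against the
cells where the true networks actually differ.  A replicated study
averages the metrics over independently simulated datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from diffsem.assemble import (
    differential_network,
    threshold_network,
)
from diffsem.simulate import GroundTruth, simulate_paired_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "support_metrics",
    "paired_network_metrics",
    "run_replicated_study",
]


@dataclass
class EvalReport:
    """PD/FDR for the paired networks and the differential network."""

    pd_networks: float
    fdr_networks: float
    pd_delta: float
    fdr_delta: float
    setup: dict = field(default_factory=dict)


def support_metrics(
    estimated: set[tuple[int, int]], truth: set[tuple[int, int]]
) -> tuple[float, float]:
    """PD = |est ∩ truth| / |truth|; FDR = |est \\ truth| / |est| (0 when
    the estimate is empty).  Support-based: weights and signs are ignored."""
    if not truth:
        raise ValueError("true edge set is empty; PD is undefined")
    tp = len(estimated & truth)
    pd_ = tp / len(truth)
    fdr = (len(estimated) - tp) / len(estimated) if estimated else 0.0
    return pd_, fdr


def _supp(B: np.ndarray) -> set[tuple[int, int]]:
    return {tuple(c) for c in np.argwhere(B != 0)}


def paired_network_metrics(
    B1_est: np.ndarray,
    B2_est: np.ndarray,
    truth: GroundTruth,
    t: float,
) -> EvalReport:
    """Evaluate thresholded estimates of both networks against ground truth.

    The network metrics pool both conditions (an edge slot is a
    (condition, i, j) triple); the differential metrics compare the support
    of the thresholded-estimate difference with the true delta support.
    """
    B1s = threshold_network(B1_est, t)
    B2s = threshold_network(B2_est, t)
    est_pooled = {(1, *c) for c in _supp(B1s)} | {(2, *c) for c in _supp(B2s)}
    true_pooled = {(1, *c) for c in _supp(truth.B1.entries)} | {
        (2, *c) for c in _supp(truth.B2.entries)
    }
    pd_net, fdr_net = support_metrics(est_pooled, true_pooled)
    _, delta_edges = differential_network(B1s, B2s, t)
    pd_d, fdr_d = support_metrics(delta_edges, truth.delta_support)
    return EvalReport(
        pd_networks=pd_net,
        fdr_networks=fdr_net,
        pd_delta=pd_d,
        fdr_delta=fdr_d,
        setup={"t": t},
    )


def run_replicated_study(
    setups: list[dict],
    n_replicates: int = 20,
    hp=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Average PD/FDR over independently simulated replicates.

    Each setup dict supplies the simulation parameters (``p``, ``n``,
    ``n_e``, ``sigma2``, ``kind``, ``change_fraction``) and the selection
    threshold ``t``.  Returns a tidy table with one row per (setup,
    replicate) plus a mean row per setup; failed replicates are logged and
    excluded from the means.
    """
    from diffsem.gibbs import infer_all_genes

    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for setup in setups:
        t = setup.get("t", 0.2)
        sim_keys = ("p", "n", "n_e", "sigma2", "kind", "change_fraction")
        sim_args = {k: setup[k] for k in sim_keys if k in setup}
        rep_rngs = rng.spawn(n_replicates)
        reps = []
        for r in range(n_replicates):
            try:
                data, truth = simulate_paired_dataset(rng=rep_rngs[r], **sim_args)
                post = infer_all_genes(data, hp, rep_rngs[r])
                report = paired_network_metrics(
                    np.nan_to_num(post.B1), np.nan_to_num(post.B2), truth, t
                )
            except Exception as exc:  # noqa: BLE001 - replicate isolation
                logger.error("replicate %d of %s failed: %s", r, setup, exc)
                continue
            reps.append(report)
            rows.append(
                {
                    **setup,
                    "replicate": r,
                    "pd_networks": report.pd_networks,
                    "fdr_networks": report.fdr_networks,
                    "pd_delta": report.pd_delta,
                    "fdr_delta": report.fdr_delta,
                }
            )
        if reps:
            rows.append(
                {
                    **setup,
                    "replicate": "mean",
                    "pd_networks": float(np.mean([x.pd_networks for x in reps])),
                    "fdr_networks": float(np.mean([x.fdr_networks for x in reps])),
                    "pd_delta": float(np.mean([x.pd_delta for x in reps])),
                    "fdr_delta": float(np.mean([x.fdr_delta for x in reps])),
                    "n_completed": len(reps),
                }
            )
    return pd.DataFrame(rows)
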