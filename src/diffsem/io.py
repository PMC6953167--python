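"""Labeled matrix / edge-list / supports I/O and the run manifest.

All formats are plain text: TSV or CSV matrices with a header row of
variable labels and a first column of sample labels, a JSON supports file
mapping each gene to its cis-eQTL labels, TSV edge lists and a JSON run
manifest.  Labels — never positions — are the join key between expression,
genotype and supports files.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from diffsem.simulate import GroundTruth, PairedDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_supports",
    "write_supports",
    "write_dataset",
    "read_dataset",
    "write_truth_edges",
    "read_truth_edges",
    "write_manifest",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled matrix (samples as rows).

    The delimiter is sniffed from the extension (.csv -> comma, anything
    else -> tab).  Duplicate row/column labels and non-numeric cells are
    rejected.
    """
    path = Path(path)
    # pandas silently renames duplicate header labels; check the raw line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate column labels {dupes}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row labels {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    row_labels: list[str],
    col_labels: list[str],
) -> None:
    path = Path(path)
    df = pd.DataFrame(values, index=row_labels, columns=col_labels)
    df.to_csv(path, sep=_sep_for(path))


def read_supports(
    path: str | Path,
    gene_labels: list[str],
    eqtl_labels: list[str],
) -> list[np.ndarray]:
    """Read the {gene_label: [eqtl_labels]} JSON map and resolve it to
    per-gene eQTL column indices, validating every label."""
    with open(path) as fh:
        raw = json.load(fh)
    eqtl_index = {lab: k for k, lab in enumerate(eqtl_labels)}
    supports = []
    for g in gene_labels:
        if g not in raw:
            raise ValueError(f"supports file is missing gene {g!r}")
        labs = raw[g]
        if not labs:
            raise ValueError(
                f"gene {g!r} has an empty cis-eQTL support; at least one "
                "is required for identifiability"
            )
        idx = []
        for lab in labs:
            if lab not in eqtl_index:
                raise ValueError(
                    f"eQTL label {lab!r} (gene {g!r}) not found in the "
                    "genotype matrix header"
                )
            idx.append(eqtl_index[lab])
        supports.append(np.asarray(idx, dtype=int))
    return supports


def write_supports(data: PairedDataset, path: str | Path) -> None:
    raw = {
        g: [data.eqtl_labels[k] for k in data.supports[i]]
        for i, g in enumerate(data.gene_labels)
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)


def write_dataset(data: PairedDataset, outdir: str | Path) -> None:
    """Write the four labeled matrices plus the supports JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = [f"S{i + 1}" for i in range(data.n)]
    write_matrix(data.Y1, outdir / "Y1.tsv", samples, data.gene_labels)
    write_matrix(data.Y2, outdir / "Y2.tsv", samples, data.gene_labels)
    write_matrix(data.X1, outdir / "X1.tsv", samples, data.eqtl_labels)
    write_matrix(data.X2, outdir / "X2.tsv", samples, data.eqtl_labels)
    write_supports(data, outdir / "supports.json")


def read_dataset(
    y1: str | Path,
    y2: str | Path,
    x1: str | Path,
    x2: str | Path,
    supports: str | Path,
) -> PairedDataset:
    """Assemble a PairedDataset from matrix and supports files, joining on
    labels; gene/eQTL label sets must match across conditions."""
    Y1, Y2 = read_matrix(y1), read_matrix(y2)
    X1, X2 = read_matrix(x1), read_matrix(x2)
    if list(Y1.columns) != list(Y2.columns):
        raise ValueError("gene labels differ between the two conditions")
    if list(X1.columns) != list(X2.columns):
        raise ValueError("eQTL labels differ between the two conditions")
    gene_labels = list(Y1.columns)
    eqtl_labels = list(X1.columns)
    supp = read_supports(supports, gene_labels, eqtl_labels)
    return PairedDataset(
        Y1=Y1.to_numpy(),
        Y2=Y2.to_numpy(),
        X1=X1.to_numpy(),
        X2=X2.to_numpy(),
        supports=supp,
        gene_labels=gene_labels,
        eqtl_labels=eqtl_labels,
    )


def write_truth_edges(
    truth: GroundTruth, path: str | Path, gene_labels: list[str]
) -> None:
    """Ground-truth edge list: every cell nonzero in either condition."""
    cells = np.argwhere(
        (truth.B1.entries != 0) | (truth.B2.entries != 0)
    )
    rows = [
        {
            "source": gene_labels[i],
            "target": gene_labels[j],
            "weight_cond1": truth.B1.entries[i, j],
            "weight_cond2": truth.B2.entries[i, j],
        }
        for i, j in cells
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_edges(
    path: str | Path, gene_labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the true weight matrices from a truth edge list."""
    df = pd.read_csv(path, sep="\t")
    p = len(gene_labels)
    pos = {g: i for i, g in enumerate(gene_labels)}
    B1 = np.zeros((p, p))
    B2 = np.zeros((p, p))
    for _, row in df.iterrows():
        i, j = pos[row["source"]], pos[row["target"]]
        B1[i, j] = row["weight_cond1"]
        B2[i, j] = row["weight_cond2"]
    return B1, B2


def write_manifest(
    outdir: str | Path, config: dict, seed: int | None, t0: float
) -> None:
    manifest = {
        "config": config,
        "seed": seed,
        "wall_time_s": round(time.monotonic() - t0, 3),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    import diffsem

    manifest["versions"]["diffsem"] = diffsem.__version__
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
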