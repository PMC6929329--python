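"""Delimited-matrix and label I/O for the command-line pipeline.

Matrices are exchanged as CSV (comma) or TSV (tab, chosen by file
extension), optionally with a header row of sample names and a first column
of feature names — both autodetected.  The internal orientation is always
features x samples; files with samples in rows are transposed on read.
Numeric output uses full ``repr`` precision so that a write/read round trip
is exact and reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

__all__ = [
    "ParseError",
    "read_view_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_bundle",
]


class ParseError(ValueError):
    """Malformed delimited input (coordinates are 1-based)."""


def _sep_for(path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_view_matrix(path, orientation: str = "samples-in-columns"):
    """Read one view from a delimited text file.

    Returns ``(matrix, sample_names, feature_names)`` with the matrix in
    features x samples orientation (names are None when absent).  A header
    row and/or a leading name column are detected by looking for non-numeric
    cells; non-numeric data cells raise :class:`ParseError` with their
    coordinates.
    """
    if orientation not in {"samples-in-columns", "samples-in-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r]
    if not rows:
        raise ParseError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ParseError(
            f"{path}: row {bad + 1} has {len(rows[bad])} fields, "
            f"expected {len(rows[0])}"
        )

    has_index = any(not _is_number(r[0]) for r in rows[1:])
    first = rows[0][1 if has_index else 0 :]
    has_header = any(not _is_number(c) for c in first)
    if not has_index and not has_header and not _is_number(rows[0][0]):
        has_header = has_index = True  # lone non-numeric corner cell

    col_names = rows[0][1 if has_index else 0 :] if has_header else None
    body = rows[1:] if has_header else rows
    row_names = [r[0] for r in body] if has_index else None
    data = np.empty((len(body), len(body[0]) - (1 if has_index else 0)))
    for i, r in enumerate(body):
        for j, cell in enumerate(r[1 if has_index else 0 :]):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row "
                    f"{i + 1 + (1 if has_header else 0)}, column "
                    f"{j + 1 + (1 if has_index else 0)}: {cell!r}"
                ) from None
    if orientation == "samples-in-rows":
        return data.T, row_names, col_names
    return data, col_names, row_names


def write_matrix(path, M, sample_names=None, feature_names=None) -> None:
    """Write a features x samples matrix as delimited text (repr precision)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        if sample_names is not None:
            w.writerow(([""] if feature_names is not None else []) + list(sample_names))
        for i, row in enumerate(M):
            prefix = [feature_names[i]] if feature_names is not None else []
            w.writerow(prefix + [repr(float(x)) for x in row])


def read_labels(path):
    """Read a label vector: one label per line, optional 'name,label' pairs."""
    sep = _sep_for(path)
    names, labels = [], []
    with open(path, newline="") as fh:
        for r in csv.reader(fh, delimiter=sep):
            if not r:
                continue
            if len(r) == 1:
                labels.append(r[0])
            else:
                names.append(r[0])
                labels.append(r[1])
    if labels and labels[0].lower() in {"label", "labels"}:
        labels = labels[1:]
        names = names[1:] if names else names
    try:
        labels = [int(x) for x in labels]
    except ValueError:
        pass
    return np.asarray(labels), (names or None)


def write_labels(path, labels, sample_names=None) -> None:
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        for i, lab in enumerate(np.asarray(labels).ravel()):
            row = [sample_names[i]] if sample_names is not None else []
            w.writerow(row + [int(lab)])


def write_bundle(bundle, outdir) -> dict:
    """Write a simulation bundle: view matrices, label files and a JSON
    sidecar recording t, seed, noise sd and the exact permutations used.

    Returns the mapping of artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for v, X in enumerate(bundle.X):
        p = outdir / f"view_{v + 1}.csv"
        write_matrix(p, X)
        paths[f"view_{v + 1}"] = str(p)
    p = outdir / "labels_common.csv"
    write_labels(p, bundle.y)
    paths["labels_common"] = str(p)
    for v, y_v in enumerate(bundle.y_spec):
        p = outdir / f"labels_specific_{v + 1}.csv"
        write_labels(p, y_v)
        paths[f"labels_specific_{v + 1}"] = str(p)
    sidecar = {
        "t": bundle.t,
        "seed": bundle.seed,
        "noise_sd": bundle.noise_sd,
        "orthonormal_mixing": bundle.orthonormal_mixing,
        "n": int(bundle.y.shape[0]),
        "permutations": [p.tolist() for p in bundle.permutations],
    }
    p = outdir / "bundle.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["sidecar"] = str(p)
    return paths
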