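"""Delimited-text formats for matrices and metadata, plus quantile
normalisation against a training reference.

Matrices are TSV: first column ``site_id``, header row of sample ids, beta
values serialised with 6 decimals.  Reading validates shape and range and
reports offending coordinates.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "quantile_normalize",
]


def write_matrix(matrix: MethylationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for site, row in zip(matrix.site_ids, matrix.values):
            fh.write(site + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix(path) -> MethylationMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: header has no sample columns")
    site_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {len(header)})")
        site = fields[0]
        try:
            vals = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        bad = np.where((vals < 0) | (vals > 1) | ~np.isfinite(vals))[0]
        if bad.size:
            j = int(bad[0])
            raise ValueError(
                f"{path}:{lineno}: value {vals[j]} out of [0, 1] at site "
                f"{site!r}, sample {sample_ids[j]!r}")
        site_ids.append(site)
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: matrix has a header but no sites")
    return MethylationMatrix(np.stack(rows), site_ids, sample_ids)


def write_metadata(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "age" not in frame.columns:
        raise ValueError(f"{path}: metadata must contain an 'age' column")
    return frame


def quantile_normalize(matrix: MethylationMatrix,
                       reference: MethylationMatrix,
                       probe_types: Mapping[str, str] | None = None) -> MethylationMatrix:
    """Map each sample's values onto a training-median reference by rank.

    The reference distribution is the sorted per-site medians of the training
    matrix, computed separately within each probe-type group when a
    ``site_id -> type`` partition is supplied (one group otherwise).  Within
    a group, a sample's values are replaced by the reference quantiles at
    their ranks, which anchors every normalised sample to the same
    training-derived distribution.
    """
    if set(matrix.site_ids) - set(reference.site_ids):
        raise KeyError("matrix contains sites absent from the reference")
    ref = reference.subset_sites(matrix.site_ids)
    groups: dict[str, list[int]] = {}
    for i, site in enumerate(matrix.site_ids):
        key = probe_types.get(site, "I") if probe_types else "all"
        groups.setdefault(key, []).append(i)
    out = np.empty_like(matrix.values)
    for key, idx in groups.items():
        idx = np.asarray(idx)
        ref_sorted = np.sort(np.median(ref.values[idx], axis=1))
        m = len(idx)
        probs = (np.arange(m) + 0.5) / m
        for j in range(matrix.n_samples):
            col = matrix.values[idx, j]
            r = (rankdata(col) - 0.5) / m
            out[idx, j] = np.interp(r, probs, ref_sorted)
    logger.info("quantile-normalised %d sites in %d probe-type groups",
                matrix.n_sites, len(groups))
    return MethylationMatrix(out, list(matrix.site_ids), list(matrix.sample_ids))
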