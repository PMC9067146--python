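"""Expressed-feature filtering, log transformation and quantile normalization.

These are the preprocessing steps applied to FPKM-scale transcript matrices
before the permutation test: keep features detectably expressed, move to the
log2(FPKM + 1) scale, and force every sample onto a common value
distribution so the permutation null is exchangeable across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, PermomicsError, SchemaError


def filter_expressed(
    matrix: OmicsMatrix,
    mode: str = "all_min",
    threshold: float = 1.0,
    majority_frac: float = 0.5,
) -> OmicsMatrix:
    """Keep features passing the expressed filter.

    ``all_min`` keeps features whose value is >= ``threshold`` in every
    sample (the cell-line rule); ``majority`` keeps features whose value is
    strictly > ``threshold`` in strictly more than ``majority_frac`` of the
    samples (the cohort rule).  Both inequalities are deliberate and
    distinct.  Sample set and feature order are preserved.
    """
    matrix.require_layer("fpkm")
    vals = matrix.values.to_numpy()
    if mode == "all_min":
        keep = (vals >= threshold).all(axis=1)
    elif mode == "majority":
        frac_above = (vals > threshold).mean(axis=1)
        keep = frac_above > majority_frac
    else:
        raise PermomicsError(f"unknown filter mode {mode!r}")
    return matrix.copy_with(matrix.values.loc[keep])


def log_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Replace every FPKM value v by log2(v + 1); layer becomes ``lognorm``."""
    matrix.require_layer("fpkm")
    vals = matrix.values.to_numpy()
    if vals.size and np.nanmin(vals) < 0:
        raise SchemaError("log_transform requires non-negative values")
    out = pd.DataFrame(np.log2(vals + 1.0), index=matrix.values.index,
                       columns=matrix.values.columns)
    return matrix.copy_with(out, layer="lognorm")


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Quantile-normalize samples to the mean-of-sorted-values reference.

    Each column's values are replaced by the across-sample mean of the
    order statistics at that value's within-column rank, so that afterwards
    every column holds the identical multiset of values.  Ties within a
    column receive the mean of the reference values spanning their rank
    range (the classical convention).  Missing values are an error, never
    imputed.
    """
    matrix.require_layer("fpkm", "lognorm", "protein")
    if matrix.n_samples < 2:
        raise PermomicsError("quantile normalization requires >= 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise SchemaError("missing values present; quantile_normalize does not impute")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        order = np.argsort(vals[:, j], kind="stable")
        sv = vals[order, j]
        # tie groups get the mean of the reference values spanning their ranks
        starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        sizes = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(reference, starts) / sizes
        col = np.empty(n)
        col[order] = np.repeat(group_means, sizes)
        out[:, j] = col
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(frame)
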