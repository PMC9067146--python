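"""Empirical permutation two-group testing with data-derived cutoffs.

The statistic is the Welch two-sample t on log-scale abundances.  Instead of
the t reference distribution, significance comes from an empirical null:
sample labels are permuted across both groups (1000 times by default, or
exhaustively when the design is small enough), the t statistic and log2
fold-change are recomputed per feature, and all values are pooled across
features and permutations.  The pooled null yields

* a two-sided empirical p per feature, ``(1 + #{|t_null| >= |t_obs|}) / (1 + N)``;
* a data-derived fold-change cutoff, the mean of the magnitudes of the
  2.5th and 97.5th percentiles of the pooled null log2FC distribution;

and, for protein data, a second-stage *gap* filter: per feature,
``min(higher-mean group) - max(lower-mean group)``, positive only when the
replicate ranges separate completely, thresholded at the mean of the 25th
and 75th percentiles of the gaps of the stage-1-selected features.

Calling rules (strict inequalities throughout):

``deg``     p < 0.05 and |log2FC| > 0.58 (fixed, = 1.5-fold), no gap stage.
``dep``     p < 0.2, |log2FC| > null-derived cutoff, |gap| > derived cutoff.
``cohort``  p < 0.05, |log2FC| > null-derived cutoff, no gap stage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, PermomicsError

#: t assigned when both groups have zero variance but unequal means; larger
#: in magnitude than any finite null t so such features rank most extreme.
T_SENTINEL = 1e9


@dataclass
class ComparisonSpec:
    """Two-group comparison: which samples are 'a' (treated) and 'b' (control)."""

    group_a: list
    group_b: list
    n_permutations: int = 1000
    seed: int = 0
    exhaustive_if_possible: bool = True

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise PermomicsError("groups must be disjoint")
        if len(a) < 2 or len(b) < 2:
            raise PermomicsError("each group needs >= 2 samples")
        if self.n_permutations < 1:
            raise PermomicsError("n_permutations must be >= 1")


@dataclass
class NullDistribution:
    """Pooled permutation-null t statistics and log2 fold-changes."""

    t: np.ndarray
    log2fc: np.ndarray
    n_permutations: int
    exhaustive: bool
    seed: int

    def __post_init__(self) -> None:
        self._abs_t_sorted = None

    @property
    def size(self) -> int:
        return self.t.size

    def abs_t_sorted(self) -> np.ndarray:
        if self._abs_t_sorted is None:
            self._abs_t_sorted = np.sort(np.abs(self.t))
        return self._abs_t_sorted


@dataclass
class CutoffSet:
    """Thresholds applied by :func:`call_features`, with provenance."""

    p_cutoff: float
    fc_cutoff: float
    fc_mode: str = "fixed"  # fixed | null_percentile
    gap_cutoff: float | None = None
    gap_mode: str = "none"  # none | quartile_mean
    gap_signed: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 0:
            raise PermomicsError("fc_cutoff must be > 0")
        if self.fc_mode not in ("fixed", "null_percentile"):
            raise PermomicsError(f"unknown fc_mode {self.fc_mode!r}")
        if self.gap_mode not in ("none", "quartile_mean"):
            raise PermomicsError(f"unknown gap_mode {self.gap_mode!r}")


def _group_arrays(matrix: OmicsMatrix, spec: ComparisonSpec):
    missing = (set(spec.group_a) | set(spec.group_b)) - set(matrix.sample_ids)
    if missing:
        raise PermomicsError(f"samples not in matrix: {sorted(missing)}")
    Xa = matrix.values[list(spec.group_a)].to_numpy(dtype=float)
    Xb = matrix.values[list(spec.group_b)].to_numpy(dtype=float)
    return Xa, Xb


def welch_t(Xa: np.ndarray, Xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Welch t and mean difference for two samples (columns = replicates).

    Zero variance in both groups gives t = 0 when the means agree and the
    guarded sentinel ±``T_SENTINEL`` otherwise.
    """
    na, nb = Xa.shape[1], Xb.shape[1]
    ma, mb = Xa.mean(axis=1), Xb.mean(axis=1)
    va = Xa.var(axis=1, ddof=1)
    vb = Xb.var(axis=1, ddof=1)
    diff = ma - mb
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 == 0
    if np.any(degenerate):
        t = np.where(degenerate & (diff == 0), 0.0, t)
        t = np.where(degenerate & (diff != 0), np.sign(diff) * T_SENTINEL, t)
    return t, diff


def observed_stats(matrix: OmicsMatrix, spec: ComparisonSpec) -> pd.DataFrame:
    """Per-feature observed statistics: group means, log2FC (= mean_a - mean_b
    on the log scale), and the Welch t.  Calls are left unset."""
    matrix.require_layer("lognorm", "protein")
    Xa, Xb = _group_arrays(matrix, spec)
    t, diff = welch_t(Xa, Xb)
    return pd.DataFrame(
        {
            "mean_a": Xa.mean(axis=1),
            "mean_b": Xb.mean(axis=1),
            "log2fc": diff,
            "t": t,
        },
        index=matrix.values.index.rename("feature_id"),
    )


def _assignments(n_total: int, n_a: int, spec: ComparisonSpec):
    """Label assignments as index arrays into the pooled sample axis.

    Exhaustive when requested and the number of distinct assignments fits
    within ``n_permutations``; otherwise assignments are sampled uniformly
    (with replacement — a small design cannot yield 1000 distinct ones).
    """
    n_distinct = math.comb(n_total, n_a)
    if spec.exhaustive_if_possible and n_distinct <= spec.n_permutations:
        combos = [np.array(c, dtype=int) for c in itertools.combinations(range(n_total), n_a)]
        return combos, True
    rng = np.random.default_rng(spec.seed)
    combos = [rng.permutation(n_total)[:n_a] for _ in range(spec.n_permutations)]
    return combos, False


def build_null(matrix: OmicsMatrix, spec: ComparisonSpec) -> NullDistribution:
    """Pooled permutation null of t and log2FC across features and relabelings."""
    matrix.require_layer("lognorm", "protein")
    Xa, Xb = _group_arrays(matrix, spec)
    X = np.hstack([Xa, Xb])
    n_total, n_a = X.shape[1], Xa.shape[1]
    combos, exhaustive = _assignments(n_total, n_a, spec)
    all_idx = np.arange(n_total)
    ts, fcs = [], []
    for idx_a in combos:
        idx_b = np.setdiff1d(all_idx, idx_a, assume_unique=True)
        t, diff = welch_t(X[:, idx_a], X[:, idx_b])
        ts.append(t)
        fcs.append(diff)
    return NullDistribution(
        t=np.concatenate(ts),
        log2fc=np.concatenate(fcs),
        n_permutations=len(combos),
        exhaustive=exhaustive,
        seed=spec.seed,
    )


def empirical_pvalues(stats: pd.DataFrame, null: NullDistribution) -> pd.DataFrame:
    """Two-sided empirical p against the pooled null, with add-one correction.

    ``p = (1 + #{|t_null| >= |t_obs|}) / (1 + N_null)`` so p is never zero.
    A Benjamini-Hochberg column over these p-values is attached for
    inspection; the calling rules threshold ``p_empirical`` directly.
    """
    if null.size == 0:
        raise PermomicsError("empty null distribution")
    sorted_abs = null.abs_t_sorted()
    abs_obs = np.abs(stats["t"].to_numpy())
    n_ge = null.size - np.searchsorted(sorted_abs, abs_obs, side="left")
    out = stats.copy()
    out["p_empirical"] = (1.0 + n_ge) / (1.0 + null.size)
    out["p_bh"] = multipletests(out["p_empirical"], method="fdr_bh")[1]
    return out


def derive_fc_cutoff(
    null: NullDistribution | np.ndarray,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> float:
    """Fold-change cutoff = (|q_lower| + |q_upper|) / 2 of the pooled null
    log2FCs, percentiles by linear interpolation.  For a symmetric null this
    equals the upper percentile itself."""
    fcs = null.log2fc if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if fcs.size == 0:
        raise PermomicsError("empty null log2FC distribution")
    q_lo, q_hi = np.percentile(fcs, [lower_pct, upper_pct], method="linear")
    return float((abs(q_lo) + abs(q_hi)) / 2.0)


def compute_gap(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Gap = min(higher-mean group) - max(lower-mean group) for one feature.

    Positive only when the two replicate ranges separate completely; tied
    means take group a as the higher group (documented tie-break).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PermomicsError("both groups must be non-empty")
    if a.mean() >= b.mean():
        return float(a.min() - b.max())
    return float(b.min() - a.max())


def compute_gaps(matrix: OmicsMatrix, spec: ComparisonSpec) -> pd.Series:
    """Vectorized per-feature gap statistic for a comparison."""
    Xa, Xb = _group_arrays(matrix, spec)
    a_high = Xa.mean(axis=1) >= Xb.mean(axis=1)
    gap_a_high = Xa.min(axis=1) - Xb.max(axis=1)
    gap_b_high = Xb.min(axis=1) - Xa.max(axis=1)
    return pd.Series(
        np.where(a_high, gap_a_high, gap_b_high),
        index=matrix.values.index.rename("feature_id"),
        name="gap",
    )


def derive_gap_cutoff(gaps, lower_pct: float = 25.0, upper_pct: float = 75.0) -> float:
    """Gap cutoff = mean of the 25th and 75th percentiles (linear
    interpolation) of the gap values of the stage-1-selected features."""
    g = np.asarray(gaps, dtype=float)
    if g.size < 1:
        raise PermomicsError("need at least one gap value")
    q_lo, q_hi = np.percentile(g, [lower_pct, upper_pct], method="linear")
    return float((q_lo + q_hi) / 2.0)


def call_features(stats: pd.DataFrame, cutoffs: CutoffSet) -> pd.DataFrame:
    """Apply the calling rules; adds a ``call`` column in {up, down, ns}.

    Stage 1 keeps features with ``p_empirical < p_cutoff`` and
    ``|log2FC| > fc_cutoff`` (both strict).  When ``gap_mode`` is
    ``quartile_mean``, stage 2 keeps the stage-1 features whose gap exceeds
    ``gap_cutoff`` — the absolute gap by default, the signed gap when
    ``gap_signed`` (a signed gap demands fully separated replicate ranges).
    """
    out = stats.copy()
    stage1 = (out["p_empirical"] < cutoffs.p_cutoff) & (
        out["log2fc"].abs() > cutoffs.fc_cutoff
    )
    selected = stage1
    if cutoffs.gap_mode == "quartile_mean":
        if "gap" not in out.columns:
            raise PermomicsError("gap column required for gap_mode='quartile_mean'")
        if cutoffs.gap_cutoff is None:
            raise PermomicsError("gap_cutoff not set")
        gap_stat = out["gap"] if cutoffs.gap_signed else out["gap"].abs()
        selected = stage1 & (gap_stat > cutoffs.gap_cutoff)
    call = np.where(selected & (out["log2fc"] > 0), "up",
                    np.where(selected & (out["log2fc"] < 0), "down", "ns"))
    out["call"] = call
    return out


PRESETS = {
    "deg": dict(layer=("lognorm",), p_cutoff=0.05, fc_mode="fixed",
                fc_cutoff=0.58, gap_mode="none"),
    "dep": dict(layer=("protein",), p_cutoff=0.2, fc_mode="null_percentile",
                fc_cutoff=None, gap_mode="quartile_mean"),
    "cohort": dict(layer=("lognorm",), p_cutoff=0.05, fc_mode="null_percentile",
                   fc_cutoff=None, gap_mode="none"),
}


def run_comparison(
    matrix: OmicsMatrix,
    spec: ComparisonSpec,
    preset: str = "deg",
    gap_signed: bool = False,
) -> tuple[pd.DataFrame, CutoffSet, NullDistribution]:
    """Full two-group analysis under a preset: observed stats, permutation
    null, empirical p, cutoff derivation (when the preset derives them),
    gap stage (dep preset) and calls.

    Returns the per-feature stats table (with calls), the cutoffs applied
    (with provenance), and the null distribution used.
    """
    if preset not in PRESETS:
        raise PermomicsError(f"unknown preset {preset!r}")
    cfg = PRESETS[preset]
    matrix.require_layer(*cfg["layer"])

    stats = observed_stats(matrix, spec)
    null = build_null(matrix, spec)
    stats = empirical_pvalues(stats, null)

    if cfg["fc_mode"] == "fixed":
        fc_cutoff = cfg["fc_cutoff"]
        fc_prov = {"fc_mode": "fixed"}
    else:
        fc_cutoff = derive_fc_cutoff(null)
        fc_prov = {"fc_mode": "null_percentile", "fc_percentiles": (2.5, 97.5)}

    gap_cutoff = None
    if cfg["gap_mode"] == "quartile_mean":
        stats["gap"] = compute_gaps(matrix, spec)
        stage1 = (stats["p_empirical"] < cfg["p_cutoff"]) & (
            stats["log2fc"].abs() > fc_cutoff
        )
        if stage1.any():
            gap_stat = stats.loc[stage1, "gap"] if gap_signed else stats.loc[stage1, "gap"].abs()
            gap_cutoff = derive_gap_cutoff(gap_stat)
        else:
            gap_cutoff = np.inf  # nothing selected at stage 1, nothing to filter

    cutoffs = CutoffSet(
        p_cutoff=cfg["p_cutoff"],
        fc_cutoff=fc_cutoff,
        fc_mode=cfg["fc_mode"],
        gap_cutoff=gap_cutoff,
        gap_mode=cfg["gap_mode"],
        gap_signed=gap_signed,
        provenance={
            "preset": preset,
            "n_permutations": null.n_permutations,
            "exhaustive": null.exhaustive,
            "seed": null.seed,
            "gap_percentiles": (25.0, 75.0) if cfg["gap_mode"] != "none" else None,
            **fc_prov,
        },
    )
    return call_features(stats, cutoffs), cutoffs, null
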