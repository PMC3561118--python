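"""SAM-style two-class differential expression with permutation q-values.

The per-probe statistic is the regularised relative difference

    d = (xbar_b - xbar_a) / (s + s0)

where ``s`` is the pooled standard error of the mean difference and ``s0``
is a small additive constant ("fudge factor") that damps spuriously large
statistics at probes with tiny variance. False-discovery rates come from
permuting the group labels: for each probe's |d| threshold the q-value is
the median, over label assignments, of the number of permuted |d*| at or
above the threshold, divided by the number of probes actually called at
that threshold, clipped to [0, 1] and made monotone in |d|.

Comparison orientation: "a vs b" reports group *b* relative to group *a*,
so a transcript induced by the condition of group b gets a positive signed
fold-change. Down-changes use the negative-reciprocal display convention
(a halving is -2.0, not 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet

__all__ = [
    "DEConfig",
    "ThresholdPolicy",
    "fold_change",
    "sam_statistic",
    "estimate_s0",
    "permutation_qvalues",
    "differential_expression",
    "call_differential",
]


@dataclass
class DEConfig:
    """Knobs for the permutation differential-expression engine.

    s0_mode: how the fudge factor is chosen — "cv_minimization" (search the
    percentiles of the per-probe standard errors for the value that
    minimises the coefficient of variation of |d| spread across the
    variance range), "median_s" (median per-probe standard error) or
    "fixed" (use ``s0_fixed``).
    exhaustive_limit: when the number of distinct label assignments is at
    most this, every assignment is enumerated and the q-values are fully
    deterministic; otherwise ``n_permutations`` assignments are sampled
    with ``seed``.
    tie_rule: "geq" counts permuted |d*| equal to the threshold as
    exceedances (conservative); "gt" does not.
    """

    s0_mode: str = "cv_minimization"
    s0_fixed: float | None = None
    n_permutations: int = 500
    exhaustive_limit: int = 10_000
    seed: int = 0
    tie_rule: str = "geq"

    def __post_init__(self) -> None:
        if self.s0_mode not in ("cv_minimization", "median_s", "fixed"):
            raise ValueError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "fixed":
            if self.s0_fixed is None or self.s0_fixed < 0:
                raise ValueError("fixed s0_mode needs a nonnegative s0_fixed")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tie_rule not in ("geq", "gt"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass
class ThresholdPolicy:
    """Inclusion gate for calling a probe differential.

    A probe joins a set only if its absolute (linear-scale) fold-change is
    at least ``min_abs_fold`` and its permutation q-value is below
    ``max_q``. The defaults mirror a 1.5-fold / q<1% regime.
    """

    min_abs_fold: float = 1.5
    max_q: float = 0.01

    def __post_init__(self) -> None:
        if self.min_abs_fold < 1:
            raise ValueError("min_abs_fold must be >= 1")
        if not (0 < self.max_q < 1):
            raise ValueError("max_q must lie in (0, 1)")


def fold_change(mean_log2_a, mean_log2_b):
    """Signed linear fold-change of b relative to a from log2 group means.

    Returns +r for r = 2**(b - a) when r >= 1 and -1/r otherwise, so a
    doubling is +2.0 and a halving is -2.0. Accepts scalars or arrays.
    """
    a = np.asarray(mean_log2_a, dtype=float)
    b = np.asarray(mean_log2_b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group means must be finite")
    ratio = np.exp2(b - a)
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    if signed.ndim == 0:
        return float(signed)
    return signed


def _pooled_se(values_a: np.ndarray, values_b: np.ndarray, axis: int = -1):
    """Pooled standard error of the difference of two group means.

    s = sqrt[(1/na + 1/nb) * (SS_a + SS_b) / (na + nb - 2)]
    """
    na = values_a.shape[axis]
    nb = values_b.shape[axis]
    ss_a = np.sum((values_a - values_a.mean(axis=axis, keepdims=True)) ** 2, axis=axis)
    ss_b = np.sum((values_b - values_b.mean(axis=axis, keepdims=True)) ** 2, axis=axis)
    return np.sqrt((1.0 / na + 1.0 / nb) * (ss_a + ss_b) / (na + nb - 2))


def _relative_difference(num, denom):
    """d = num / denom with the 0/0 -> 0 and x/0 -> signed-inf conventions."""
    num = np.asarray(num, dtype=float)
    denom = np.asarray(denom, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / denom
        zero_denom = denom == 0
        d = np.where(zero_denom & (num == 0), 0.0, d)
        d = np.where(zero_denom & (num != 0), np.sign(num) * np.inf, d)
    return d


def sam_statistic(group_a, group_b, s0: float) -> float:
    """Relative difference d = (xbar_b - xbar_a)/(s + s0) for one probe."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    s = _pooled_se(a, b)
    return float(_relative_difference(b.mean() - a.mean(), s + s0))


def _sam_d_matrix(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray, s0: float) -> np.ndarray:
    va = values[:, mask_a]
    vb = values[:, mask_b]
    s = _pooled_se(va, vb, axis=1)
    return _relative_difference(vb.mean(axis=1) - va.mean(axis=1), s + s0)


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation scaled by 1/0.64 (SAM's convention)."""
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    return float(np.median(np.abs(x - np.median(x))) / 0.64)


def _cv_of_window_mads(d: np.ndarray, s: np.ndarray, n_groups: int) -> float:
    order = np.argsort(s, kind="mergesort")
    mads = np.array([_mad(d[idx]) for idx in np.array_split(order, n_groups)])
    mads = mads[np.isfinite(mads)]
    if mads.size < 2 or mads.mean() == 0:
        return float("inf")
    return float(mads.std(ddof=1) / mads.mean())


def estimate_s0(
    matrix: ExpressionMatrix | np.ndarray,
    group_a,
    group_b,
    s0_mode: str = "cv_minimization",
    s0_fixed: float | None = None,
) -> float:
    """Choose the SAM fudge factor for one two-group comparison.

    ``group_a``/``group_b`` are boolean masks over samples (or, when
    ``matrix`` is an :class:`ExpressionMatrix`, (genotype, oxygen) pairs).
    In cv_minimization mode the candidates are the 0th, 5th, ..., 100th
    percentiles of the per-probe pooled standard errors; the winner
    minimises the coefficient of variation of the spread of d across
    standard-error windows, so that |d| is roughly variance-independent.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values.to_numpy(dtype=float)
        mask_a = matrix.group_mask(*group_a) if not isinstance(group_a, np.ndarray) else group_a
        mask_b = matrix.group_mask(*group_b) if not isinstance(group_b, np.ndarray) else group_b
    else:
        values = np.asarray(matrix, dtype=float)
        mask_a = np.asarray(group_a, dtype=bool)
        mask_b = np.asarray(group_b, dtype=bool)

    if s0_mode == "fixed":
        if s0_fixed is None or s0_fixed < 0:
            raise ValueError("fixed mode needs nonnegative s0_fixed")
        return float(s0_fixed)

    va = values[:, mask_a]
    vb = values[:, mask_b]
    s = _pooled_se(va, vb, axis=1)

    if s0_mode == "median_s":
        return float(np.median(s))
    if s0_mode != "cv_minimization":
        raise ValueError(f"unknown s0_mode {s0_mode!r}")
    if values.shape[0] < 10:
        raise ValueError("cv_minimization needs at least 10 probes")

    diff = vb.mean(axis=1) - va.mean(axis=1)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_groups = min(100, max(2, values.shape[0] // 10))
    best_alpha, best_cv = None, math.inf
    for alpha in candidates:
        d = _relative_difference(diff, s + alpha)
        cv = _cv_of_window_mads(d, s, n_groups)
        if cv < best_cv:
            best_alpha, best_cv = float(alpha), cv
    if best_alpha is None:  # all windows degenerate (e.g. zero variance)
        return float(np.median(s))
    return best_alpha


def _n_distinct_assignments(n: int, na: int) -> int:
    return math.comb(n, na)


def _iter_assignments(n: int, na: int):
    idx = np.arange(n)
    for combo in combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        yield mask


def permutation_qvalues(
    values: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    config: DEConfig,
    s0: float | None = None,
):
    """Per-probe d statistics and permutation q-values for one comparison.

    Returns ``(d, q, meta)`` where meta records the s0 used and whether the
    label assignments were enumerated exhaustively or sampled.
    """
    values = np.asarray(values, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 samples")

    if s0 is None:
        s0 = estimate_s0(values, mask_a, mask_b, config.s0_mode, config.s0_fixed)

    d = _sam_d_matrix(values, mask_a, mask_b, s0)
    absd = np.abs(d)

    # pool of samples taking part in the comparison, in a fixed order
    pool = np.flatnonzero(mask_a | mask_b)
    sub = values[:, pool]
    side = "left" if config.tie_rule == "geq" else "right"

    # observed number of probes called at each probe's |d| threshold
    sorted_abs = np.sort(absd)
    observed = absd.size - np.searchsorted(sorted_abs, absd, side=side)
    observed = np.maximum(observed, 1)  # each probe is called at its own threshold

    n_total = _n_distinct_assignments(pool.size, na)
    exhaustive = n_total <= config.exhaustive_limit
    if exhaustive:
        masks = list(_iter_assignments(pool.size, na))
    else:
        rng = np.random.default_rng(config.seed)
        masks = []
        for _ in range(config.n_permutations):
            sel = rng.choice(pool.size, size=na, replace=False)
            mask = np.zeros(pool.size, dtype=bool)
            mask[sel] = True
            masks.append(mask)

    exceed = np.empty((len(masks), absd.size), dtype=float)
    for i, pm in enumerate(masks):
        d_star = _sam_d_matrix(sub, pm, ~pm, s0)
        sorted_star = np.sort(np.abs(d_star))
        exceed[i] = absd.size - np.searchsorted(sorted_star, absd, side=side)

    q = np.clip(np.median(exceed, axis=0) / observed, 0.0, 1.0)

    # monotone: a larger |d| never gets a larger q. Walking the probes from
    # weakest to strongest |d| and taking running minima gives every probe
    # the smallest raw q seen at or below its own threshold.
    order = np.argsort(absd, kind="mergesort")  # ascending |d|
    q_mono = np.empty_like(q)
    q_mono[order] = np.minimum.accumulate(q[order])

    meta = {"s0": float(s0), "exhaustive": exhaustive, "n_assignments": len(masks)}
    return d, q_mono, meta


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Run the full SAM-style comparison "group_a vs group_b".

    Groups are (genotype, oxygen) pairs. Returns a DataFrame indexed by
    probe_id with columns mean_log2_a, mean_log2_b, fold_change_signed,
    d_statistic, q_value; comparison metadata lives in ``df.attrs``.
    """
    config = config or DEConfig()
    mask_a = matrix.group_mask(*group_a)
    mask_b = matrix.group_mask(*group_b)
    values = matrix.values.to_numpy(dtype=float)
    mean_a = values[:, mask_a].mean(axis=1)
    mean_b = values[:, mask_b].mean(axis=1)
    d, q, meta = permutation_qvalues(values, mask_a, mask_b, config)
    out = pd.DataFrame(
        {
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "fold_change_signed": fold_change(mean_a, mean_b),
            "d_statistic": d,
            "q_value": q,
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )
    out.attrs["comparison"] = {"a": group_a, "b": group_b}
    out.attrs.update(meta)
    return out


def call_differential(result: pd.DataFrame, policy: ThresholdPolicy, name: str) -> GeneSet:
    """Gate a comparison's results into a directed gene set.

    Inclusion requires |signed fold| >= min_abs_fold AND q < max_q;
    direction is the sign of the fold-change.
    """
    fold = result["fold_change_signed"]
    keep = (fold.abs() >= policy.min_abs_fold) & (result["q_value"] < policy.max_q)
    members = {
        probe: ("up" if f > 0 else "down")
        for probe, f in fold[keep].items()
    }
    return GeneSet(name, members)
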