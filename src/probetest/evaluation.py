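"""Figures of merit: average ROC over spike-in experiments and top-N overlap.

ROC curves are parameterized by the number of called genes (one point per
called count 0..n), the only grid that makes curves from the rearranged
experiments commensurable without interpolation assumptions; tied scores
are handled by linear interpolation across the tie block, so curves are
invariant under sample and gene-id relabeling. AUC is the trapezoid-rule
integral of TP rate against FP rate.

Robustness follows the resampling scheme of the overlap statistic: random
sample subsets (drawn without replacement, stratified proportionally by
condition so the pooled variance stays estimable), top-N gene lists per
subset, pairwise shared fractions f_{a,b} over all unordered pairs, and
their mean f as the summary.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Callable, Mapping, Sequence, Set

import numpy as np

from .data import GeneTestResult, ProbeMatrix, TwoGroupDesign
from .errors import ConfigurationError, DomainError, ValidationError

__all__ = [
    "RocCurve",
    "OverlapResult",
    "roc_curve",
    "average_roc",
    "top_n",
    "overlap_fraction",
    "robustness",
]

RankingMethod = Callable[[ProbeMatrix, TwoGroupDesign], list[GeneTestResult]]


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """A ROC polyline with one vertex per called-gene count."""

    thresholds: np.ndarray
    fp_rate: np.ndarray
    tp_rate: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        for name in ("thresholds", "fp_rate", "tp_rate"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        fp, tp = self.fp_rate, self.tp_rate
        if fp.shape != tp.shape or fp.shape != self.thresholds.shape:
            raise ValidationError("roc vectors must share one shape")
        if np.any(np.diff(fp) < -1e-12) or np.any(np.diff(tp) < -1e-12):
            raise ValidationError("fp_rate and tp_rate must be nondecreasing")
        if not (
            fp[0] == 0 and tp[0] == 0 and abs(fp[-1] - 1) < 1e-12 and abs(tp[-1] - 1) < 1e-12
        ):
            raise ValidationError("roc must include endpoints (0,0) and (1,1)")


@dataclasses.dataclass(frozen=True)
class OverlapResult:
    """Pairwise top-N overlap fractions and their mean."""

    n_top: int
    per_pair_fractions: np.ndarray
    mean_overlap: float

    def __post_init__(self) -> None:
        fr = np.asarray(self.per_pair_fractions, dtype=float)
        object.__setattr__(self, "per_pair_fractions", fr)
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValidationError("overlap fractions must lie in [0, 1]")
        if not (0.0 <= self.mean_overlap <= 1.0):
            raise ValidationError("mean_overlap must lie in [0, 1]")


def roc_curve(
    scores: Mapping[str, float],
    truth: Set[str],
    excluded: Set[str] = frozenset(),
) -> RocCurve:
    """ROC of a score map against a truth set, excluded genes removed.

    Sweeps descending score thresholds: at each, TP rate is the fraction
    of truth genes called and FP rate the fraction of non-truth genes
    called. Vertices are produced at every called count 0..n (ties
    interpolated linearly across their block).
    """
    genes = [g for g in scores if g not in excluded]
    truth_eval = {g for g in genes if g in truth}
    if not truth_eval:
        raise DomainError("truth set is empty after exclusions")
    n_truth = len(truth_eval)
    n_null = len(genes) - n_truth
    if n_null == 0:
        raise DomainError("no non-truth genes to compute an FP rate from")
    s = np.asarray([scores[g] for g in genes], dtype=float)
    is_truth = np.asarray([g in truth_eval for g in genes])
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    truth_sorted = is_truth[order]
    # block boundaries where the score strictly drops
    n = len(genes)
    drop = np.nonzero(np.diff(s_sorted))[0] + 1
    bounds = np.concatenate([[0], drop, [n]])
    cum_tp = np.concatenate([[0], np.cumsum(truth_sorted)])
    counts = np.arange(n + 1)
    tp = np.interp(counts, bounds, cum_tp[bounds]) / n_truth
    fp = (counts - np.interp(counts, bounds, cum_tp[bounds])) / n_null
    thresholds = np.concatenate([[np.inf], s_sorted])
    auc = float(np.trapezoid(tp, fp))
    return RocCurve(thresholds=thresholds, fp_rate=fp, tp_rate=tp, auc=auc)


def average_roc(curves: Sequence[RocCurve]) -> RocCurve:
    """Pointwise average of ROC curves on a common called-fraction grid.

    Each curve is resampled onto a grid of called-gene fractions (exact
    when all curves share a gene count), TP and FP rates are averaged
    index-wise and the AUC of the averaged polyline is reported.
    """
    if not curves:
        raise DomainError("need at least one curve")
    if len(curves) == 1:
        return curves[0]
    grid_len = max(len(c.fp_rate) for c in curves)
    grid = np.linspace(0.0, 1.0, grid_len)
    fps = np.zeros(grid_len)
    tps = np.zeros(grid_len)
    for c in curves:
        own = np.linspace(0.0, 1.0, len(c.fp_rate))
        fps += np.interp(grid, own, c.fp_rate)
        tps += np.interp(grid, own, c.tp_rate)
    fps /= len(curves)
    tps /= len(curves)
    auc = float(np.trapezoid(tps, fps))
    return RocCurve(thresholds=grid, fp_rate=fps, tp_rate=tps, auc=auc)


def top_n(results: Sequence[GeneTestResult], n_top: int) -> list[str]:
    """Gene ids of the ``n_top`` best-ranked results, rank order."""
    if n_top < 1 or n_top > len(results):
        raise DomainError(
            f"n_top must be in 1..{len(results)}, got {n_top}"
        )
    ordered = sorted(results, key=lambda r: r.rank)
    return [r.gene_id for r in ordered[:n_top]]


def overlap_fraction(list_a: Sequence[str], list_b: Sequence[str]) -> float:
    """Fraction of genes shared by two equally sized duplicate-free lists."""
    if len(list_a) != len(list_b):
        raise DomainError(
            f"lists must have equal length, got {len(list_a)} and {len(list_b)}"
        )
    set_a, set_b = set(list_a), set(list_b)
    if len(set_a) != len(list_a) or len(set_b) != len(list_b):
        raise ValidationError("lists must be duplicate-free")
    return len(set_a & set_b) / len(list_a)


def _stratified_sizes(
    subsample_size: int, n_a: int, n_b: int
) -> tuple[int, int]:
    total = n_a + n_b
    if subsample_size > total:
        raise ConfigurationError(
            f"subsample_size {subsample_size} exceeds {total} samples"
        )
    k_a = int(round(subsample_size * n_a / total))
    k_b = subsample_size - k_a
    if k_a < 2 or k_b < 2 or k_a > n_a or k_b > n_b:
        raise ConfigurationError(
            f"subsample of {subsample_size} leaves a condition with < 2 samples "
            f"(split {k_a}/{k_b} of {n_a}/{n_b})"
        )
    return k_a, k_b


def robustness(
    matrix: ProbeMatrix,
    design: TwoGroupDesign,
    subsample_size: int,
    n_subsamples: int,
    n_top: int,
    method: RankingMethod,
    seed: int,
) -> OverlapResult:
    """Mean top-N overlap of a ranking method over random sample subsets.

    ``method`` maps a (sub)matrix and its design to ranked results; the
    median-t pipeline or a baseline wrapper both fit. Reproducible per
    seed.
    """
    if n_subsamples < 2:
        raise ConfigurationError("n_subsamples must be >= 2")
    a_ids = np.asarray(design.samples_a, dtype=object)
    b_ids = np.asarray(design.samples_b, dtype=object)
    k_a, k_b = _stratified_sizes(subsample_size, len(a_ids), len(b_ids))
    rng = np.random.default_rng(seed)
    lists: list[list[str]] = []
    for _ in range(n_subsamples):
        sel_a = list(rng.choice(a_ids, size=k_a, replace=False))
        sel_b = list(rng.choice(b_ids, size=k_b, replace=False))
        sub_matrix = matrix.subset_samples(sel_a + sel_b)
        sub_design = TwoGroupDesign.from_groups(sel_a, sel_b)
        results = method(sub_matrix, sub_design)
        lists.append(top_n(results, n_top))
    fractions = np.asarray(
        [
            overlap_fraction(lists[a], lists[b])
            for a, b in itertools.combinations(range(n_subsamples), 2)
        ]
    )
    return OverlapResult(
        n_top=n_top,
        per_pair_fractions=fractions,
        mean_overlap=float(fractions.mean()),
    )
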