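"""Probe-level two-sample t statistics, median-t aggregation and ranking.

The core method: pooled two-sample t statistics are computed per probe on
quantile-normalized intensities (no background correction, no log
transform — the t statistic is scale- and location-invariant, so testing
the normalized intensity is equivalent to testing the underlying
concentration), each gene is scored by the median of its probes' t values
and genes are ranked by descending absolute median t.

Also provides the standard gene-level t-test on summarized expression
values as a comparison baseline.

Zero pooled variance is handled as follows: equal group means give t = 0
(no evidence); unequal means give a signed-infinity sentinel whose sign is
that of the mean difference. Infinite medians rank above all finite ones
and receive two-sided p = 0.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GeneTestResult, ProbeMatrix, TwoGroupDesign
from .errors import ValidationError
from .median_t import get_median_t_distribution
from .normalization import quantile_normalize, sanity_check_normalized

__all__ = [
    "PooledTStatistic",
    "pooled_t",
    "probe_t_values",
    "median_t_per_gene",
    "rank_genes",
    "gene_level_t_baseline",
    "run_probe_level_test",
]


@dataclasses.dataclass(frozen=True)
class PooledTStatistic:
    """A pooled two-sample t statistic (equal-variance form)."""

    t: float
    df: int
    group_means: tuple[float, float]
    pooled_sd_term: float

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValidationError(f"df must be >= 2, got {self.df}")
        if self.pooled_sd_term < 0:
            raise ValidationError("pooled_sd_term must be >= 0")


def pooled_t(values_a: Sequence[float], values_b: Sequence[float]) -> PooledTStatistic:
    """Pooled t statistic (A minus B in the numerator).

    The denominator is s = sqrt(a * (SS_A + SS_B)) with
    a = (1/n_A + 1/n_B) / (n_A + n_B - 2) and SS the within-group sums of
    squared deviations.
    """
    a_arr = np.asarray(values_a, dtype=float)
    b_arr = np.asarray(values_b, dtype=float)
    n_a, n_b = a_arr.size, b_arr.size
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"both groups need >= 2 values (got {n_a} and {n_b})"
        )
    df = n_a + n_b - 2
    mean_a = float(a_arr.mean())
    mean_b = float(b_arr.mean())
    ss = float(((a_arr - mean_a) ** 2).sum() + ((b_arr - mean_b) ** 2).sum())
    a_const = (1.0 / n_a + 1.0 / n_b) / df
    s = math.sqrt(a_const * ss)
    diff = mean_a - mean_b
    if s > 0.0:
        t = diff / s
    elif diff == 0.0:
        t = 0.0
    else:
        t = math.copysign(math.inf, diff)
    return PooledTStatistic(
        t=t, df=df, group_means=(mean_a, mean_b), pooled_sd_term=s
    )


def _pooled_t_rows(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Row-wise pooled t statistics for a (rows x samples) value matrix."""
    A = values[:, idx_a]
    B = values[:, idx_b]
    n_a, n_b = A.shape[1], B.shape[1]
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    a_const = (1.0 / n_a + 1.0 / n_b) / (n_a + n_b - 2)
    s = np.sqrt(a_const * ss)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / s
        return np.where(
            s > 0.0, t, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf)
        )


def probe_t_values(
    matrix: ProbeMatrix,
    design: TwoGroupDesign,
    *,
    check_normalized: bool = True,
) -> dict[str, np.ndarray]:
    """Per-probe t statistics grouped by gene, vectors ordered by probe id.

    Emits a warning (does not fail) when the matrix does not look
    quantile-normalized.
    """
    if check_normalized and not sanity_check_normalized(matrix):
        warnings.warn(
            "matrix does not look quantile-normalized; probe t-values are "
            "still scale/location invariant per probe but arrays may not be "
            "comparable",
            stacklevel=2,
        )
    missing = [s for s in design.condition_of if s not in matrix.sample_ids]
    if missing:
        raise ValidationError(f"design sample {missing[0]!r} absent from matrix")
    idx_a = np.asarray([matrix.sample_index(s) for s in design.samples_a], dtype=int)
    idx_b = np.asarray([matrix.sample_index(s) for s in design.samples_b], dtype=int)
    t_rows = _pooled_t_rows(matrix.values, idx_a, idx_b)
    return {
        gene: t_rows[rows]
        for gene, rows in matrix.probe_indices_by_gene().items()
    }


def median_t_per_gene(probe_ts: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Sample median of each gene's probe t vector.

    Even-length vectors use the mean of the two central order statistics;
    infinite sentinels participate in the ordering on the extended reals.
    """
    out: dict[str, float] = {}
    for gene, ts in probe_ts.items():
        arr = np.asarray(ts, dtype=float)
        if arr.size == 0:
            raise ValidationError(f"gene {gene!r} has an empty probe t vector")
        out[gene] = float(np.median(arr))
    return out


def rank_genes(
    median_ts: Mapping[str, float],
    p_values: Mapping[str, float],
    probe_ts: Mapping[str, np.ndarray] | None = None,
) -> list[GeneTestResult]:
    """Rank genes by descending |median t|, ties broken by gene id.

    ``probe_ts``, when given, must share the key set and populates the
    per-probe t vectors of the results.
    """
    if set(median_ts) != set(p_values):
        raise ValidationError("median_ts and p_values must share one key set")
    if probe_ts is not None and set(probe_ts) != set(median_ts):
        raise ValidationError("probe_ts must share the key set of median_ts")
    order = sorted(median_ts, key=lambda g: (-abs(median_ts[g]), g))
    results = []
    for rank, gene in enumerate(order, start=1):
        ts = (
            np.asarray(probe_ts[gene], dtype=float)
            if probe_ts is not None
            else np.asarray([median_ts[gene]], dtype=float)
        )
        results.append(
            GeneTestResult(
                gene_id=gene,
                probe_t_values=ts,
                median_t=float(median_ts[gene]),
                p_value=float(p_values[gene]),
                rank=rank,
            )
        )
    return results


def gene_level_t_baseline(
    expression: pd.DataFrame, design: TwoGroupDesign
) -> dict[str, PooledTStatistic]:
    """Standard pooled t-test per gene on a summarized genes × samples table.

    The comparison baseline: one t statistic per gene computed on the
    expression values inferred by a preprocessing method. Note the result
    is not invariant under monotone transforms such as log2.
    """
    missing = [s for s in design.condition_of if s not in expression.columns]
    if missing:
        raise ValidationError(f"design sample {missing[0]!r} absent from expression")
    cols = list(expression.columns)
    idx_a = np.asarray([cols.index(s) for s in design.samples_a], dtype=int)
    idx_b = np.asarray([cols.index(s) for s in design.samples_b], dtype=int)
    values = expression.to_numpy(dtype=float)
    A = values[:, idx_a]
    B = values[:, idx_b]
    t_rows = _pooled_t_rows(values, idx_a, idx_b)
    n_a, n_b = len(idx_a), len(idx_b)
    a_const = (1.0 / n_a + 1.0 / n_b) / (n_a + n_b - 2)
    out: dict[str, PooledTStatistic] = {}
    for i, gene in enumerate(expression.index):
        mean_a = float(A[i].mean())
        mean_b = float(B[i].mean())
        ss = float(((A[i] - mean_a) ** 2).sum() + ((B[i] - mean_b) ** 2).sum())
        out[str(gene)] = PooledTStatistic(
            t=float(t_rows[i]),
            df=n_a + n_b - 2,
            group_means=(mean_a, mean_b),
            pooled_sd_term=math.sqrt(a_const * ss),
        )
    return out


def run_probe_level_test(
    matrix: ProbeMatrix,
    design: TwoGroupDesign,
    *,
    normalize: bool = True,
    sided: str = "two",
) -> list[GeneTestResult]:
    """Full pipeline: normalize, probe t, median t, p-values, ranking."""
    if normalize:
        matrix = quantile_normalize(matrix)
    probe_ts = probe_t_values(matrix, design, check_normalized=not normalize)
    medians = median_t_per_gene(probe_ts)
    df = design.df
    genes_by_n: dict[int, list[str]] = {}
    for gene, ts in probe_ts.items():
        genes_by_n.setdefault(int(ts.size), []).append(gene)
    p_vals: dict[str, float] = {}
    for n, genes in genes_by_n.items():
        dist = get_median_t_distribution(n, float(df))
        ps = dist.p_values(np.asarray([medians[g] for g in genes]), sided=sided)
        p_vals.update(zip(genes, (float(p) for p in ps)))
    return rank_genes(medians, p_vals, probe_ts)
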