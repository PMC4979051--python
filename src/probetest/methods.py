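"""Ready-made ranking methods for the evaluation procedures.

A ranking method maps a probe matrix plus a two-group design to a ranked
result list. Two are provided: the probe-level median-t pipeline and the
gene-level t-test baseline applied to (imperfectly) background-corrected,
summarized expression.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .data import GeneTestResult, ProbeMatrix, TwoGroupDesign
from .evaluation import RankingMethod
from .normalization import quantile_normalize
from .spikein import SpikeInModel, summarize_with_background_error
from .testing import gene_level_t_baseline, rank_genes, run_probe_level_test

__all__ = ["median_t_method", "make_gene_t_method", "gene_t_results"]


def median_t_method(
    matrix: ProbeMatrix, design: TwoGroupDesign
) -> list[GeneTestResult]:
    """The probe-level median-t pipeline (normalizes internally)."""
    return run_probe_level_test(matrix, design, normalize=True, sided="two")


def gene_t_results(
    expression, design: TwoGroupDesign
) -> list[GeneTestResult]:
    """Rank genes by |t| of the gene-level baseline on summarized values."""
    stats = gene_level_t_baseline(expression, design)
    t_map = {g: s.t for g, s in stats.items()}
    df = design.df
    finite = np.asarray(
        [t if np.isfinite(t) else 0.0 for t in t_map.values()], dtype=float
    )
    # two-sided Student-t p-values; infinite sentinels get p = 0
    p_arr = 2.0 * special.stdtr(df, -np.abs(finite))
    p_map = {}
    for (g, t), p in zip(t_map.items(), p_arr):
        p_map[g] = 0.0 if not np.isfinite(t) else float(p)
    return rank_genes(t_map, p_map)


def make_gene_t_method(
    model: SpikeInModel,
    misestimation_sd: float,
    seed: int,
    floor: float = 1e-3,
) -> RankingMethod:
    """Baseline method: normalize, background-correct with error, summarize,
    then apply the standard gene-level t-test.

    ``model`` must carry realized per-probe background values (the model
    returned by a simulation).
    """

    def method(matrix: ProbeMatrix, design: TwoGroupDesign) -> list[GeneTestResult]:
        normalized = quantile_normalize(matrix)
        expression = summarize_with_background_error(
            normalized, model, misestimation_sd, seed=seed, floor=floor
        )
        return gene_t_results(expression, design)

    return method
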