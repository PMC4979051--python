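"""Synthetic probe-level data under the linear intensity model.

Intensities follow Y = (B + phi * theta) * eps where B is a probe-specific,
sample-independent background, phi a probe-specific affinity, theta the
per-gene concentration and eps multiplicative lognormal noise with mean 1
and a configurable coefficient of variation (the linear model itself has
no noise term; multiplicative noise is the conventional high-intensity
microarray error model).

Two generators are provided:

* a Latin-square spike-in layout emulating the HG-U133 benchmark (42
  spiked genes = 14 concentration groups x 3 genes, 3 replicate arrays per
  sample group, a doubling concentration series containing 0), with the
  cyclic rearrangement into 14 two-condition "experiments"; and
* a generic two-condition dataset with a known set of fold-changed genes.

All randomness flows from one explicit seed; no global random state.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ProbeMatrix, TwoGroupDesign
from .errors import ConfigurationError, DomainError, ValidationError

__all__ = [
    "SpikeInModel",
    "SpikeInDesign",
    "RearrangedExperiment",
    "SpikeInSimulation",
    "simulate_latin_square",
    "rearrange_latin_square",
    "simulate_two_condition",
    "summarize_with_background_error",
    "default_concentrations",
]


def default_concentrations(n_groups: int = 14, start: float = 0.125) -> tuple[float, ...]:
    """0 followed by a doubling series: 0, 0.125, 0.25, ..., 512 for 14 groups."""
    if n_groups < 2:
        raise ConfigurationError("need at least 2 concentration groups")
    return (0.0,) + tuple(start * 2.0**i for i in range(n_groups - 1))


@dataclasses.dataclass(frozen=True)
class SpikeInModel:
    """Intensity-model parameters and (optionally) realized per-probe values.

    ``background`` and ``affinity`` may be explicit maps probe_id -> value;
    when absent they are drawn lognormally (median ``background_median``
    a.u., median ``affinity_median``, with the given log-scale sds) by
    :meth:`realize`. Defaults put low-concentration spikes near background,
    the regime where background correction hurts. ``theta_median`` /
    ``theta_sdlog`` parameterize concentrations of unspiked (null) genes.
    """

    noise_cv: float = 0.2
    background_median: float = 100.0
    background_sdlog: float = 0.5
    affinity_median: float = 1.0
    affinity_sdlog: float = 0.5
    theta_median: float = 50.0
    theta_sdlog: float = 1.0
    background: Mapping[str, float] | None = None
    affinity: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DomainError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.affinity_median <= 0 and self.affinity is None:
            raise DomainError("affinity_median must be > 0")
        if self.background_median < 0:
            raise DomainError("background_median must be >= 0")
        if self.background is not None:
            if any(v < 0 for v in self.background.values()):
                raise ValidationError("explicit background values must be >= 0")
        if self.affinity is not None:
            if any(v <= 0 for v in self.affinity.values()):
                raise ValidationError("explicit affinity values must be > 0")

    def realize(
        self, probe_ids: Sequence[str], rng: np.random.Generator
    ) -> "SpikeInModel":
        """A copy with explicit background/affinity maps for these probes."""
        n = len(probe_ids)
        if self.background is not None:
            bg = {p: float(self.background[p]) for p in probe_ids}
        else:
            draws = self.background_median * np.exp(
                rng.normal(0.0, self.background_sdlog, size=n)
            )
            bg = dict(zip(probe_ids, draws.tolist()))
        if self.affinity is not None:
            phi = {p: float(self.affinity[p]) for p in probe_ids}
        else:
            draws = self.affinity_median * np.exp(
                rng.normal(0.0, self.affinity_sdlog, size=n)
            )
            phi = dict(zip(probe_ids, draws.tolist()))
        return dataclasses.replace(self, background=bg, affinity=phi)

    def _noise(self, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        """Lognormal multiplicative noise with mean 1 and cv = noise_cv."""
        if self.noise_cv == 0:
            return np.ones(shape)
        sigma2 = np.log1p(self.noise_cv**2)
        return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape))


@dataclasses.dataclass(frozen=True)
class SpikeInDesign:
    """Latin-square layout: gene groups cycle through a concentration series.

    Gene group ``m`` receives concentration index ``(m + k) % n_groups`` on
    the arrays of sample group ``k`` (cyclic shift), so across the
    ``n_groups`` sample groups every gene group visits every concentration
    exactly once.
    """

    n_groups: int = 14
    genes_per_group: int = 3
    replicates: int = 3
    concentrations: tuple[float, ...] = default_concentrations()
    n_null_genes: int = 0
    probes_per_gene: int = 11

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigurationError("n_groups must be >= 2")
        if self.genes_per_group < 1 or self.replicates < 1:
            raise ConfigurationError("genes_per_group and replicates must be >= 1")
        if self.probes_per_gene < 1:
            raise ConfigurationError("probes_per_gene must be >= 1")
        if self.n_null_genes < 0:
            raise ConfigurationError("n_null_genes must be >= 0")
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        if len(self.concentrations) != self.n_groups:
            raise ConfigurationError(
                f"{len(self.concentrations)} concentrations for "
                f"{self.n_groups} groups"
            )
        if any(c < 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be >= 0")

    # -- identifiers ----------------------------------------------------

    @property
    def n_spiked_genes(self) -> int:
        return self.n_groups * self.genes_per_group

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.replicates

    def spiked_gene_ids(self, group: int) -> tuple[str, ...]:
        return tuple(
            f"spike_{group + 1:02d}_{j + 1}" for j in range(self.genes_per_group)
        )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        spiked = [g for m in range(self.n_groups) for g in self.spiked_gene_ids(m)]
        nulls = [f"null_{i + 1:05d}" for i in range(self.n_null_genes)]
        return tuple(spiked + nulls)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"array_{i + 1:02d}" for i in range(self.n_samples))

    def sample_group(self, sample_index: int) -> int:
        return sample_index // self.replicates

    def samples_of_group(self, group: int) -> tuple[str, ...]:
        start = group * self.replicates
        return self.sample_ids[start : start + self.replicates]

    def probe_ids_of(self, gene_id: str) -> tuple[str, ...]:
        return tuple(
            f"{gene_id}:{p + 1:02d}" for p in range(self.probes_per_gene)
        )

    def probe_map(self) -> dict[str, str]:
        return {
            probe: gene
            for gene in self.gene_ids
            for probe in self.probe_ids_of(gene)
        }

    # -- the concentration schedule -------------------------------------

    def concentration_index(self, gene_group: int, sample_group: int) -> int:
        return (gene_group + sample_group) % self.n_groups

    def concentration(self, gene_group: int, sample_group: int) -> float:
        return self.concentrations[self.concentration_index(gene_group, sample_group)]

    def schedule(self) -> pd.DataFrame:
        """Spiked-gene concentrations, genes x samples."""
        rows = {}
        for m in range(self.n_groups):
            per_sample = [
                self.concentration(m, self.sample_group(i))
                for i in range(self.n_samples)
            ]
            for gene in self.spiked_gene_ids(m):
                rows[gene] = per_sample
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(self.sample_ids)
        )


@dataclasses.dataclass(frozen=True)
class RearrangedExperiment:
    """One two-condition comparison carved out of the Latin square."""

    name: str
    condition_a_samples: tuple[str, ...]
    condition_b_samples: tuple[str, ...]
    truth: frozenset[str]
    excluded: frozenset[str]

    def __post_init__(self) -> None:
        if self.truth & self.excluded:
            raise ValidationError("truth and excluded must be disjoint")

    def to_design(self) -> TwoGroupDesign:
        return TwoGroupDesign.from_groups(
            self.condition_a_samples, self.condition_b_samples
        )


def rearrange_latin_square(design: SpikeInDesign) -> list[RearrangedExperiment]:
    """All cyclic consecutive pairings of sample groups as A/B experiments.

    Experiment k assigns the replicates of sample group k to condition A
    and those of group (k+1) mod n_groups to condition B. The single gene
    group whose concentration transition is the wrap from the last schedule
    index back to the first (maximum concentration -> 0 pM) is excluded
    from evaluation; every other spiked gene is truth.
    """
    if 0.0 not in design.concentrations:
        raise ConfigurationError(
            "rearrangement requires a 0-concentration group in the design"
        )
    experiments = []
    for k in range(design.n_groups):
        excluded_group = (design.n_groups - 1 - k) % design.n_groups
        truth: set[str] = set()
        excluded: set[str] = set()
        for m in range(design.n_groups):
            genes = design.spiked_gene_ids(m)
            (excluded if m == excluded_group else truth).update(genes)
        experiments.append(
            RearrangedExperiment(
                name=f"experiment_{k + 1:02d}",
                condition_a_samples=design.samples_of_group(k),
                condition_b_samples=design.samples_of_group(
                    (k + 1) % design.n_groups
                ),
                truth=frozenset(truth),
                excluded=frozenset(excluded),
            )
        )
    return experiments


@dataclasses.dataclass(frozen=True)
class SpikeInSimulation:
    """A simulated Latin-square dataset with its ground truth attached."""

    matrix: ProbeMatrix
    design: SpikeInDesign
    model: SpikeInModel  # realized: explicit background/affinity maps
    theta: pd.DataFrame  # genes x samples concentrations

    @property
    def experiments(self) -> list[RearrangedExperiment]:
        return rearrange_latin_square(self.design)


def _intensities(
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
    theta: np.ndarray,
    probes_per_gene: int,
    model: SpikeInModel,
    rng: np.random.Generator,
) -> tuple[ProbeMatrix, SpikeInModel]:
    probe_ids = [
        f"{gene}:{p + 1:02d}" for gene in gene_ids for p in range(probes_per_gene)
    ]
    probe_map = {
        probe: gene
        for gene in gene_ids
        for probe in (f"{gene}:{p + 1:02d}" for p in range(probes_per_gene))
    }
    realized = model.realize(probe_ids, rng)
    bg = np.asarray([realized.background[p] for p in probe_ids])
    phi = np.asarray([realized.affinity[p] for p in probe_ids])
    gene_of_probe = np.repeat(np.arange(len(gene_ids)), probes_per_gene)
    mean = bg[:, None] + phi[:, None] * theta[gene_of_probe, :]
    eps = realized._noise(mean.shape, rng)
    matrix = ProbeMatrix(
        values=mean * eps,
        probe_ids=tuple(probe_ids),
        sample_ids=tuple(sample_ids),
        probe_to_gene=probe_map,
    )
    return matrix, realized


def simulate_latin_square(
    design: SpikeInDesign,
    model: SpikeInModel | None = None,
    seed: int = 0,
) -> SpikeInSimulation:
    """Simulate probe intensities for a Latin-square spike-in layout.

    Spiked genes follow the cyclic concentration schedule; null genes draw
    one concentration each (lognormal, model parameters) held constant
    across all samples. Reproducible per seed: randomness is consumed in
    the fixed order null-theta, background, affinity, noise.
    """
    model = model if model is not None else SpikeInModel()
    rng = np.random.default_rng(seed)
    gene_ids = design.gene_ids
    n_samples = design.n_samples
    theta = np.empty((len(gene_ids), n_samples))
    schedule = design.schedule()
    theta[: design.n_spiked_genes, :] = schedule.to_numpy()
    if design.n_null_genes:
        null_theta = model.theta_median * np.exp(
            rng.normal(0.0, model.theta_sdlog, size=design.n_null_genes)
        )
        theta[design.n_spiked_genes :, :] = null_theta[:, None]
    matrix, realized = _intensities(
        gene_ids, design.sample_ids, theta, design.probes_per_gene, model, rng
    )
    theta_df = pd.DataFrame(theta, index=list(gene_ids), columns=list(design.sample_ids))
    return SpikeInSimulation(
        matrix=matrix, design=design, model=realized, theta=theta_df
    )


def simulate_two_condition(
    n_genes: int,
    n_deg: int,
    fold_change: float,
    n_a: int,
    n_b: int,
    model: SpikeInModel | None = None,
    probes_per_gene: int = 11,
    seed: int = 0,
    return_model: bool = False,
):
    """Generic two-condition dataset with a known fold-changed truth set.

    Per-gene baseline concentrations are lognormal; the first ``n_deg``
    genes have theta multiplied by ``fold_change`` in condition B.
    Returns ``(matrix, design, truth)``; with ``return_model=True`` the
    realized model (explicit per-probe background/affinity, as needed by
    :func:`summarize_with_background_error`) is appended as a fourth
    element.
    """
    if not (0 <= n_deg <= n_genes):
        raise DomainError(f"need 0 <= n_deg <= n_genes, got {n_deg}/{n_genes}")
    if fold_change <= 0:
        raise DomainError(f"fold_change must be > 0, got {fold_change}")
    if n_a < 2 or n_b < 2:
        raise ConfigurationError("both conditions need >= 2 samples")
    if probes_per_gene < 1:
        raise ConfigurationError("probes_per_gene must be >= 1")
    model = model if model is not None else SpikeInModel()
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"gene_{i + 1:05d}" for i in range(n_genes))
    truth = frozenset(gene_ids[:n_deg])
    a_ids = tuple(f"A_{i + 1:02d}" for i in range(n_a))
    b_ids = tuple(f"B_{i + 1:02d}" for i in range(n_b))
    sample_ids = a_ids + b_ids
    base = model.theta_median * np.exp(rng.normal(0.0, model.theta_sdlog, size=n_genes))
    theta = np.tile(base[:, None], (1, n_a + n_b))
    theta[:n_deg, n_a:] *= fold_change
    matrix, realized = _intensities(
        gene_ids, sample_ids, theta, probes_per_gene, model, rng
    )
    design = TwoGroupDesign.from_groups(a_ids, b_ids)
    if return_model:
        return matrix, design, truth, realized
    return matrix, design, truth


def summarize_with_background_error(
    matrix: ProbeMatrix,
    model: SpikeInModel,
    misestimation_sd: float,
    seed: int,
    floor: float = 1e-3,
) -> pd.DataFrame:
    """Background-correct-then-summarize with imperfect background estimates.

    Per probe and array the estimate B-hat = B + N(0, misestimation_sd) is
    subtracted (estimation error varies across arrays, as in practice),
    the result is clamped at a small positive floor and each gene is
    summarized as the median over its probes. The relative error of the
    recovered concentration grows as expression decreases — the regime the
    probe-level test avoids. Output feeds :func:`~probetest.testing.gene_level_t_baseline`.
    """
    if misestimation_sd < 0:
        raise DomainError(f"misestimation_sd must be >= 0, got {misestimation_sd}")
    if model.background is None or model.affinity is None:
        raise ValidationError(
            "model must carry realized background/affinity maps "
            "(use the model returned by a simulation)"
        )
    rng = np.random.default_rng(seed)
    bg = np.asarray([model.background[p] for p in matrix.probe_ids])
    if misestimation_sd > 0:
        bhat = bg[:, None] + rng.normal(
            0.0, misestimation_sd, size=matrix.values.shape
        )
    else:
        bhat = np.broadcast_to(bg[:, None], matrix.values.shape)
    corrected = np.maximum(matrix.values - bhat, floor)
    by_gene = matrix.probe_indices_by_gene()
    genes = list(matrix.gene_ids)
    summarized = np.empty((len(genes), matrix.n_samples))
    for i, gene in enumerate(genes):
        summarized[i] = np.median(corrected[by_gene[gene], :], axis=0)
    return pd.DataFrame(summarized, index=genes, columns=list(matrix.sample_ids))
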