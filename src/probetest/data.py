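"""Core data types and plain-text I/O.

Probe-level intensity matrices, probe→gene maps, two-group sample designs
and per-gene test results, together with tab-separated readers and writers.

File dialects (all UTF-8, tab-separated, "." decimal separator, no quoting):

* probe matrix — header row of sample ids, first column probe ids;
* probe map — two columns ``probe_id<TAB>gene_id``, header optional;
* labels — two columns ``sample_id<TAB>A|B``, header optional;
* results — header ``gene_id n_probes median_t p_value rank``.

Missing values are not permitted: a cell that does not parse as a finite
non-negative number (including ``NA``) is a :class:`~probetest.errors.ParseError`
with its row/column location.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ProbeMatrix",
    "TwoGroupDesign",
    "GeneTestResult",
    "read_probe_matrix",
    "write_probe_matrix",
    "write_probe_map",
    "read_labels",
    "write_labels",
    "write_results",
    "read_results",
]


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


@dataclasses.dataclass(frozen=True)
class ProbeMatrix:
    """A probes × samples intensity matrix with a total probe→gene map.

    Parameters
    ----------
    values
        Non-negative, finite intensities, shape ``(n_probes, n_samples)``.
    probe_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    probe_to_gene
        Total map from every probe id to its gene (probe-set) id.
    """

    values: np.ndarray
    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    probe_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "probe_to_gene", dict(self.probe_to_gene))
        self._validate()

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValidationError(
                f"{len(self.probe_ids)} probe ids for {n_probes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        dup = _first_duplicate(self.probe_ids)
        if dup is not None:
            raise ValidationError(f"duplicate probe id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        probe_set = set(self.probe_ids)
        missing = probe_set - set(self.probe_to_gene)
        if missing:
            raise ValidationError(
                f"probe {sorted(missing)[0]!r} present in matrix but absent from map"
            )
        extra = set(self.probe_to_gene) - probe_set
        if extra:
            raise ValidationError(
                f"probe {sorted(extra)[0]!r} present in map but absent from matrix"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite intensity at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.values.size and np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative intensity at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    # -- derived views -------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        """Gene ids in order of first appearance along the probe rows."""
        seen: dict[str, None] = {}
        for p in self.probe_ids:
            seen.setdefault(self.probe_to_gene[p], None)
        return tuple(seen)

    def probe_indices_by_gene(self) -> dict[str, np.ndarray]:
        """Row indices of each gene's probes, ordered by probe id."""
        by_gene: dict[str, list[int]] = {}
        for idx, p in enumerate(self.probe_ids):
            by_gene.setdefault(self.probe_to_gene[p], []).append(idx)
        out: dict[str, np.ndarray] = {}
        for g, idxs in by_gene.items():
            idxs.sort(key=lambda i: self.probe_ids[i])
            out[g] = np.asarray(idxs, dtype=int)
        return out

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id: {sample_id!r}") from None

    def subset_samples(self, sample_ids: Iterable[str]) -> "ProbeMatrix":
        """A new matrix restricted to the given samples, in the given order."""
        ids = tuple(sample_ids)
        cols = [self.sample_index(s) for s in ids]
        return ProbeMatrix(
            values=self.values[:, cols],
            probe_ids=self.probe_ids,
            sample_ids=ids,
            probe_to_gene=self.probe_to_gene,
        )

    def with_values(self, values: np.ndarray) -> "ProbeMatrix":
        return ProbeMatrix(
            values=values,
            probe_ids=self.probe_ids,
            sample_ids=self.sample_ids,
            probe_to_gene=self.probe_to_gene,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )


@dataclasses.dataclass(frozen=True)
class TwoGroupDesign:
    """Assignment of samples to conditions ``A`` and ``B``.

    Both groups must contain at least two samples so the pooled variance
    of the two-sample t statistic is estimable.
    """

    condition_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_of", dict(self.condition_of))
        for s, c in self.condition_of.items():
            if c not in ("A", "B"):
                raise ValidationError(
                    f"condition of sample {s!r} must be 'A' or 'B', got {c!r}"
                )
        if self.n_a < 2 or self.n_b < 2:
            raise ValidationError(
                f"both conditions need >= 2 samples (got n_A={self.n_a}, n_B={self.n_b})"
            )

    @classmethod
    def from_groups(
        cls, a_samples: Iterable[str], b_samples: Iterable[str]
    ) -> "TwoGroupDesign":
        mapping = {s: "A" for s in a_samples}
        for s in b_samples:
            if s in mapping:
                raise ValidationError(f"sample {s!r} assigned to both conditions")
            mapping[s] = "B"
        return cls(mapping)

    @property
    def samples_a(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.condition_of.items() if c == "A")

    @property
    def samples_b(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.condition_of.items() if c == "B")

    @property
    def n_a(self) -> int:
        return sum(1 for c in self.condition_of.values() if c == "A")

    @property
    def n_b(self) -> int:
        return sum(1 for c in self.condition_of.values() if c == "B")

    @property
    def df(self) -> int:
        """Degrees of freedom of the pooled two-sample t statistic."""
        return self.n_a + self.n_b - 2

    @property
    def variance_constant(self) -> float:
        """The constant a = (1/n_A + 1/n_B) / (n_A + n_B - 2)."""
        return (1.0 / self.n_a + 1.0 / self.n_b) / self.df

    def swapped(self) -> "TwoGroupDesign":
        """The design with condition labels A and B exchanged."""
        flip = {"A": "B", "B": "A"}
        return TwoGroupDesign({s: flip[c] for s, c in self.condition_of.items()})

    def restrict(self, sample_ids: Iterable[str]) -> "TwoGroupDesign":
        return TwoGroupDesign({s: self.condition_of[s] for s in sample_ids})


@dataclasses.dataclass(frozen=True)
class GeneTestResult:
    """Per-gene outcome of the probe-level median-t test."""

    gene_id: str
    probe_t_values: np.ndarray
    median_t: float
    p_value: float
    rank: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probe_t_values", np.asarray(self.probe_t_values, dtype=float)
        )
        if self.probe_t_values.size:
            med = float(np.median(self.probe_t_values))
            if not (
                med == self.median_t
                or (math.isnan(med) and math.isnan(self.median_t))
                or math.isclose(med, self.median_t, rel_tol=1e-9, abs_tol=1e-9)
            ):
                raise ValidationError(
                    f"median_t {self.median_t} does not match the median of "
                    f"probe_t_values for gene {self.gene_id!r}"
                )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(
                f"p_value {self.p_value} outside [0, 1] for gene {self.gene_id!r}"
            )
        if self.rank < 1:
            raise ValidationError(f"rank must be positive, got {self.rank}")

    @property
    def n_probes(self) -> int:
        return int(self.probe_t_values.size)


# -- readers / writers ------------------------------------------------------


def _read_lines(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.rstrip("\n").rstrip("\r") for ln in fh]


def _parse_cell(token: str, probe_id: str, sample_id: str) -> float:
    try:
        x = float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric intensity {token!r} at probe {probe_id!r}, "
            f"sample {sample_id!r}"
        ) from None
    if not math.isfinite(x):
        raise ParseError(
            f"non-finite intensity {token!r} at probe {probe_id!r}, "
            f"sample {sample_id!r}"
        )
    if x < 0:
        raise ParseError(
            f"negative intensity {x} at probe {probe_id!r}, sample {sample_id!r}"
        )
    return x


def read_probe_matrix(path: str, map_path: str) -> ProbeMatrix:
    """Read a probe matrix TSV and its probe→gene map TSV.

    The matrix file has a header row of sample ids and probe ids in the
    first column; row order is preserved. The map file holds two columns
    ``probe_id<TAB>gene_id`` (a ``probe_id<TAB>gene_id`` header line is
    tolerated).
    """
    lines = _read_lines(path)
    if not lines or not lines[0]:
        raise ParseError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    sample_ids = tuple(header[1:])
    if any(not s for s in sample_ids):
        raise ParseError(f"{path}: empty sample id in header")
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{ln_no}: expected {len(sample_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        probe_id = fields[0]
        probe_ids.append(probe_id)
        rows.append(
            [
                _parse_cell(tok, probe_id, sample_ids[j])
                for j, tok in enumerate(fields[1:])
            ]
        )
    probe_to_gene = read_probe_map(map_path)
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(sample_ids)), dtype=float)
    )
    return ProbeMatrix(
        values=values,
        probe_ids=tuple(probe_ids),
        sample_ids=sample_ids,
        probe_to_gene=probe_to_gene,
    )


def read_probe_map(map_path: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for ln_no, line in enumerate(_read_lines(map_path), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{map_path}:{ln_no}: expected 2 fields, got {len(fields)}")
        probe_id, gene_id = fields
        if ln_no == 1 and (probe_id, gene_id) == ("probe_id", "gene_id"):
            continue
        if probe_id in mapping:
            raise ValidationError(f"duplicate probe id in map: {probe_id!r}")
        mapping[probe_id] = gene_id
    return mapping


def write_probe_matrix(matrix: ProbeMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, probe_id in enumerate(matrix.probe_ids):
            fh.write(
                probe_id
                + "\t"
                + "\t".join(_fmt(v) for v in matrix.values[i])
                + "\n"
            )


def write_probe_map(probe_to_gene: Mapping[str, str], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for probe_id, gene_id in probe_to_gene.items():
            fh.write(f"{probe_id}\t{gene_id}\n")


def read_labels(path: str) -> TwoGroupDesign:
    mapping: dict[str, str] = {}
    for ln_no, line in enumerate(_read_lines(path), start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{ln_no}: expected 2 fields, got {len(fields)}")
        sample_id, cond = fields
        if ln_no == 1 and (sample_id, cond) == ("sample_id", "condition"):
            continue
        if sample_id in mapping:
            raise ValidationError(f"duplicate sample id in labels: {sample_id!r}")
        mapping[sample_id] = cond
    return TwoGroupDesign(mapping)


def write_labels(design: TwoGroupDesign, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\n")
        for sample_id, cond in design.condition_of.items():
            fh.write(f"{sample_id}\t{cond}\n")


_RESULT_COLUMNS = ("gene_id", "n_probes", "median_t", "p_value", "rank")


def write_results(results: Sequence[GeneTestResult], path: str) -> None:
    """Write a ranked results table, ordered by rank ascending.

    p-values and median t values are rendered with 9 significant digits.
    """
    ordered = sorted(results, key=lambda r: r.rank)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in ordered:
            fh.write(
                f"{r.gene_id}\t{r.n_probes}\t{r.median_t:.9g}\t"
                f"{r.p_value:.9g}\t{r.rank}\n"
            )


def read_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(_RESULT_COLUMNS):
        raise ParseError(f"{path}: unexpected result columns {list(df.columns)}")
    return df
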