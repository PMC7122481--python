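"""Reading, validation and harmonisation of expression matrices and labels.

Expression matrices are genes × samples, already normalised (e.g. RMA or
Illumina-processed, log scale). Values only need to be comparable *within*
a sample — the downstream rank features never compare values across samples.
Missing measurements are carried as NaN, never as silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens accepted as "missing" on read; "NA" is written on output
MISSING_TOKENS = ("NA", "")

POSITIVE_LABEL = "HCC"
NEGATIVE_LABEL = "CwoHCC"


class ExpressionParseError(ValueError):
    """Malformed expression/label/probe-map input."""


@dataclass
class ExpressionMatrix:
    """Genes × samples real-valued expression with identifiers.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique, non-empty row identifiers (gene symbols or probe ids).
    sample_ids : sequence of str
        Unique, non-empty column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Expression values; NaN marks a missing measurement.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if not self.gene_ids:
            raise ExpressionParseError("matrix has no genes")
        if not self.sample_ids:
            raise ExpressionParseError("matrix has no samples")
        if any(g == "" for g in self.gene_ids):
            raise ExpressionParseError("empty gene identifier")
        if any(s == "" for s in self.sample_ids):
            raise ExpressionParseError("empty sample identifier")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ExpressionParseError(
                f"duplicate gene identifier {dup!r}; collapse probes explicitly"
            )
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ExpressionParseError(f"duplicate sample identifier {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionParseError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class SampleLabels:
    """Binary phenotype per sample: positive = HCC, negative = CwoHCC."""

    sample_ids: list[str]
    labels: np.ndarray  # bool, True = positive class
    positive_name: str = POSITIVE_LABEL
    negative_name: str = NEGATIVE_LABEL

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=bool)
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ExpressionParseError(f"duplicate labeled sample {dup!r}")
        if self.labels.shape != (len(self.sample_ids),):
            raise ExpressionParseError("labels length does not match sample_ids")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    def as_names(self) -> list[str]:
        return [self.positive_name if l else self.negative_name for l in self.labels]

    def subset(self, sample_ids: Sequence[str]) -> "SampleLabels":
        pos = {s: l for s, l in zip(self.sample_ids, self.labels)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return SampleLabels(
            list(sample_ids),
            np.array([pos[s] for s in sample_ids], dtype=bool),
            self.positive_name,
            self.negative_name,
        )


@dataclass
class ProbeGeneMap:
    """Many-to-one probe → gene mapping."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {str(p): str(g) for p, g in self.mapping.items()}


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a delimited expression matrix (genes in rows, samples in columns).

    The first column holds gene/probe ids, the header row sample ids. "NA"
    and empty cells are missing. Duplicate gene rows are rejected — probe
    collapsing must be requested explicitly via :func:`collapse_probes`.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n")
    sample_header = header.split(sep)[1:]
    if not sample_header:
        raise ExpressionParseError(f"{path}: header row has no sample ids")
    dup = _first_duplicate(sample_header)
    if dup is not None:  # pandas would silently rename duplicate columns
        raise ExpressionParseError(f"{path}: duplicate sample identifier {dup!r}")
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, dtype=str, keep_default_na=False
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ExpressionParseError(f"{path}: cannot parse: {exc}") from exc
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j].strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ExpressionParseError(
                        f"{path}: non-numeric cell {cell!r} at gene "
                        f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
                    ) from None
    return ExpressionMatrix(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=values,
    )


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a matrix in the same dialect ``read_expression`` accepts."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    frame = m.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def read_labels(
    path: str | Path,
    positive: str = POSITIVE_LABEL,
    negative: str = NEGATIVE_LABEL,
) -> SampleLabels:
    """Read a two-column TSV (sample_id, label)."""
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ExpressionParseError(f"{path}: expected two columns (sample_id, label)")
    ids = frame.iloc[:, 0].tolist()
    raw = frame.iloc[:, 1].tolist()
    labels = []
    for s, lab in zip(ids, raw):
        if lab == positive:
            labels.append(True)
        elif lab == negative:
            labels.append(False)
        else:
            raise ExpressionParseError(
                f"{path}: sample {s!r} has label {lab!r}, "
                f"expected {positive!r} or {negative!r}"
            )
    return SampleLabels(ids, np.array(labels, dtype=bool), positive, negative)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "label": labels.as_names()}
    ).to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column TSV (probe_id, gene_id)."""
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ExpressionParseError(f"{path}: expected two columns (probe_id, gene_id)")
    mapping: dict[str, str] = {}
    for p, g in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        if p in mapping and mapping[p] != g:
            raise ExpressionParseError(f"{path}: probe {p!r} maps to multiple genes")
        mapping[p] = g
    return ProbeGeneMap(mapping)


def collapse_probes(m: ExpressionMatrix, probe_map: ProbeGeneMap) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by per-sample arithmetic mean.

    Missing probe values are excluded from the mean for that sample; a gene
    whose probes are all missing in a sample stays missing there. Probes not
    present in the map are dropped (with a logged count).
    """
    mapping = probe_map.mapping
    mapped = [i for i, p in enumerate(m.gene_ids) if p in mapping]
    dropped = m.n_genes - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", dropped)
    if not mapped:
        raise ExpressionParseError("no probe in the matrix appears in the map")
    groups: dict[str, list[int]] = {}
    for i in mapped:
        groups.setdefault(mapping[m.gene_ids[i]], []).append(i)
    genes = sorted(groups)
    out = np.empty((len(genes), m.n_samples), dtype=float)
    import warnings

    for r, g in enumerate(genes):
        block = m.values[groups[g]]
        with warnings.catch_warnings():  # all-NaN columns stay NaN, silently
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[r] = np.nanmean(block, axis=0)
    return ExpressionMatrix(genes, list(m.sample_ids), out)


def intersect_genes(ms: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all matrices to their common genes, in lexicographic order.

    Gene symbols are matched case-sensitively. Raises on an empty
    intersection.
    """
    if len(ms) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(ms[0].gene_ids)
    for m in ms[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("empty common gene set")
    order = sorted(common)
    return [m.restrict_genes(order) for m in ms]


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
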