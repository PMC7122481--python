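"""Within-sample relative expression orderings (REO).

The REO of a gene pair (a, b) in one sample is the order relation between
their expression values, Ea > Eb or Ea < Eb. Because the relation only
compares values measured in the same sample, it is invariant under any
per-sample strictly increasing transform — the property that makes REO
features robust to batch effects, platform differences and normalisation
choices.

A pair is *stable* in a group of samples when one direction holds in at
least a threshold fraction (default 95%) of the group's samples. A
*reversal* pair is stable in both phenotype groups with opposite
directions; reversal pairs are the candidate diagnostic features.

Samples are encoded into a ternary profile over {1, 0, -1}: 1 when
Ea > Eb, 0 when Ea < Eb, and -1 when either gene is absent or missing.
Ties (Ea = Eb) count toward neither direction for stability and encode
as 0; the stability denominator is always the full group size, so ties
and missing values count against stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

DIRECTION_GT = "GT"  # Ea > Eb dominant, with (a, b) the canonical pair order
DIRECTION_LT = "LT"

#: separator used in pair-id strings ("geneA|geneB", oriented a|b)
PAIR_SEP = "|"


@dataclass(frozen=True)
class GenePair:
    """Unordered gene pair stored canonically with gene_a < gene_b.

    Direction (which gene dominates) is carried separately, e.g. in
    :class:`REOPairSet`; the pair itself is pure identity.
    """

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"degenerate pair ({self.gene_a!r}, {self.gene_b!r})")
        if self.gene_a > self.gene_b:
            raise ValueError(
                f"pair ({self.gene_a!r}, {self.gene_b!r}) not in canonical "
                "lexicographic order; use GenePair.of"
            )

    @classmethod
    def of(cls, x: str, y: str) -> "GenePair":
        """Construct from genes in any order."""
        if x == y:
            raise ValueError(f"degenerate pair ({x!r}, {y!r})")
        return cls(*sorted((x, y)))


@dataclass(frozen=True)
class PairOrderStats:
    """Exact per-pair order counts across the samples of one matrix."""

    pair: GenePair
    n_gt: int  # samples with Ea > Eb (a = canonical gene_a)
    n_lt: int
    n_tie: int
    n_missing: int

    @property
    def n_samples(self) -> int:
        return self.n_gt + self.n_lt + self.n_tie + self.n_missing


@dataclass
class REOPairSet:
    """A set of gene pairs with dominant direction and per-group consistency.

    ``table`` columns:

    - ``gene_a``, ``gene_b`` — canonical pair identity (gene_a < gene_b);
    - ``direction`` — dominant direction in the reference (positive) group,
      ``"GT"`` meaning Ea > Eb with a = gene_a;
    - ``consistency_pos`` — fraction of reference-group samples showing
      the dominant direction;
    - ``consistency_neg`` — same for the other group (NaN for a
      single-group stable set).

    For a reversal set the two groups' dominant directions are opposite by
    construction, so only the positive-group direction is stored.
    """

    table: pd.DataFrame
    kind: str = "stable"  # "stable" | "reversal"

    COLUMNS = ["gene_a", "gene_b", "direction", "consistency_pos", "consistency_neg"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"pair table missing columns {missing}")
        self.table = (
            self.table[self.COLUMNS]
            .sort_values(["gene_a", "gene_b"], kind="mergesort")
            .reset_index(drop=True)
        )
        bad = self.table["gene_a"] >= self.table["gene_b"]
        if bad.any():
            raise ValueError("pairs must be stored with gene_a < gene_b")

    def __len__(self) -> int:
        return len(self.table)

    def oriented_pairs(self) -> list[tuple[str, str]]:
        """(a, b) per pair, oriented so that Ea > Eb in the reference group."""
        out = []
        for ga, gb, d in zip(
            self.table["gene_a"], self.table["gene_b"], self.table["direction"]
        ):
            out.append((ga, gb) if d == DIRECTION_GT else (gb, ga))
        return out

    def pair_ids(self) -> list[str]:
        return [f"{a}{PAIR_SEP}{b}" for a, b in self.oriented_pairs()]

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.rename(columns={"direction": "direction_pos_group"})
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "reversal") -> "REOPairSet":
        frame = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
        frame = frame.rename(columns={"direction_pos_group": "direction"})
        return cls(frame, kind=kind)

    def subset(self, pair_ids: Sequence[str]) -> "REOPairSet":
        """Restrict to the given oriented pair ids, preserving their order."""
        by_id = {pid: i for i, pid in enumerate(self.pair_ids())}
        rows = [by_id[p] for p in pair_ids]
        sub = self.table.iloc[rows].reset_index(drop=True)
        obj = object.__new__(REOPairSet)
        obj.table = sub  # bypass re-sorting to honour the requested order
        obj.kind = self.kind
        return obj


@dataclass
class REOProfile:
    """Ternary feature matrix (pairs × samples) over {1, 0, -1}."""

    pair_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.pair_ids), len(self.sample_ids)):
            raise ValueError("profile shape does not match pair/sample ids")
        ok = np.isin(self.values, (-1, 0, 1))
        if not ok.all():
            raise ValueError("profile entries must be in {1, 0, -1}")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pair_ids, columns=self.sample_ids)

    def restrict(self, pair_ids: Sequence[str]) -> "REOProfile":
        idx = {p: i for i, p in enumerate(self.pair_ids)}
        missing = [p for p in pair_ids if p not in idx]
        if missing:
            raise KeyError(f"pairs not in profile: {missing[:5]}")
        rows = [idx[p] for p in pair_ids]
        return REOProfile(list(pair_ids), list(self.sample_ids), self.values[rows])

    def write_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "pair_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "REOProfile":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            [str(p) for p in frame.index],
            [str(s) for s in frame.columns],
            frame.to_numpy(dtype=np.int8),
        )


def _order_counts(
    values: np.ndarray, i: int, js: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised GT/LT/tie/missing counts of gene row i against rows js."""
    a = values[i]
    b = values[js]
    miss = np.isnan(a)[None, :] | np.isnan(b)
    with np.errstate(invalid="ignore"):
        n_gt = (a[None, :] > b).sum(axis=1)
        n_lt = (a[None, :] < b).sum(axis=1)
    n_missing = miss.sum(axis=1)
    n_tie = values.shape[1] - n_gt - n_lt - n_missing
    return n_gt, n_lt, n_tie, n_missing


def _lex_rows(m: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    """Gene names sorted lexicographically with the matching row view."""
    order = sorted(range(m.n_genes), key=lambda i: m.gene_ids[i])
    genes = [m.gene_ids[i] for i in order]
    return genes, m.values[order]


def pair_order_stats(
    m: ExpressionMatrix, pair_block: tuple[int, int] | None = None
) -> Iterator[PairOrderStats]:
    """Yield exact order counts for every unordered gene pair.

    Pairs are enumerated over the lexicographically sorted gene list; with
    ``pair_block = (start, stop)`` only pairs whose first (smaller) gene has
    sorted index in ``[start, stop)`` are yielded, so the union over a block
    partition reproduces the whole-matrix enumeration exactly.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes to form pairs")
    genes, values = _lex_rows(m)
    n = len(genes)
    start, stop = pair_block if pair_block is not None else (0, n)
    start, stop = max(0, start), min(stop, n)
    for i in range(start, stop):
        js = np.arange(i + 1, n)
        if js.size == 0:
            continue
        n_gt, n_lt, n_tie, n_missing = _order_counts(values, i, js)
        for k, j in enumerate(js):
            yield PairOrderStats(
                pair=GenePair(genes[i], genes[int(j)]),
                n_gt=int(n_gt[k]),
                n_lt=int(n_lt[k]),
                n_tie=int(n_tie[k]),
                n_missing=int(n_missing[k]),
            )


def find_stable_pairs(
    m: ExpressionMatrix, threshold: float = 0.95, block_size: int = 256
) -> REOPairSet:
    """Detect pairs with one REO direction in ≥ ``threshold`` of all samples.

    The comparison is inclusive (at least 95% by default). The denominator
    is the total sample count: ties and missing values count against
    stability. Enumeration is chunked over gene blocks with bounded memory;
    the result is independent of ``block_size``.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes to form pairs")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    genes, values = _lex_rows(m)
    n, n_samples = len(genes), m.n_samples
    need = threshold * n_samples  # inclusive: count >= need
    rows: list[tuple[str, str, str, float]] = []
    for i in range(n - 1):
        for jstart in range(i + 1, n, block_size):
            js = np.arange(jstart, min(jstart + block_size, n))
            n_gt, n_lt, _, _ = _order_counts(values, i, js)
            # float comparison of count >= threshold*n is safe here because
            # counts are integers; use a tiny epsilon against representation
            # error in threshold*n_samples (e.g. 0.95*20 = 19.000000000000004)
            stable_gt = n_gt >= need - 1e-9
            stable_lt = n_lt >= need - 1e-9
            for k in np.nonzero(stable_gt)[0]:
                rows.append(
                    (genes[i], genes[int(js[k])], DIRECTION_GT, n_gt[k] / n_samples)
                )
            for k in np.nonzero(stable_lt)[0]:
                rows.append(
                    (genes[i], genes[int(js[k])], DIRECTION_LT, n_lt[k] / n_samples)
                )
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "direction", "consistency_pos"])
    table["consistency_neg"] = np.nan
    return REOPairSet(table, kind="stable")


def find_reversal_pairs(stable_pos: REOPairSet, stable_neg: REOPairSet) -> REOPairSet:
    """Pairs stable in both groups with opposite dominant directions.

    The returned set is oriented by the positive group: ``direction`` is the
    dominant direction among positive samples, so encoded features are 1 for
    a typical positive-group sample and 0 for a typical negative-group one.
    """
    pos = stable_pos.table
    neg = stable_neg.table
    merged = pos.merge(
        neg,
        on=["gene_a", "gene_b"],
        suffixes=("_p", "_n"),
    )
    rev = merged[merged["direction_p"] != merged["direction_n"]]
    table = pd.DataFrame(
        {
            "gene_a": rev["gene_a"],
            "gene_b": rev["gene_b"],
            "direction": rev["direction_p"],
            "consistency_pos": rev["consistency_pos_p"].astype(float),
            "consistency_neg": rev["consistency_pos_n"].astype(float),
        }
    )
    return REOPairSet(table, kind="reversal")


def encode_profile(m: ExpressionMatrix, pairs: REOPairSet) -> REOProfile:
    """Encode samples into the ternary REO feature space of ``pairs``.

    Per sample and oriented pair (a, b): 1 if Ea > Eb, 0 if Ea < Eb, and
    -1 if either gene is absent from the matrix or missing in that sample.
    Ties encode as 0. Orientation follows the pair set's reference
    (positive-group) direction.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    idx = m.gene_index()
    out = np.empty((len(pairs), m.n_samples), dtype=np.int8)
    for r, (ga, gb) in enumerate(pairs.oriented_pairs()):
        ia, ib = idx.get(ga), idx.get(gb)
        if ia is None or ib is None:
            out[r] = -1
            continue
        a, b = m.values[ia], m.values[ib]
        miss = np.isnan(a) | np.isnan(b)
        with np.errstate(invalid="ignore"):
            gt = a > b
        row = np.zeros(m.n_samples, dtype=np.int8)
        row[gt] = 1
        row[miss] = -1
        out[r] = row
    return REOProfile(pairs.pair_ids(), list(m.sample_ids), out)
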