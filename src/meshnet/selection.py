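"""MeSH term counting and the routine/emerging filters.

For each Time Period Tn, C(Mi)Tn is the number of publications in Tn whose
heading list contains descriptor Mi — document frequency, so a descriptor
repeated with several qualifiers on one record still counts once.  Two
per-row filters then pick the noteworthy terms:

* **routine removal** — a term positive in every period is broad, routine
  vocabulary for the area (and a strong-hub hazard in co-occurrence
  networks); it is removed.
* **emerging selection** — a term is emerging when its count strictly
  increased from T(N-1) to TN and its final count is at least
  ``min_final_count`` (default 3, i.e. on average once a year over a
  three-year period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus
from .lifetime import TimePeriod

__all__ = [
    "TermCountTable",
    "SelectionConfig",
    "count_mesh_by_period",
    "remove_routine",
    "select_emerging",
]


@dataclass(frozen=True)
class SelectionConfig:
    min_final_count: int = 3

    def __post_init__(self) -> None:
        if self.min_final_count < 0:
            raise ValueError("min_final_count must be >= 0")


@dataclass(frozen=True)
class TermCountTable:
    """Per-term occurrence counts across Time Periods T1..TN.

    ``counts`` has one row per term (same order as ``terms``) and one
    column per period, oldest first.
    """

    terms: tuple[str, ...]
    counts: np.ndarray  # shape (n_terms, N), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != len(self.terms):
            raise ValueError("counts must be (n_terms, N)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate term in table")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]

    def row(self, term: str) -> np.ndarray:
        return self.counts[self.terms.index(term)]

    def to_frame(self, config: SelectionConfig | None = None) -> pd.DataFrame:
        """Inspection table: one row per term, count columns C_T1..C_TN,
        plus routine/emerging flags."""
        config = config or SelectionConfig()
        n = self.n_periods
        df = pd.DataFrame(
            self.counts, index=list(self.terms),
            columns=[f"C_T{i}" for i in range(1, n + 1)],
        )
        df.index.name = "term"
        df["routine"] = (self.counts > 0).all(axis=1)
        if n >= 2:
            df["emerging"] = (self.counts[:, -1] > self.counts[:, -2]) & (
                self.counts[:, -1] >= config.min_final_count
            )
        return df

    def to_tsv(self, path, config: SelectionConfig | None = None) -> None:
        self.to_frame(config).to_csv(path, sep="\t")


def count_mesh_by_period(corpus: Corpus, periods: Sequence[TimePeriod]) -> TermCountTable:
    """Document-frequency counts of every descriptor per Time Period.

    Terms with all-zero vectors (none, by construction, unless the corpus
    extends beyond the periods) are excluded; the emitted set is the
    *initial* MeSH terms.  Term order is lexicographic for reproducible
    downstream matrices.
    """
    if not periods:
        raise ValueError("periods must be non-empty")
    year_to_col = {y: i for i, p in enumerate(periods) for y in p.years}
    tally: dict[str, np.ndarray] = {}
    for record in corpus:
        col = year_to_col.get(record.year)
        if col is None:
            continue
        for descriptor in record.descriptors:
            row = tally.get(descriptor)
            if row is None:
                row = tally[descriptor] = np.zeros(len(periods), dtype=np.int64)
            row[col] += 1
    terms = tuple(sorted(t for t, v in tally.items() if v.any()))
    counts = (
        np.vstack([tally[t] for t in terms])
        if terms
        else np.zeros((0, len(periods)), dtype=np.int64)
    )
    return TermCountTable(terms, counts)


def remove_routine(table: TermCountTable) -> TermCountTable:
    """Drop every term positive in all N periods; all other rows unchanged.

    Undefined for N = 1, where every observed term is trivially "present
    in all periods" and the rule would empty the table.
    """
    if table.n_periods < 2:
        raise ValueError(
            "routine removal needs at least 2 time periods: with N=1 every "
            "term is present in all periods and the rule degenerates"
        )
    keep = ~(table.counts > 0).all(axis=1)
    return TermCountTable(
        tuple(t for t, k in zip(table.terms, keep) if k), table.counts[keep]
    )


def select_emerging(
    table: TermCountTable, config: SelectionConfig | None = None
) -> list[str]:
    """Terms with C(TN) - C(TN-1) > 0 and C(TN) >= min_final_count.

    Returned in descending final-period count, ties broken by ascending
    descriptor string.
    """
    config = config or SelectionConfig()
    if table.n_periods < 2:
        raise ValueError("emerging selection needs at least 2 time periods")
    final = table.counts[:, -1]
    prev = table.counts[:, -2]
    picked = [
        (term, int(c))
        for term, c, p in zip(table.terms, final, prev)
        if c - p > 0 and c >= config.min_final_count
    ]
    picked.sort(key=lambda tc: (-tc[1], tc[0]))
    return [term for term, _ in picked]
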