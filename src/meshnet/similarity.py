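"""Title-keyword profiles and MeSH-term correlation matrices.

Two MeSH terms that index publications with similar titles are about the
same thing, even when they never share a publication.  Correlating terms by
the cosine similarity of their title-keyword profiles, instead of by raw
co-occurrence counts, avoids the strong-hub bias that query terms, trendy
terms and other near-ubiquitous descriptors impose on co-word networks.

For the final Time Period TN, the MeSH-TK matrix has one row V(Mi) per
MeSH term and one column per title keyword TKk over the whole retrieved
set (K columns); entry C(TKk|Mi) is the number of TN publications that
both carry Mi and contain TKk in their title.  Correlation is then

    Sim(Mi, Mj) = V(Mi) . V(Mj) / (|V(Mi)| |V(Mj)|)

with similarity 0 when either profile is empty.  The conventional
co-occurrence matrix (publications carrying both terms) is kept as a
baseline mode for comparison.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Corpus

__all__ = [
    "MeshTkMatrix",
    "SimilarityMatrix",
    "load_stopwords",
    "extract_keywords",
    "build_mesh_tk_matrix",
    "cosine_similarity",
    "similarity_matrix",
    "cooccurrence_matrix",
]

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")


def load_stopwords() -> frozenset[str]:
    """The versioned stopword list shipped with the package."""
    text = resources.files("meshnet").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def stopwords_sha256() -> str:
    """Checksum of the shipped stopword list, for reproducibility audits."""
    data = resources.files("meshnet").joinpath("stopwords.txt").read_bytes()
    return hashlib.sha256(data).hexdigest()


_STOPWORDS = None


def _stopwords() -> frozenset[str]:
    global _STOPWORDS
    if _STOPWORDS is None:
        _STOPWORDS = load_stopwords()
    return _STOPWORDS


def extract_keywords(title: str, stopwords: frozenset[str] | None = None) -> set[str]:
    """Normalized title keywords: unigrams plus noun phrases.

    Lowercase, punctuation stripped, stopwords dropped.  Stopwords act as
    phrase boundaries: each maximal run of consecutive content tokens is a
    noun phrase (emitted when at least two tokens long), and every content
    token is also a unigram keyword.  Set semantics per title — a repeated
    word counts once.  No stemming or lemmatization: merging variants
    would silently change the keyword vocabulary K.
    """
    if not title:
        raise ValueError("title must be non-empty")
    if stopwords is None:
        stopwords = _stopwords()
    tokens = [t for t in _TOKEN_SPLIT.split(title.lower()) if t]
    keywords: set[str] = set()
    run: list[str] = []
    for token in tokens + [""]:  # sentinel flushes the last run
        if token and token not in stopwords:
            run.append(token)
            continue
        if run:
            keywords.update(run)
            if len(run) >= 2:
                keywords.add(" ".join(run))
            run = []
    return keywords


@dataclass(frozen=True)
class MeshTkMatrix:
    """MeSH x title-keyword count matrix for the final Time Period."""

    terms: tuple[str, ...]
    keywords: tuple[str, ...]
    counts: np.ndarray  # shape (n_terms, K)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.terms), len(self.keywords)):
            raise ValueError("counts shape must be (n_terms, K)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def k(self) -> int:
        return len(self.keywords)

    def vector(self, term: str) -> np.ndarray:
        """The title-keyword profile V(Mi)."""
        return self.counts[self.terms.index(term)]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric term-by-term correlation matrix.

    ``mode`` is ``"title"`` (cosine of title-keyword profiles, values in
    [0, 1]) or ``"cooccurrence"`` (integer publication co-occurrence
    counts, the conventional baseline).
    """

    terms: tuple[str, ...]
    values: np.ndarray
    mode: str = "title"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.terms)
        if values.shape != (n, n):
            raise ValueError("values must be square over terms")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.mode not in ("title", "cooccurrence"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "values", values)

    def value(self, term_i: str, term_j: str) -> float:
        return float(
            self.values[self.terms.index(term_i), self.terms.index(term_j)]
        )

    def to_tsv(self, path) -> None:
        """Long-format export: one (term_i, term_j, value) line per
        unordered pair with i < j."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term_i\tterm_j\tvalue\n")
            for i, ti in enumerate(self.terms):
                for j in range(i + 1, len(self.terms)):
                    fh.write(f"{ti}\t{self.terms[j]}\t{self.values[i, j]:.10g}\n")


def corpus_keywords(corpus: Corpus, stopwords: frozenset[str] | None = None) -> set[str]:
    """All distinct keywords over a corpus' titles (defines K when taken
    over the whole retrieved set)."""
    keywords: set[str] = set()
    for record in corpus:
        if record.title:
            keywords |= extract_keywords(record.title, stopwords)
    return keywords


def build_mesh_tk_matrix(
    corpus_tn: Corpus,
    mesh_terms: Sequence[str],
    vocabulary: Iterable[str] | None = None,
    stopwords: frozenset[str] | None = None,
) -> MeshTkMatrix:
    """MeSH-TK co-occurrence matrix over the final-period publications.

    ``vocabulary`` should be the keyword set of the WHOLE retrieved corpus
    (it defines K); when omitted it is computed from ``corpus_tn`` alone.
    Each entry counts publications (binary per title): a publication adds 1
    to C(TKk|Mi) when it carries Mi and its title contains TKk.  A term
    with no final-period publication keeps a zero row, with a warning.
    """
    if not mesh_terms:
        raise ValueError("mesh_terms must be non-empty")
    if vocabulary is None:
        vocabulary = corpus_keywords(corpus_tn, stopwords)
    keywords = tuple(sorted(set(vocabulary)))
    kw_col = {kw: j for j, kw in enumerate(keywords)}
    term_row = {t: i for i, t in enumerate(mesh_terms)}
    counts = np.zeros((len(mesh_terms), len(keywords)), dtype=np.int64)
    for record in corpus_tn:
        rows = [term_row[d] for d in record.descriptors if d in term_row]
        if not rows or not record.title:
            continue
        cols = [kw_col[kw] for kw in extract_keywords(record.title, stopwords) if kw in kw_col]
        for i in rows:
            counts[i, cols] += 1
    empty = [t for t, i in term_row.items() if not counts[i].any()]
    if empty:
        warnings.warn(
            f"{len(empty)} MeSH term(s) have empty title-keyword profiles "
            f"(no final-period publication or title): {empty[:5]}",
            stacklevel=2,
        )
    return MeshTkMatrix(tuple(mesh_terms), keywords, counts)


def cosine_similarity(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """Cosine of two keyword-profile vectors; 0 when either is all-zero
    (no shared vocabulary, hence no edge)."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError(f"length mismatch: {v_i.shape} vs {v_j.shape}")
    ni = np.linalg.norm(v_i)
    nj = np.linalg.norm(v_j)
    if ni == 0.0 or nj == 0.0:
        return 0.0
    return float(np.dot(v_i, v_j) / (ni * nj))


def similarity_matrix(matrix: MeshTkMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity over all MeSH-term profile rows."""
    if len(matrix.terms) < 2:
        raise ValueError("need at least 2 MeSH terms")
    profiles = matrix.counts.astype(float)
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    normalized = profiles / safe[:, None]
    values = normalized @ normalized.T
    np.clip(values, 0.0, 1.0, out=values)
    values = (values + values.T) / 2.0  # exact symmetry
    np.fill_diagonal(values, np.where(norms > 0.0, 1.0, 0.0))
    return SimilarityMatrix(matrix.terms, values, mode="title")


def cooccurrence_matrix(corpus_tn: Corpus, mesh_terms: Sequence[str]) -> SimilarityMatrix:
    """Conventional baseline: entry (i, j) is the number of final-period
    publications carrying both Mi and Mj; the diagonal is each term's
    document frequency."""
    if not mesh_terms:
        raise ValueError("mesh_terms must be non-empty")
    term_row = {t: i for i, t in enumerate(mesh_terms)}
    n = len(mesh_terms)
    values = np.zeros((n, n), dtype=float)
    for record in corpus_tn:
        rows = sorted(term_row[d] for d in record.descriptors if d in term_row)
        for a, i in enumerate(rows):
            for j in rows[a:]:
                values[i, j] += 1
                if i != j:
                    values[j, i] += 1
    return SimilarityMatrix(tuple(mesh_terms), values, mode="cooccurrence")


def export_mtx(matrix: MeshTkMatrix, prefix) -> None:
    """Sparse MatrixMarket export plus row/column label files
    (``<prefix>.mtx``, ``<prefix>.rows.txt``, ``<prefix>.cols.txt``)."""
    from pathlib import Path

    import scipy.io
    import scipy.sparse

    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")),
                     scipy.sparse.csr_matrix(matrix.counts))
    prefix.with_suffix(".rows.txt").write_text(
        "\n".join(matrix.terms) + "\n", encoding="utf-8")
    prefix.with_suffix(".cols.txt").write_text(
        "\n".join(matrix.keywords) + "\n", encoding="utf-8")
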