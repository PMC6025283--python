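"""Synthetic corpora with planted term dynamics and clustered vocabularies.

The generator emulates the two structures the pipeline exploits: per-term
occurrence trajectories across three-year Time Periods (routine terms
positive everywhere, emerging terms rising into the final period with a
final count of at least 3, transient terms neither) and clustered title
vocabularies (each cluster of MeSH terms writes its titles from a private
keyword pool, so related terms have overlapping title-keyword profiles and
unrelated ones, at zero noise, share no vocabulary at all).

Every publication slot in a period belongs to exactly one pool — one per
vocabulary cluster, plus a generic pool with filler vocabulary — and a
term's planted documents are drawn from its cluster's pool only.  Titles
start with the cluster's anchor keyword, guaranteeing that same-cluster
profiles always overlap.  *Query* terms are special: they are planted
across all pools (up to every publication of a period), emulating a
search-query term that indexes the entire retrieved set and acts as a
strong hub under co-occurrence correlation.

A single :class:`numpy.random.Generator` seeded from ``spec.seed`` drives
everything; equal specs produce byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus_io import Corpus, MeshHeading, PublicationRecord

__all__ = ["VocabularyCluster", "CorpusSpec", "GroundTruth", "generate",
           "default_spec", "hub_fixture_spec"]

Trajectory = tuple[int, ...]

FILLER_VOCABULARY = (
    "study", "analysis", "patients", "clinical", "cohort",
    "report", "evaluation", "survey", "outcomes", "series",
)

_PAD = ("the", "of", "in", "and")  # stopword padding between keywords


@dataclass(frozen=True)
class VocabularyCluster:
    """A set of title keywords shared by a set of MeSH terms.  The first
    keyword is the anchor, present in every title of the cluster."""

    name: str
    keywords: tuple[str, ...]
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.keywords) < 2:
            raise ValueError(f"cluster {self.name}: need an anchor plus >=1 keyword")
        if not self.terms:
            raise ValueError(f"cluster {self.name}: no terms attached")


@dataclass(frozen=True)
class CorpusSpec:
    """Declarative description of a synthetic corpus.

    Trajectories are per-period document counts, oldest period first; each
    role's defining inequalities are validated up front:

    * routine    — positive in every period;
    * emerging   — final count > previous count, final count >= 3, and at
      least one zero period (otherwise the routine filter would remove it);
    * transient  — neither routine nor emerging;
    * query      — planted across ALL pools, any trajectory (the hub
      pathology needs a final count equal to the period's publication count).
    """

    n_periods: int = 5
    window_years: int = 3
    y_last: int = 2016
    pubs_per_period: tuple[int, ...] = (34, 48, 64, 96, 144)
    routine: Mapping[str, Trajectory] = field(default_factory=dict)
    emerging: Mapping[str, Trajectory] = field(default_factory=dict)
    transient: Mapping[str, Trajectory] = field(default_factory=dict)
    query: Mapping[str, Trajectory] = field(default_factory=dict)
    clusters: tuple[VocabularyCluster, ...] = ()
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pubs_per_period) != self.n_periods:
            raise ValueError("pubs_per_period must have n_periods entries")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        for role, trajectories in (("routine", self.routine),
                                   ("emerging", self.emerging),
                                   ("transient", self.transient),
                                   ("query", self.query)):
            for term, traj in trajectories.items():
                if len(traj) != self.n_periods:
                    raise ValueError(f"{term}: trajectory length != n_periods")
                if any(c < 0 for c in traj):
                    raise ValueError(f"{term}: negative count")
                self._check_role(role, term, tuple(traj))
        all_terms = list(self.routine) + list(self.emerging) + list(self.transient) + list(self.query)
        if len(set(all_terms)) != len(all_terms):
            raise ValueError("a term may carry only one role")
        clustered = [t for c in self.clusters for t in c.terms]
        if len(set(clustered)) != len(clustered):
            raise ValueError("a term may belong to only one cluster")
        unknown = set(clustered) - set(all_terms)
        if unknown:
            raise ValueError(f"clustered terms without a trajectory: {sorted(unknown)}")
        words = [w for c in self.clusters for kw in c.keywords for w in kw.split()]
        if len(set(words)) != len(words):
            raise ValueError("cluster vocabularies must not share words")
        if set(words) & set(FILLER_VOCABULARY):
            raise ValueError("cluster vocabularies must not reuse filler words")
        self._check_feasible()

    @staticmethod
    def _check_role(role: str, term: str, traj: Trajectory) -> None:
        is_routine = all(c > 0 for c in traj)
        is_emerging = len(traj) >= 2 and traj[-1] > traj[-2] and traj[-1] >= 3
        if role == "routine" and not is_routine:
            raise ValueError(f"{term}: routine trajectory must be positive everywhere")
        if role == "emerging":
            if not is_emerging:
                raise ValueError(f"{term}: emerging trajectory must rise into the "
                                 f"final period with final count >= 3")
            if is_routine:
                raise ValueError(f"{term}: emerging trajectory needs a zero period "
                                 f"(all-positive terms are routine)")
        if role == "transient" and (is_routine or is_emerging):
            raise ValueError(f"{term}: transient trajectory must be neither "
                             f"routine nor emerging: {traj}")

    def _cluster_of(self) -> dict[str, VocabularyCluster | None]:
        lookup: dict[str, VocabularyCluster | None] = {}
        for role in (self.routine, self.emerging, self.transient, self.query):
            for term in role:
                lookup[term] = None
        for cluster in self.clusters:
            for term in cluster.terms:
                lookup[term] = cluster
        return lookup

    def _pool_needs(self, period: int) -> dict[str, int]:
        """Slots each pool must hold in one period: the max planted count
        among the pool's terms (terms of one pool may share publications)."""
        lookup = self._cluster_of()
        needs = {c.name: 0 for c in self.clusters}
        needs["__generic__"] = 0
        for role in (self.routine, self.emerging, self.transient):
            for term, traj in role.items():
                cluster = lookup[term]
                pool = cluster.name if cluster is not None else "__generic__"
                needs[pool] = max(needs[pool], traj[period])
        return needs

    def _check_feasible(self) -> None:
        for p, pubs in enumerate(self.pubs_per_period):
            total = sum(self._pool_needs(p).values())
            if total > pubs:
                raise ValueError(
                    f"infeasible spec: period {p + 1} needs {total} planted "
                    f"publications but has only {pubs}"
                )
            for term, traj in self.query.items():
                if traj[p] > pubs:
                    raise ValueError(
                        f"infeasible spec: query term {term} needs {traj[p]} "
                        f"publications in period {p + 1}, only {pubs} exist"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """Planted facts about a generated corpus."""

    roles: dict[str, str]            # term -> routine|emerging|transient|query
    cluster_of: dict[str, str | None]
    trajectories: dict[str, Trajectory]

    @property
    def routine_terms(self) -> frozenset[str]:
        return frozenset(t for t, r in self.roles.items() if r == "routine")

    @property
    def emerging_terms(self) -> frozenset[str]:
        return frozenset(t for t, r in self.roles.items() if r == "emerging")


def _make_title(rng: np.random.Generator, keywords: tuple[str, ...],
                anchor: str | None, noise_pool: tuple[str, ...],
                noise_rate: float) -> str:
    picks = list(rng.choice(len(keywords), size=min(2, len(keywords)), replace=False))
    chosen = ([anchor] if anchor else []) + [keywords[i] for i in picks]
    if noise_pool and rng.random() < noise_rate:
        chosen.append(noise_pool[int(rng.integers(len(noise_pool)))])
    parts = [_PAD[0], chosen[0]]
    for i, kw in enumerate(chosen[1:], start=1):
        parts += [_PAD[i % len(_PAD)], kw]
    return " ".join(parts)


def generate(spec: CorpusSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus realizing ``spec`` exactly.

    Per-term per-period document counts match the planted trajectories
    exactly (recounting the output reproduces the spec), and publication
    years tile each period's calendar window evenly so annual counts are
    balanced.
    """
    rng = np.random.default_rng(spec.seed)
    lookup = spec._cluster_of()
    records: list[PublicationRecord] = []
    w = spec.window_years

    for p in range(spec.n_periods):
        pubs = spec.pubs_per_period[p]
        start_year = spec.y_last - (spec.n_periods - p) * w + 1
        headings: list[list[str]] = [[] for _ in range(pubs)]
        pools: dict[str, list[int]] = {}
        order = list(rng.permutation(pubs))
        cursor = 0
        needs = spec._pool_needs(p)
        for cluster in spec.clusters:
            pools[cluster.name] = order[cursor : cursor + needs[cluster.name]]
            cursor += needs[cluster.name]
        pools["__generic__"] = order[cursor:]

        for role in (spec.routine, spec.emerging, spec.transient):
            for term, traj in role.items():
                if traj[p] == 0:
                    continue
                cluster = lookup[term]
                pool = pools[cluster.name if cluster is not None else "__generic__"]
                picked = rng.choice(len(pool), size=traj[p], replace=False)
                for i in picked:
                    headings[pool[i]].append(term)
        for term, traj in spec.query.items():
            if traj[p] == 0:
                continue
            picked = rng.choice(pubs, size=traj[p], replace=False)
            for i in picked:
                headings[int(i)].append(term)

        slot_cluster: dict[int, VocabularyCluster] = {}
        for cluster in spec.clusters:
            for slot in pools[cluster.name]:
                slot_cluster[slot] = cluster
        for slot in range(pubs):
            cluster = slot_cluster.get(slot)
            if cluster is not None:
                off_cluster = tuple(
                    kw for c in spec.clusters if c.name != cluster.name
                    for kw in c.keywords
                )
                title = _make_title(rng, cluster.keywords[1:], cluster.keywords[0],
                                    off_cluster, spec.noise_rate)
            else:
                all_cluster_kw = tuple(kw for c in spec.clusters for kw in c.keywords)
                title = _make_title(rng, FILLER_VOCABULARY, None,
                                    all_cluster_kw, spec.noise_rate)
            records.append(
                PublicationRecord(
                    pmid=f"SYN{p + 1:02d}{slot:05d}",
                    title=title,
                    year=start_year + slot % w,
                    headings=tuple(
                        MeshHeading(d) for d in sorted(set(headings[slot]))
                    ),
                )
            )

    roles: dict[str, str] = {}
    for role_name, mapping in (("routine", spec.routine), ("emerging", spec.emerging),
                               ("transient", spec.transient), ("query", spec.query)):
        for term in mapping:
            roles[term] = role_name
    truth = GroundTruth(
        roles=roles,
        cluster_of={t: (c.name if c else None) for t, c in lookup.items()},
        trajectories={t: tuple(traj)
                      for m in (spec.routine, spec.emerging, spec.transient, spec.query)
                      for t, traj in m.items()},
    )
    corpus = Corpus(records, provenance=f"synthetic(seed={spec.seed})")
    return corpus, truth


def default_spec(seed: int = 0, noise_rate: float = 0.0) -> CorpusSpec:
    """The study-condition spec used throughout the test suite: five
    three-year periods with rising publication volume (first-period annual
    average just above the eligibility threshold of 10), three routine
    terms, two vocabulary clusters of four emerging terms each, and three
    transient terms."""
    cluster_a = VocabularyCluster(
        name="checkpoint",
        keywords=("checkpoint", "immune", "blockade", "inhibitor",
                  "lymphocyte", "antigen"),
        terms=("CTLA-4 Antigen", "Immune Checkpoint Inhibitors",
               "Lymphocyte Activation", "Programmed Cell Death 1 Receptor"),
    )
    cluster_b = VocabularyCluster(
        name="stroma",
        keywords=("stromal", "fibroblast", "matrix", "angiogenesis",
                  "vessel", "hypoxia"),
        terms=("Cancer-Associated Fibroblasts", "Extracellular Matrix",
               "Neovascularization, Pathologic", "Tumor Hypoxia"),
    )
    return CorpusSpec(
        routine={
            "Neoplasms": (3, 4, 5, 6, 7),
            "Humans": (6, 8, 10, 12, 16),
            "Immunotherapy": (2, 2, 3, 4, 5),
        },
        emerging={
            "CTLA-4 Antigen": (0, 0, 1, 2, 6),
            "Immune Checkpoint Inhibitors": (0, 0, 0, 2, 5),
            "Lymphocyte Activation": (0, 1, 1, 3, 7),
            "Programmed Cell Death 1 Receptor": (0, 0, 0, 0, 4),
            "Cancer-Associated Fibroblasts": (0, 0, 1, 1, 5),
            "Extracellular Matrix": (0, 0, 0, 3, 8),
            "Neovascularization, Pathologic": (0, 1, 2, 2, 6),
            "Tumor Hypoxia": (0, 0, 0, 1, 3),
        },
        transient={
            "Mice": (0, 3, 2, 1, 1),
            "Cell Line": (1, 0, 4, 4, 2),
            "Adjuvants, Immunologic": (0, 2, 0, 5, 0),
        },
        clusters=(cluster_a, cluster_b),
        noise_rate=noise_rate,
        seed=seed,
    )


def hub_fixture_spec(seed: int = 0) -> CorpusSpec:
    """A constructed fixture reproducing the strong-hub pathology: the
    query term indexes EVERY final-period publication, so under
    co-occurrence correlation it is linked to every other term, while its
    title-keyword profile is a bland mixture of all clusters."""
    base = default_spec(seed=seed)
    clusters = base.clusters + (
        VocabularyCluster(
            name="vector",
            keywords=("oncolytic", "virus", "vector", "transduction", "capsid"),
            terms=("Genetic Vectors", "Oncolytic Viruses", "Transduction, Genetic"),
        ),
    )
    emerging = dict(base.emerging)
    emerging.update({
        "Genetic Vectors": (0, 0, 1, 2, 6),
        "Oncolytic Viruses": (0, 0, 0, 1, 4),
        "Transduction, Genetic": (0, 1, 0, 2, 5),
    })
    return CorpusSpec(
        pubs_per_period=base.pubs_per_period,
        routine=base.routine,
        emerging=emerging,
        transient=base.transient,
        query={"Tumor Microenvironment": (0, 0, 10, 40, base.pubs_per_period[-1])},
        clusters=clusters,
        noise_rate=0.0,
        seed=seed,
    )
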