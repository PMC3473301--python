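"""Training-set construction from a multi-strain pangenome.

Positives are highly conserved ORFs (HCOs): ORFs from all strains of a
species are clustered in an undirected similarity graph built from pairwise
alignment-bitscore distances, clusters covering every genome of the species
are kept, and each cluster's medoid represents it.  Negatives are the five
out-of-frame readings of each Positive's interior — the sequences a gene
finder must learn to reject.  Both classes are preprocessed by removing the
leading start codon and all in-frame stop codons, so classification rests on
content rather than endpoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .alphabets import (
    DegenerateSequenceError,
    LabeledOrf,
    reverse_complement,
    strip_start_and_stops,
)

__all__ = [
    "BitscoreTable",
    "HcoCluster",
    "pairwise_distance",
    "build_graph",
    "extract_hcos",
    "sample_positives",
    "make_negatives",
    "split_folds",
    "DEFAULT_THRESHOLD",
    "DEFAULT_POSITIVE_CAP",
]

log = logging.getLogger(__name__)

#: distance threshold for graph edges: clustered sequences are roughly
#: 100(1-t)% = 70% similar
DEFAULT_THRESHOLD = 0.3
#: at most this many Positives are sampled per species
DEFAULT_POSITIVE_CAP = 400


def pairwise_distance(s_ij: float, s_ji: float, s_ii: float, s_jj: float) -> float:
    """Bitscore distance d(i,j) = 1 - (s(i;j)+s(j;i)) / (s(i;i)+s(j;j)).

    Symmetric in (i,j); 0 for identical sequences, 1 when there is no
    alignment in either direction.  Clamped to [0, 1].
    """
    if min(s_ij, s_ji, s_ii, s_jj) < 0:
        raise ValueError("bitscores must be non-negative")
    denom = s_ii + s_jj
    if denom <= 0:
        raise ValueError("self-score sum s(i;i)+s(j;j) must be positive")
    return float(min(1.0, max(0.0, 1.0 - (s_ij + s_ji) / denom)))


@dataclass
class BitscoreTable:
    """All-vs-all pairwise alignment bitscores s(query; subject).

    A missing reciprocal hit is treated as bitscore 0 (distance toward 1).
    Self-scores must be present and positive for every ORF involved.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, query: str, subject: str, bitscore: float) -> None:
        if bitscore < 0:
            raise ValueError("bitscore must be non-negative")
        self.entries[(query, subject)] = float(bitscore)

    def score(self, query: str, subject: str) -> float:
        return self.entries.get((query, subject), 0.0)

    def self_score(self, orf_id: str) -> float:
        s = self.entries.get((orf_id, orf_id), 0.0)
        if s <= 0:
            raise ValueError(f"missing or non-positive self-score for {orf_id!r}")
        return s

    def distance(self, i: str, j: str) -> float:
        if i == j:
            return 0.0
        return pairwise_distance(
            self.score(i, j), self.score(j, i), self.self_score(i), self.self_score(j)
        )

    def ids(self) -> list[str]:
        return sorted({q for q, s in self.entries if q == s})


@dataclass
class HcoCluster:
    """A highly conserved ORF: one similarity cluster covering all genomes."""

    member_ids: list[str]
    genomes_covered: set[str]
    medoid_id: str


def build_graph(
    node_genomes: dict[str, str],
    distances: "BitscoreTable | dict[tuple[str, str], float]",
    t: float = DEFAULT_THRESHOLD,
) -> nx.Graph:
    """Similarity graph: nodes are ORFs, an edge iff d(i,j) <= t.

    ``distances`` is either a BitscoreTable (all pairs evaluated through the
    bitscore distance) or an explicit mapping of unordered pairs to
    distances (absent pairs count as distance 1, no edge).
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold t must lie in [0, 1]")
    g = nx.Graph(threshold=t)
    ids = sorted(node_genomes)
    for orf_id in ids:
        g.add_node(orf_id, genome=node_genomes[orf_id])
    if isinstance(distances, BitscoreTable):
        pair_iter = (
            (a, b, distances.distance(a, b))
            for k, a in enumerate(ids)
            for b in ids[k + 1 :]
        )
    else:
        norm = {}
        for (a, b), d in distances.items():
            norm[(a, b) if a <= b else (b, a)] = d
        pair_iter = ((a, b, d) for (a, b), d in norm.items())
    for a, b, d in pair_iter:
        if not 0 <= d <= 1:
            raise ValueError(f"distance d({a},{b})={d} outside [0, 1]")
        if d <= t:
            g.add_edge(a, b, weight=d)
    return g


def extract_hcos(
    graph: nx.Graph,
    genome_set: set[str],
    distance_fn=None,
) -> list[HcoCluster]:
    """Connected components covering every genome of the species, with medoids.

    Cluster growth is transitive, so two members may be farther apart than
    the threshold; the medoid minimizes the sum of pairwise distances to all
    other members, computed with ``distance_fn(i, j)`` when given (e.g.
    ``BitscoreTable.distance``) and otherwise from edge weights (missing
    edges counting as distance 1).
    """
    if not genome_set:
        raise ValueError("genome_set must be non-empty")
    for n, data in graph.nodes(data=True):
        if data.get("genome") not in genome_set:
            raise ValueError(f"node {n!r} tagged with genome outside the species set")

    def edge_dist(i: str, j: str) -> float:
        if graph.has_edge(i, j):
            return graph[i][j]["weight"]
        return 1.0

    dist = distance_fn if distance_fn is not None else edge_dist
    hcos: list[HcoCluster] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        covered = {graph.nodes[m]["genome"] for m in members}
        if covered != set(genome_set):
            continue
        sums = {
            m: sum(dist(m, o) for o in members if o != m) for m in members
        }
        medoid = min(members, key=lambda m: (sums[m], m))
        hcos.append(HcoCluster(member_ids=members, genomes_covered=covered,
                               medoid_id=medoid))
    hcos.sort(key=lambda h: h.medoid_id)
    return hcos


def sample_positives(
    hcos: list[HcoCluster],
    sequences: dict[str, str],
    genome_of: dict[str, str],
    species_id: str,
    cap: int = DEFAULT_POSITIVE_CAP,
    seed: int = 0,
) -> list[LabeledOrf]:
    """Medoid sequences of the HCOs as Positives (label +1), capped.

    If the species has more than ``cap`` HCOs, a uniform random sample of
    size ``cap`` is drawn (seeded).  Sequences are preprocessed with
    ``strip_start_and_stops``; the raw interior is kept on the record so the
    out-of-frame Negatives can be derived from it.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if not hcos:
        raise ValueError(f"no HCOs for species {species_id!r}")
    chosen = hcos
    if len(hcos) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(hcos), size=cap, replace=False)
        chosen = [hcos[i] for i in sorted(idx)]
    out = []
    for h in chosen:
        raw = sequences[h.medoid_id]
        out.append(
            LabeledOrf(
                species_id=species_id,
                genome_id=genome_of[h.medoid_id],
                orf_id=h.medoid_id,
                residues=strip_start_and_stops(raw),
                label=+1,
                raw_residues=raw,
            )
        )
    return out


def make_negatives(positive: LabeledOrf) -> list[LabeledOrf]:
    """The 5 out-of-frame readings of a Positive's interior, as Negatives.

    Same-strand offsets +1 and +2, and the three reading frames of the
    reverse complement, each trimmed to whole codons and then start/stop
    stripped.  Out-of-frame readings contain spurious stop codons, which is
    why stripping is applied to both classes.  A frame left empty by
    stripping is dropped with a warning (fewer than 5 only then).
    """
    raw = positive.raw_residues if positive.raw_residues is not None else positive.residues
    rc = reverse_complement(raw)
    frames = [
        ("fwd1", raw[1:]),
        ("fwd2", raw[2:]),
        ("rev0", rc),
        ("rev1", rc[1:]),
        ("rev2", rc[2:]),
    ]
    out = []
    for tag, seq in frames:
        try:
            stripped = strip_start_and_stops(seq)
        except DegenerateSequenceError:
            warnings.warn(
                f"{positive.orf_id}: out-of-frame reading {tag} degenerate, dropped",
                stacklevel=2,
            )
            continue
        out.append(
            LabeledOrf(
                species_id=positive.species_id,
                genome_id=positive.genome_id,
                orf_id=f"{positive.orf_id}:{tag}",
                residues=stripped,
                label=-1,
            )
        )
    return out


def split_folds(
    data: list[LabeledOrf], folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Random stratified partition into near-equal folds.

    Positives and Negatives are each divided into near-equal subsets so
    every fold sees both classes in the training design's 1:5 ratio.
    Returns the fold index (0..folds-1) of each item.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.array([o.label for o in data])
    if len(data) < folds:
        raise ValueError("fewer items than folds")
    for cls in (+1, -1):
        if 0 < (labels == cls).sum() < folds:
            raise ValueError(f"fewer items of class {cls:+d} than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(data), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(data)), labels)):
        assignment[test_idx] = fold
    return assignment
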