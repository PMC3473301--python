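"""Synthetic multi-strain pangenomes with planted structure.

Every other module is testable without external genome downloads: the
generator emulates what the real training data look like — gene families
conserved across all strains of a species (bounded divergence), a
genome-wide species-specific codon usage (codon bias, GC-tilted), and
negatives arising as the out-of-frame readings of positives.  A toy
shared-k-mer scorer stands in for an all-against-all reciprocal alignment
search and feeds the bitscore-distance clustering.

The generator is deliberately simple: no phylogeny (strains are independent
draws from the ancestor), no indels, no intergenic sequence and no
horizontal transfer.  What it guarantees is a planted truth table (family
membership per ORF) against which cluster recovery can be scored exactly,
and tunable codon-usage contrast between classes for classifier power
checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .alphabets import CODON, LabeledOrf, strip_start_and_stops
from .dataset import BitscoreTable, make_negatives

__all__ = [
    "SimulationConfig",
    "Pangenome",
    "draw_codon_usage",
    "generate_pangenome",
    "generate_bitscores",
    "make_classification_fixture",
    "make_null_fixture",
    "planted_performance_panel",
]

log = logging.getLogger(__name__)

_STOPS_FOR_ANCESTOR = ("TAA", "TAG", "TGA")
_GC = np.array([(c.count("G") + c.count("C")) / 3.0 for c in CODON.symbols])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pangenome panel.

    Defaults mirror the real study's design: 12 species, several genomes
    per species (the studied species had 4-25), up to 400 conserved gene
    families per species, gene lengths of a few hundred codons, moderate
    within-species divergence (well below the clustering threshold) and a
    species-level codon bias drawn from a Dirichlet with mean concentration
    ``codon_usage_concentration`` per codon (smaller = stronger bias).
    """

    n_species: int = 12
    strains_per_species: int = 6
    families_per_species: int = 400
    family_length_range: tuple[int, int] = (100, 400)  # codons, incl. start/stop
    codon_usage_concentration: float = 5.0
    within_family_divergence: float = 0.02  # per-codon resampling probability
    gc_target: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.within_family_divergence < 0.75:
            raise ValueError("divergence must lie in [0, 0.75)")
        if self.family_length_range[0] < 20:
            raise ValueError("family lengths must be >= 20 codons")
        if self.family_length_range[0] > self.family_length_range[1]:
            raise ValueError("invalid length range")
        if min(self.n_species, self.strains_per_species,
               self.families_per_species) < 1:
            raise ValueError("all counts must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must lie in (0, 1)")
        if self.codon_usage_concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class Pangenome:
    """Generated sequences plus the planted truth table."""

    # species -> genome -> orf_id -> sequence (with start and stop codon)
    sequences: dict[str, dict[str, dict[str, str]]]
    # columns: species, genome, orf_id, family
    truth: pd.DataFrame
    config: SimulationConfig

    def species_ids(self) -> list[str]:
        return sorted(self.sequences)

    def genome_ids(self, species: str) -> list[str]:
        return sorted(self.sequences[species])

    def orfs_of_species(self, species: str) -> dict[str, str]:
        out = {}
        for genome in self.sequences[species].values():
            out.update(genome)
        return out


def draw_codon_usage(
    rng: np.random.Generator, concentration: float, gc_target: float
) -> np.ndarray:
    """Species codon-usage distribution over the 61 sense codons.

    Dirichlet draw whose base measure tilts each codon by the product of
    GC-biased per-base probabilities, so the expected usage honors the
    genomic GC target while the concentration controls how skewed the
    realized synonymous preferences are.
    """
    base_p = {
        "G": gc_target / 2, "C": gc_target / 2,
        "A": (1 - gc_target) / 2, "T": (1 - gc_target) / 2,
    }
    w = np.array([np.prod([base_p[b] for b in c]) for c in CODON.symbols])
    w = w / w.sum()
    alpha = concentration * 61 * w
    return rng.dirichlet(alpha)


def _sample_coding(rng: np.random.Generator, usage: np.ndarray, n_codons: int) -> list[int]:
    return list(rng.choice(61, size=n_codons, p=usage))


def _codons_to_str(codons: list[int]) -> str:
    return "".join(CODON.symbols[c] for c in codons)


def generate_pangenome(config: SimulationConfig) -> Pangenome:
    """Generate the panel: per species a codon usage, per family an ancestral
    gene, per strain a diverged copy.

    The ancestor's interior is i.i.d. from the species usage with a start
    codon prepended and a stop appended; strain copies resample each interior
    codon from the usage with probability ``within_family_divergence``
    (codon-level mutation keeps the frame and can never introduce a
    premature stop).  Deterministic for a given config (seeded).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, dict[str, dict[str, str]]] = {}
    rows = []
    for si in range(config.n_species):
        sp = f"sp{si:02d}"
        usage = draw_codon_usage(
            rng, config.codon_usage_concentration, config.gc_target
        )
        genomes = {f"g{gi:02d}": {} for gi in range(config.strains_per_species)}
        for fi in range(config.families_per_species):
            fam = f"{sp}_fam{fi:04d}"
            lo, hi = config.family_length_range
            interior = np.array(_sample_coding(rng, usage, int(rng.integers(lo, hi + 1)) - 2))
            stop = _STOPS_FOR_ANCESTOR[rng.integers(0, 3)]
            for gi in range(config.strains_per_species):
                mutate = rng.random(len(interior)) < config.within_family_divergence
                codons = interior.copy()
                if mutate.any():
                    codons[mutate] = rng.choice(61, size=int(mutate.sum()), p=usage)
                seq = "ATG" + _codons_to_str(list(codons)) + stop
                orf_id = f"{sp}|g{gi:02d}|{fam}"
                genomes[f"g{gi:02d}"][orf_id] = seq
                rows.append({"species": sp, "genome": f"g{gi:02d}",
                             "orf_id": orf_id, "family": fam})
        sequences[sp] = genomes
    return Pangenome(
        sequences=sequences,
        truth=pd.DataFrame(rows, columns=["species", "genome", "orf_id", "family"]),
        config=config,
    )


def generate_bitscores(
    sequences: dict[str, str], k: int = 8
) -> BitscoreTable:
    """Toy all-vs-all scorer: s(i;j) = number of distinct shared k-mers.

    Symmetric by construction with s(i;i) = the sequence's own distinct
    k-mer count, so the bitscore distance behaves like an alignment-derived
    one: 0 for identical sequences, near 1 for unrelated ones.  Implemented
    as a sparse k-mer incidence product so all-vs-all stays fast.
    """
    if not sequences:
        raise ValueError("no sequences to score")
    ids = sorted(sequences)
    for i in ids:
        if len(sequences[i]) < k:
            raise ValueError(f"sequence {i!r} shorter than k={k}")
    kmer_index: dict[str, int] = {}
    rows, cols = [], []
    for r, i in enumerate(ids):
        seq = sequences[i]
        seen = {seq[j : j + k] for j in range(len(seq) - k + 1)}
        for km in seen:
            cols.append(kmer_index.setdefault(km, len(kmer_index)))
            rows.append(r)
    inc = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(ids), len(kmer_index)),
    )
    shared = (inc @ inc.T).toarray()
    table = BitscoreTable()
    for a in range(len(ids)):
        for b in range(len(ids)):
            if shared[a, b] > 0:
                table.add(ids[a], ids[b], float(shared[a, b]))
    return table


# ---------------------------------------------------------------------------
# classifier fixtures
# ---------------------------------------------------------------------------

def make_classification_fixture(
    n_positives: int = 400,
    concentration: float = 5.0,
    length_range: tuple[int, int] = (100, 400),
    gc_target: float = 0.5,
    seed: int = 0,
    species_id: str = "sim",
) -> list[LabeledOrf]:
    """High-contrast fixture: codon-biased Positives, out-of-frame Negatives.

    Positives are i.i.d. genes from one strongly biased codon usage;
    Negatives are their five out-of-frame readings, exactly as in the real
    training-set construction, giving the 1:5 class design.
    """
    rng = np.random.default_rng(seed)
    usage = draw_codon_usage(rng, concentration, gc_target)
    data: list[LabeledOrf] = []
    for i in range(n_positives):
        n_codons = int(rng.integers(length_range[0], length_range[1] + 1)) - 2
        raw = "ATG" + _codons_to_str(_sample_coding(rng, usage, n_codons)) + \
            _STOPS_FOR_ANCESTOR[rng.integers(0, 3)]
        pos = LabeledOrf(
            species_id=species_id, genome_id="g00", orf_id=f"{species_id}|g00|orf{i:05d}",
            residues=strip_start_and_stops(raw), label=+1, raw_residues=raw,
        )
        data.append(pos)
        data.extend(make_negatives(pos))
    return data


def make_null_fixture(
    n_positives: int = 400,
    concentration: float = 5.0,
    length_range: tuple[int, int] = (100, 400),
    gc_target: float = 0.5,
    seed: int = 0,
    species_id: str = "null",
) -> list[LabeledOrf]:
    """Null fixture: both classes i.i.d. from the same codon usage (1:5).

    No signal separates the classes, so any classifier's expected accuracy
    is the majority-class rate 5/6.
    """
    rng = np.random.default_rng(seed)
    usage = draw_codon_usage(rng, concentration, gc_target)
    data: list[LabeledOrf] = []
    for i in range(n_positives * 6):
        label = +1 if i < n_positives else -1
        n_codons = int(rng.integers(length_range[0], length_range[1] + 1)) - 2
        residues = _codons_to_str(_sample_coding(rng, usage, n_codons))
        data.append(
            LabeledOrf(
                species_id=species_id, genome_id="g00",
                orf_id=f"{species_id}|g00|orf{i:05d}",
                residues=strip_start_and_stops(residues), label=label,
            )
        )
    return data


def planted_performance_panel(
    n_species: int = 12,
    method_effect: float = 0.15,
    representation_effect: float = 0.10,
    interaction_effect: float = 0.05,
    sigma_species: float = 0.077,
    sigma_residual: float = 0.049,
    baseline: float = 1.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Transformed-performance table with planted fixed and random effects.

    Cell values follow the mixed-effect model directly (on the arcsine
    scale): method 2 gains ``method_effect``, the codon representation gains
    ``representation_effect``, and their combination an extra
    ``interaction_effect``; species contribute N(0, sigma_species^2) shifts
    and cells N(0, sigma_residual^2) noise.  Used for ANOVA power checks.
    """
    rng = np.random.default_rng(seed)
    methods = ["imm", "cppls"]
    reps = ["codon", "dna", "protein"]
    s_k = rng.normal(0.0, sigma_species, size=n_species)
    rows = []
    for k in range(n_species):
        for m in methods:
            for r in reps:
                z = baseline + s_k[k]
                if m == "cppls":
                    z += method_effect
                if r == "codon":
                    z += representation_effect
                    if m == "cppls":
                        z += interaction_effect
                z += rng.normal(0.0, sigma_residual)
                rows.append({"species": f"sp{k:02d}", "method": m,
                             "representation": r, "z": float(z)})
    return pd.DataFrame(rows)
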