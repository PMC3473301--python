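"""Sequence representations for coding-sequence modeling.

A protein-coding ORF can be modeled as a DNA sequence, a codon sequence or a
protein sequence.  The DNA representation must respect the reading frame: the
base observed at codon position 1, 2 or 3 carries different information, so
the effective DNA alphabet has 4 x 3 = 12 symbols (base x codon position of
the *target* symbol; the pretext a Markov chain is conditioned on crosses
frames).  The codon alphabet has the 61 sense codons (the three stop codons
never occur inside a preprocessed coding sequence), and the protein alphabet
the 20 standard amino acids.

This module provides the alphabets, genetic-code translation, the start/stop
stripping preprocessing, word counting (k-mer frequency features, word
lengths 1..K+1) and the exact accounting of how many transition
probabilities an interpolated Markov model of maximum order K requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alphabet",
    "DNA",
    "CODON",
    "PROTEIN",
    "ALPHABETS",
    "STOP_CODONS",
    "START_CODONS",
    "GENETIC_CODE",
    "DEFAULT_ORDERS",
    "LabeledOrf",
    "WordFeatureMatrix",
    "translate",
    "strip_start_and_stops",
    "reverse_complement",
    "encode",
    "word_labels",
    "count_words",
    "feature_matrix",
    "cumulative_parameter_count",
    "DegenerateSequenceError",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
#: common prokaryotic start codons; the stripping step accepts any of these
START_CODONS = ("ATG", "GTG", "TTG")

_BASES = "ACGT"
_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
)
_AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

# standard genetic code restricted to the 61 sense codons
_CODON_TABLE_RAW = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
GENETIC_CODE = dict(_CODON_TABLE_RAW)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DegenerateSequenceError(ValueError):
    """Raised when preprocessing leaves no usable sequence."""


@dataclass(frozen=True)
class Alphabet:
    """A sequence representation.

    ``symbols`` are the distinct unit symbols; for the frame-stratified DNA
    representation there are 4 base symbols but 12 effective symbols (base x
    codon position of the target).
    """

    name: str
    symbols: tuple[str, ...]
    frame_stratified: bool = False

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def effective_size(self) -> int:
        """Number of effective symbols (4 x 3 = 12 for frame-stratified DNA)."""
        return 3 * self.size if self.frame_stratified else self.size

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def __post_init__(self) -> None:
        if self.name not in ("dna", "codon", "protein"):
            raise ValueError(f"unknown alphabet name {self.name!r}")


DNA = Alphabet("dna", tuple(_BASES), frame_stratified=True)
CODON = Alphabet("codon", _CODONS)
PROTEIN = Alphabet("protein", _AMINO_ACIDS)
ALPHABETS: dict[str, Alphabet] = {"dna": DNA, "codon": CODON, "protein": PROTEIN}

#: default maximum Markov order per representation; chosen so that the three
#: models estimate a comparable number of parameters (4092 / 8420 / 3782)
DEFAULT_ORDERS: dict[str, int] = {"dna": 4, "protein": 2, "codon": 1}


@dataclass
class LabeledOrf:
    """One training/test ORF with its class label.

    ``residues`` is the preprocessed nucleotide sequence used for modeling;
    ``raw_residues`` optionally keeps the sequence before start/stop
    stripping (needed to derive out-of-frame negatives from a positive).
    label +1 = Positive (coding), -1 = Negative (out-of-frame).
    """

    species_id: str
    genome_id: str
    orf_id: str
    residues: str
    label: int
    raw_residues: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        if len(self.residues) == 0 or len(self.residues) % 3 != 0:
            raise ValueError(
                f"{self.orf_id}: residue length {len(self.residues)} is not a "
                "positive multiple of 3"
            )
        bad = set(self.residues) - set(_BASES)
        if bad:
            raise ValueError(f"{self.orf_id}: non-ACGT characters {sorted(bad)}")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def _check_nt(residues: str) -> None:
    bad = set(residues) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def translate(codon_sequence: str) -> str:
    """Translate a stop-free nucleotide sequence codon-by-codon.

    Raises ``ValueError`` on length not divisible by 3 or non-ACGT input, and
    ``DegenerateSequenceError`` on an in-frame stop codon (which signals that
    start/stop stripping has not been applied).
    """
    _check_nt(codon_sequence)
    if len(codon_sequence) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    out = []
    for i in range(0, len(codon_sequence), 3):
        codon = codon_sequence[i : i + 3]
        if codon in STOP_CODONS:
            raise DegenerateSequenceError(f"in-frame stop codon {codon} at position {i}")
        out.append(GENETIC_CODE[codon])
    return "".join(out)


def strip_start_and_stops(
    residues: str, start_codons: tuple[str, ...] = START_CODONS
) -> str:
    """Remove the leading start codon(s) and every in-frame stop codon.

    Classification should rest on sequence content, not on the endpoints
    shared by all genes, so the start codon is dropped; out-of-frame readings
    contain spurious in-frame stops, which are dropped from both classes for
    symmetry.  A trailing partial codon is trimmed first.  All *leading*
    start codons are removed (not just the first), which makes the operation
    idempotent.

    Raises ``DegenerateSequenceError`` if nothing remains.
    """
    _check_nt(residues)
    residues = residues[: len(residues) - len(residues) % 3]
    codons = [residues[i : i + 3] for i in range(0, len(residues), 3)]
    while codons and codons[0] in start_codons:
        codons.pop(0)
    codons = [c for c in codons if c not in STOP_CODONS]
    if not codons:
        raise DegenerateSequenceError("sequence empty after start/stop stripping")
    return "".join(codons)


# ---------------------------------------------------------------------------
# encoding and word counting
# ---------------------------------------------------------------------------

def encode(residues: str, alphabet: Alphabet) -> np.ndarray:
    """Encode a preprocessed nucleotide sequence as integer unit symbols.

    dna -> one int per nucleotide (frame implicit: position mod 3);
    codon -> one int per codon (61 sense codons);
    protein -> one int per translated amino acid.
    """
    _check_nt(residues)
    if alphabet.name == "dna":
        idx = alphabet.index
        return np.array([idx[b] for b in residues], dtype=np.int64)
    if len(residues) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    if alphabet.name == "codon":
        idx = alphabet.index
        try:
            return np.array(
                [idx[residues[i : i + 3]] for i in range(0, len(residues), 3)],
                dtype=np.int64,
            )
        except KeyError as exc:  # stop codon
            raise DegenerateSequenceError(f"stop codon {exc} in codon sequence") from exc
    if alphabet.name == "protein":
        aa = translate(residues)
        idx = alphabet.index
        return np.array([idx[a] for a in aa], dtype=np.int64)
    raise ValueError(f"unknown alphabet {alphabet.name}")


def cumulative_parameter_count(alphabet: Alphabet | str, K: int) -> int:
    """Total number of transition probabilities in an IMM of orders 0..K.

    An order-k chain over S symbols has S^(k+1) transition probabilities;
    the frame-stratified DNA chain keeps three target-frame-specific sets
    over 4 bases, 3*4^(k+1).  Exact integer arithmetic.
    """
    if isinstance(alphabet, str):
        try:
            alphabet = ALPHABETS[alphabet]
        except KeyError:
            raise ValueError(f"unknown alphabet {alphabet!r}") from None
    if K < 0:
        raise ValueError("K must be >= 0")
    if alphabet.frame_stratified:
        return sum(3 * 4 ** (k + 1) for k in range(K + 1))
    return sum(alphabet.size ** (k + 1) for k in range(K + 1))


def word_labels(alphabet: Alphabet, K: int) -> list[str]:
    """Column labels for the word-frequency feature space, lengths 1..K+1.

    DNA words are additionally keyed by the codon position (1..3) of the
    word's first base, e.g. ``pos1:GC``; codon words join codons with ``|``.
    """
    labels: list[str] = []
    sep = "|" if alphabet.name == "codon" else ""
    for L in range(1, K + 2):
        words = ["".join(w) if sep == "" else sep.join(w)
                 for w in itertools.product(alphabet.symbols, repeat=L)]
        if alphabet.frame_stratified:
            for pos in (1, 2, 3):
                labels.extend(f"pos{pos}:{w}" for w in words)
        else:
            labels.extend(words)
    return labels


def _word_start_indices(units: np.ndarray, S: int, L: int) -> np.ndarray:
    """Integer code of every length-L window (base-S positional encoding)."""
    n = len(units) - L + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(L):
        codes = codes * S + units[j : j + n]
    return codes


def count_words(
    residues: str,
    alphabet: Alphabet,
    K: int,
    relative: bool = True,
    allow_short: bool = False,
) -> np.ndarray:
    """Word-frequency feature row: all words of lengths 1..K+1.

    Words are counted by sliding window over the sequence in the alphabet's
    units.  For DNA each count is stratified by the codon position of the
    word's first base, so the feature dimension equals
    ``cumulative_parameter_count(alphabet, K)``.  With ``relative=True``
    (default) counts are normalized to relative frequencies within each word
    length.

    A sequence shorter than K+1 units raises unless ``allow_short`` (then
    long-word counts are zero).
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    units = encode(residues, alphabet)
    if len(units) < K + 1 and not allow_short:
        raise ValueError(
            f"sequence has {len(units)} units, fewer than the longest word K+1={K + 1}"
        )
    S = alphabet.size
    blocks: list[np.ndarray] = []
    for L in range(1, K + 2):
        nwin = max(len(units) - L + 1, 0)
        if alphabet.frame_stratified:
            block = np.zeros(3 * S**L)
            if nwin > 0:
                codes = _word_start_indices(units, S, L)
                frames = np.arange(nwin) % 3
                for f in range(3):
                    sel = codes[frames == f]
                    block[f * S**L : (f + 1) * S**L] = np.bincount(sel, minlength=S**L)
        else:
            block = np.zeros(S**L)
            if nwin > 0:
                codes = _word_start_indices(units, S, L)
                block = np.bincount(codes, minlength=S**L).astype(float)
        if relative and block.sum() > 0:
            block = block / block.sum()
        blocks.append(np.asarray(block, dtype=float))
    return np.concatenate(blocks)


@dataclass
class WordFeatureMatrix:
    """n x p matrix of word frequencies with an explicit word-index map.

    p always equals ``cumulative_parameter_count(alphabet, K)``: the number
    of word frequencies of lengths 1..K+1 matches the number of transition
    probabilities of an order-K IMM, which is what makes the two model
    families comparable in size.
    """

    row_ids: list[str]
    word_index: dict[str, int]
    values: np.ndarray
    K: int
    alphabet: Alphabet
    relative: bool = True

    def __post_init__(self) -> None:
        expected = cumulative_parameter_count(self.alphabet, self.K)
        if self.values.shape != (len(self.row_ids), expected):
            raise ValueError(
                f"feature matrix shape {self.values.shape} != "
                f"({len(self.row_ids)}, {expected})"
            )

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = [w for w, _ in sorted(self.word_index.items(), key=lambda kv: kv[1])]
        return pd.DataFrame(self.values, index=self.row_ids, columns=cols)


def feature_matrix(
    orfs: list[LabeledOrf] | list[str],
    alphabet: Alphabet | str,
    K: int | None = None,
    relative: bool = True,
    allow_short: bool = False,
) -> WordFeatureMatrix:
    """Build the word-frequency matrix for a collection of ORFs."""
    if isinstance(alphabet, str):
        alphabet = ALPHABETS[alphabet]
    if K is None:
        K = DEFAULT_ORDERS[alphabet.name]
    seqs = [(o.orf_id, o.residues) if isinstance(o, LabeledOrf) else (f"seq{i}", o)
            for i, o in enumerate(orfs)]
    rows = [count_words(s, alphabet, K, relative=relative, allow_short=allow_short)
            for _, s in seqs]
    labels = word_labels(alphabet, K)
    return WordFeatureMatrix(
        row_ids=[rid for rid, _ in seqs],
        word_index={w: i for i, w in enumerate(labels)},
        values=np.vstack(rows) if rows else np.zeros((0, len(labels))),
        K=K,
        alphabet=alphabet,
        relative=relative,
    )
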