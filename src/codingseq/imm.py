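"""Two-class interpolated Markov model (IMM) classifier.

An IMM combines Markov chains of every order k = 0..K: the probability of a
symbol given its context is a convex combination

    P(x_t | context) = sum_k w_k P_k(x_t | last k symbols),

which trades the low bias of high orders against the low variance of low
orders.  One IMM is fitted to the Positives and one to the Negatives; a test
sequence is assigned to the class with the larger total log-probability.

For the frame-stratified DNA representation each chain keeps three sets of
transition probabilities, one per codon position of the *target* base, while
the pretext crosses codon positions — the chain walks the sequence
nucleotide by nucleotide.

Transition counts are stabilized with pseudo-counts: with m observed
transitions/initiations in a class, m/4 pseudo-observations are added,
spread over contexts evenly and over target symbols by the class's 0-order
distribution (with a tiny uniform floor so every probability is strictly
positive).  Interpolation weights are estimated by EM on the
mixture-of-orders likelihood of the training data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabets import ALPHABETS, Alphabet, LabeledOrf, encode

__all__ = [
    "TransitionModel",
    "ClassChain",
    "ImmModel",
    "fit_chain",
    "fit_interpolation_weights",
    "fit_imm",
    "score",
    "classify",
    "PSEUDO_COUNT_DIVISOR",
    "UNIFORM_FLOOR",
]

log = logging.getLogger(__name__)

#: pseudo mass added per class = (number of observed transitions) / 4
PSEUDO_COUNT_DIVISOR = 4.0
#: mixing weight of the uniform distribution in the 0-order spread
#: distribution; guarantees strictly positive probabilities everywhere
UNIFORM_FLOOR = 1e-6

EM_TOL = 1e-8
EM_MAX_ITER = 2000


@dataclass
class TransitionModel:
    """Order-k transition probabilities for one class.

    ``probs`` has shape (S**k, S) for codon/protein and (3, 4**k, 4) for the
    frame-stratified DNA alphabet (leading axis = codon position of the
    target symbol).  Rows are conditional distributions and sum to 1.
    """

    order: int
    alphabet: Alphabet
    probs: np.ndarray

    def __post_init__(self) -> None:
        S = self.alphabet.size
        expected = (
            (3, S**self.order, S) if self.alphabet.frame_stratified
            else (S**self.order, S)
        )
        if self.probs.shape != expected:
            raise ValueError(f"probs shape {self.probs.shape} != {expected}")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("conditional distributions must sum to 1")
        if not (self.probs > 0).all():
            raise ValueError("all transition probabilities must be positive")

    @property
    def n_parameters(self) -> int:
        return int(np.prod(self.probs.shape))


def _zero_order_spread(counts0: np.ndarray) -> np.ndarray:
    """0-order spread distribution: empirical with a tiny uniform floor."""
    total = counts0.sum(axis=-1, keepdims=True)
    emp = np.where(total > 0, counts0 / np.maximum(total, 1), 1.0 / counts0.shape[-1])
    uni = np.full_like(emp, 1.0 / counts0.shape[-1])
    return (1.0 - UNIFORM_FLOOR) * emp + UNIFORM_FLOOR * uni


def _count_transitions(
    sequences: list[np.ndarray], alphabet: Alphabet, k: int
) -> tuple[np.ndarray, int]:
    """Pooled (pretext, target) counts at order k; also m = total positions.

    Positions with fewer than k preceding symbols are initiations handled by
    lower-order chains and do not contribute order-k transition counts; m
    counts every position (transitions and initiations alike).
    """
    S = alphabet.size
    m = 0
    if alphabet.frame_stratified:
        counts = np.zeros((3, S**k, S))
    else:
        counts = np.zeros((S**k, S))
    for seq in sequences:
        m += len(seq)
        if len(seq) < k + 1:
            continue
        n = len(seq) - k
        pretext = np.zeros(n, dtype=np.int64)
        for j in range(k):
            pretext = pretext * S + seq[j : j + n]
        target = seq[k:]
        if alphabet.frame_stratified:
            frames = (np.arange(n) + k) % 3
            for f in range(3):
                sel = frames == f
                np.add.at(counts[f], (pretext[sel], target[sel]), 1.0)
        else:
            np.add.at(counts, (pretext, target), 1.0)
    return counts, m


def fit_chain(
    sequences: list[np.ndarray] | list[str],
    alphabet: Alphabet,
    k: int,
    pseudo_divisor: float = PSEUDO_COUNT_DIVISOR,
) -> TransitionModel:
    """Fit the order-k transition probabilities of one class.

    Maximum-likelihood counts are augmented with m/4 pseudo-observations
    (m = total observed transitions/initiations in the class), spread evenly
    over contexts and over targets by the class's 0-order distribution.  A
    context never observed therefore follows the 0-order distribution
    exactly.
    """
    if not sequences:
        raise ValueError("empty training set")
    if k < 0:
        raise ValueError("order k must be >= 0")
    encoded = [encode(s, alphabet) if isinstance(s, str) else np.asarray(s)
               for s in sequences]
    counts, m = _count_transitions(encoded, alphabet, k)
    counts0, _ = _count_transitions(encoded, alphabet, 0)
    if alphabet.frame_stratified:
        spread = _zero_order_spread(counts0[:, 0, :])  # (3, 4)
        n_contexts = counts.shape[1]
        pseudo = (m / pseudo_divisor) / (3 * n_contexts) * spread[:, None, :]
    else:
        spread = _zero_order_spread(counts0[0])  # (S,)
        n_contexts = counts.shape[0]
        pseudo = (m / pseudo_divisor) / n_contexts * spread[None, :]
    total = counts + pseudo
    probs = total / total.sum(axis=-1, keepdims=True)
    return TransitionModel(order=k, alphabet=alphabet, probs=probs)


# ---------------------------------------------------------------------------
# per-position component probabilities and EM for interpolation weights
# ---------------------------------------------------------------------------

def _component_probabilities(
    chains: list[TransitionModel], seq: np.ndarray
) -> np.ndarray:
    """Matrix (len(seq), K+1): probability of each symbol under each order.

    The first k positions of a sequence lack a full order-k pretext; there
    the component falls back to the highest available lower order, so
    initiation is scored consistently with interpolation down to order 0.
    """
    alphabet = chains[0].alphabet
    S = alphabet.size
    K = len(chains) - 1
    n = len(seq)
    out = np.empty((n, K + 1))
    frames = np.arange(n) % 3 if alphabet.frame_stratified else None
    per_order = {}
    for k, chain in enumerate(chains):
        if n < k + 1:
            continue
        nk = n - k
        pretext = np.zeros(nk, dtype=np.int64)
        for j in range(k):
            pretext = pretext * S + seq[j : j + nk]
        target = seq[k:]
        if alphabet.frame_stratified:
            fr = frames[k:]
            per_order[k] = chain.probs[fr, pretext, target]
        else:
            per_order[k] = chain.probs[pretext, target]
    for k in range(K + 1):
        for t_block in range(min(k, n)):
            # position t < k: fall back to order t
            out[t_block, k] = per_order[t_block][0]
        if n > k:
            out[k:, k] = per_order[k]
    return out


def fit_interpolation_weights(
    chains: list[TransitionModel],
    sequences: list[np.ndarray] | list[str],
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[np.ndarray, bool]:
    """EM estimate of the convex interpolation weights over orders 0..K.

    Maximizes the training-data likelihood of the order-mixture; for fixed
    component probabilities this likelihood is concave in the weights, so the
    result does not depend on initialization.  Returns (weights, converged).
    """
    alphabet = chains[0].alphabet
    encoded = [encode(s, alphabet) if isinstance(s, str) else np.asarray(s)
               for s in sequences]
    P = np.vstack([_component_probabilities(chains, seq) for seq in encoded])
    K1 = len(chains)
    w = np.full(K1, 1.0 / K1)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        mix = P @ w
        ll = float(np.log(mix).sum())
        resp = (P * w) / mix[:, None]
        w = resp.mean(axis=0)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    if not converged:
        warnings.warn("EM for interpolation weights did not converge", stacklevel=2)
    return w, converged


@dataclass
class ClassChain:
    """Interpolated chain of one class: orders 0..K plus mixture weights."""

    chains: list[TransitionModel]
    weights: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.chains):
            raise ValueError("one weight per order required")
        if (self.weights < 0).any() or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be a convex combination")

    def log_probability(self, seq: np.ndarray) -> float:
        P = _component_probabilities(self.chains, seq)
        return float(np.log(P @ self.weights).sum())


@dataclass
class ImmModel:
    """Two-class IMM: a positive and a negative interpolated chain."""

    alphabet: Alphabet
    K: int
    positive_chain: ClassChain
    negative_chain: ClassChain
    pseudo_count_divisor: float = PSEUDO_COUNT_DIVISOR
    log_prior_ratio: float = 0.0

    @property
    def n_parameters(self) -> int:
        """Stored transition probabilities per class (Table-size accounting)."""
        return sum(c.n_parameters for c in self.positive_chain.chains)

    def to_json(self) -> str:
        def chain_dict(cc: ClassChain):
            return {
                "weights": cc.weights.tolist(),
                "orders": [
                    {"order": c.order, "probs": c.probs.tolist()} for c in cc.chains
                ],
            }

        return json.dumps(
            {
                "format": "codingseq-imm-v1",
                "alphabet": self.alphabet.name,
                "K": self.K,
                "pseudo_count_divisor": self.pseudo_count_divisor,
                "log_prior_ratio": self.log_prior_ratio,
                "positive": chain_dict(self.positive_chain),
                "negative": chain_dict(self.negative_chain),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ImmModel":
        d = json.loads(text)
        if d.get("format") != "codingseq-imm-v1":
            raise ValueError("unrecognized IMM model format")
        alphabet = ALPHABETS[d["alphabet"]]

        def chain(obj):
            chains = [
                TransitionModel(o["order"], alphabet, np.asarray(o["probs"]))
                for o in obj["orders"]
            ]
            return ClassChain(chains, np.asarray(obj["weights"]))

        return cls(
            alphabet=alphabet,
            K=d["K"],
            positive_chain=chain(d["positive"]),
            negative_chain=chain(d["negative"]),
            pseudo_count_divisor=d["pseudo_count_divisor"],
            log_prior_ratio=d.get("log_prior_ratio", 0.0),
        )


def fit_imm(
    positives: list[str] | list[LabeledOrf],
    negatives: list[str] | list[LabeledOrf],
    alphabet: Alphabet | str,
    K: int,
    use_prior: bool = False,
) -> ImmModel:
    """Fit the two-class IMM from preprocessed sequences of each class.

    ``use_prior`` adds log(n_pos/n_neg) to the score difference (off by
    default: classification is a pure likelihood ratio at threshold 0).
    """
    if isinstance(alphabet, str):
        alphabet = ALPHABETS[alphabet]

    def residues(xs):
        return [x.residues if isinstance(x, LabeledOrf) else x for x in xs]

    pos, neg = residues(positives), residues(negatives)
    if not pos or not neg:
        raise ValueError("both classes need training sequences")

    def fit_class(seqs) -> ClassChain:
        enc = [encode(s, alphabet) for s in seqs]
        chains = [fit_chain(enc, alphabet, k) for k in range(K + 1)]
        if K == 0:
            return ClassChain(chains, np.array([1.0]))
        w, conv = fit_interpolation_weights(chains, enc)
        return ClassChain(chains, w, conv)

    prior = float(np.log(len(pos) / len(neg))) if use_prior else 0.0
    return ImmModel(
        alphabet=alphabet,
        K=K,
        positive_chain=fit_class(pos),
        negative_chain=fit_class(neg),
        log_prior_ratio=prior,
    )


def score(model: ImmModel, orf: str | LabeledOrf) -> tuple[float, float]:
    """Log-probability of the sequence under the Positive and Negative IMM."""
    residues = orf.residues if isinstance(orf, LabeledOrf) else orf
    seq = encode(residues, model.alphabet)
    if len(seq) == 0:
        raise ValueError("sequence has no scoreable positions")
    return (
        model.positive_chain.log_probability(seq) + model.log_prior_ratio,
        model.negative_chain.log_probability(seq),
    )


def classify(model: ImmModel, orf: str | LabeledOrf) -> int:
    """+1 if the Positive log-probability exceeds the Negative one, else -1.

    An exact tie is called -1 (conservative: non-coding).
    """
    lp, ln = score(model, orf)
    return +1 if lp - ln > 0 else -1
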