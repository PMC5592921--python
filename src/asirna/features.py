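"""Feature encodings for 19-nt guide strands.

Encoder recipes are registered under short ids and composed into hybrid vectors:

===========  ======================================================  ====
id           encoding                                                dim
===========  ======================================================  ====
``m``        mononucleotide composition                              4
``d``        dinucleotide composition                                16
``t``        trinucleotide composition                               64
``tt``       tetranucleotide composition                             256
``p``        pentanucleotide composition                             1024
``binary``   per-position one-hot (19 positions x A,C,G,U)           76
``thermo``   nearest-neighbor duplex thermodynamics                  21
``struct``   per-position paired flag from a base-pair-max fold      19
===========  ======================================================  ====

Hybrids concatenate components in order, e.g. ``("m","d","t","tt","binary")``
gives the 416-dimensional vector used by the efficacy regressor.

All encoders are deterministic, and dimensionality depends only on the recipe,
never on the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np

from .sequence import GUIDE_LEN, RNA_ALPHABET

__all__ = [
    "FeatureVector",
    "kmer_composition",
    "binary_encoding",
    "thermodynamic_features",
    "secondary_structure_features",
    "hybrid",
    "encode",
    "encode_matrix",
    "encoder_dim",
    "ENCODER_IDS",
]

_BASES = "ACGU"

# pair set for the structure fold: Watson-Crick plus G:U wobble, standard in RNA folding
_FOLD_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_MIN_LOOP = 3  # minimum unpaired bases enclosed by a pair


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered numeric encoding of a guide."""

    values: np.ndarray
    names: tuple[str, ...]
    spec_id: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def _check_guide(guide: str) -> None:
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(guide)}")
    bad = set(guide) - RNA_ALPHABET
    if bad:
        raise ValueError(f"guide contains non-RNA characters: {bad}")


@lru_cache(maxsize=8)
def _kmer_order(k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in product(_BASES, repeat=k))


def kmer_composition(guide: str, k: int) -> FeatureVector:
    """Overlapping k-mer frequency vector (length 4^k, lexicographic A<C<G<U).

    Each value is the count of that k-mer among the 19-k+1 windows divided by
    19-k+1, so the vector sums to 1.
    """
    _check_guide(guide)
    if not 1 <= k <= 5:
        raise ValueError("k must be in 1..5")
    order = _kmer_order(k)
    index = {kmer: i for i, kmer in enumerate(order)}
    n_win = GUIDE_LEN - k + 1
    vals = np.zeros(len(order))
    for i in range(n_win):
        vals[index[guide[i : i + k]]] += 1.0
    vals /= n_win
    return FeatureVector(vals, order, spec_id=_KMER_IDS[k])


def binary_encoding(guide: str) -> FeatureVector:
    """Position-wise one-hot encoding: 19 blocks of 4 indicators (A,C,G,U), 76 dims."""
    _check_guide(guide)
    vals = np.zeros(GUIDE_LEN * 4)
    names = []
    for pos in range(GUIDE_LEN):
        for j, base in enumerate(_BASES):
            names.append(f"pos{pos + 1}_{base}")
        vals[pos * 4 + _BASES.index(guide[pos])] = 1.0
    return FeatureVector(vals, tuple(names), spec_id="binary")


@lru_cache(maxsize=1)
def _nn_table() -> dict[str, float]:
    text = (
        resources.files("asirna.data").joinpath("nn_rna_xia1998.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("step"):
            continue
        step, dg = line.split("\t")
        table[step] = float(dg)
    if len(table) != 16:
        raise RuntimeError("nearest-neighbor table must have 16 steps")
    return table


def thermodynamic_features(guide: str) -> FeatureVector:
    """Duplex thermodynamic profile of the guide:target duplex (21 values, kcal/mol).

    The 18 nearest-neighbor stacking free energies of consecutive dinucleotide
    steps (5'->3' on the guide, fully complementary target), followed by the total
    duplex delta-G (sum of steps), the 5'-terminal stability (sum of the first 4
    steps) and the 3'-terminal stability (sum of the last 4 steps).  The asymmetry
    between the two duplex ends governs which strand RISC prefers to load.
    """
    _check_guide(guide)
    nn = _nn_table()
    steps = np.array([nn[guide[i : i + 2]] for i in range(GUIDE_LEN - 1)])
    vals = np.concatenate(
        [steps, [steps.sum(), steps[:4].sum(), steps[-4:].sum()]]
    )
    names = tuple(
        [f"dg_step{i + 1}" for i in range(GUIDE_LEN - 1)]
        + ["dg_total", "dg_5prime", "dg_3prime"]
    )
    return FeatureVector(vals, names, spec_id="thermo")


def _nussinov_paired(seq: str) -> np.ndarray:
    """Per-position paired flags from a base-pair-maximization dynamic program.

    Minimum hairpin loop of 3 unpaired bases; ties are resolved toward fewer pairs
    (leaving j unpaired is preferred whenever it attains the optimum), which makes
    the traceback deterministic.
    """
    n = len(seq)
    M = np.zeros((n, n), dtype=int)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i][j - 1]  # j unpaired (preferred on ties)
            for k in range(i, j - _MIN_LOOP):
                if (seq[k], seq[j]) in _FOLD_PAIRS:
                    left = M[i][k - 1] if k > i else 0
                    cand = left + 1 + (M[k + 1][j - 1] if k + 1 <= j - 1 else 0)
                    if cand > best:
                        best = cand
            M[i][j] = best

    paired = np.zeros(n)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= _MIN_LOOP:
            continue
        if M[i][j] == M[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - _MIN_LOOP):
            if (seq[k], seq[j]) in _FOLD_PAIRS:
                left = M[i][k - 1] if k > i else 0
                inner = M[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner == M[i][j]:
                    paired[k] = paired[j] = 1.0
                    if k > i:
                        stack.append((i, k - 1))
                    if k + 1 <= j - 1:
                        stack.append((k + 1, j - 1))
                    break
    return paired


def secondary_structure_features(guide: str) -> FeatureVector:
    """Per-position base-paired indicators (1 = paired) of the guide folded on itself."""
    _check_guide(guide)
    vals = _nussinov_paired(guide)
    names = tuple(f"paired_pos{i + 1}" for i in range(GUIDE_LEN))
    return FeatureVector(vals, names, spec_id="struct")


_KMER_IDS = {1: "m", 2: "d", 3: "t", 4: "tt", 5: "p"}

_ENCODERS: dict[str, Callable[[str], FeatureVector]] = {
    "m": lambda g: kmer_composition(g, 1),
    "d": lambda g: kmer_composition(g, 2),
    "t": lambda g: kmer_composition(g, 3),
    "tt": lambda g: kmer_composition(g, 4),
    "p": lambda g: kmer_composition(g, 5),
    "binary": binary_encoding,
    "thermo": thermodynamic_features,
    "struct": secondary_structure_features,
}

_DIMS = {"m": 4, "d": 16, "t": 64, "tt": 256, "p": 1024,
         "binary": 76, "thermo": 21, "struct": 19}

ENCODER_IDS = tuple(_ENCODERS)


def encoder_dim(spec: str | Sequence[str]) -> int:
    """Dimensionality of an encoder id or hybrid recipe (pure function of the recipe)."""
    if isinstance(spec, str):
        spec = (spec,)
    try:
        return sum(_DIMS[s] for s in spec)
    except KeyError as e:
        raise ValueError(f"unknown encoder id {e.args[0]!r}") from None


def hybrid(guide: str, spec: Sequence[str]) -> FeatureVector:
    """Concatenate encoder outputs in recipe order; names are prefixed by encoder id."""
    if not spec:
        raise ValueError("hybrid spec must be non-empty")
    parts = []
    for enc_id in spec:
        if enc_id not in _ENCODERS:
            raise ValueError(f"unknown encoder id {enc_id!r}")
        parts.append(_ENCODERS[enc_id](guide))
    vals = np.concatenate([p.values for p in parts])
    names = tuple(f"{p.spec_id}:{n}" for p in parts for n in p.names)
    return FeatureVector(vals, names, spec_id="+".join(spec))


def encode(guide: str, spec: str | Sequence[str]) -> FeatureVector:
    """Encode one guide with a single encoder id or a hybrid recipe."""
    if isinstance(spec, str):
        spec = (spec,)
    return hybrid(guide, spec)


def encode_matrix(
    guides: Iterable[str], spec: str | Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode many guides into an (n_guides, dim) matrix plus column names."""
    if isinstance(spec, str):
        spec = (spec,)
    vecs = [encode(g, spec) for g in guides]
    if not vecs:
        raise ValueError("no guides to encode")
    return np.vstack([v.values for v in vecs]), vecs[0].names
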