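"""Synthetic fixtures with known ground truth for every tier of the toolkit.

Three generators, all fully deterministic under a fixed seed:

* :func:`gen_allele_pair` — a random mRNA context with one central substitution,
  emitted both as an :class:`~asirna.sequence.AllelePair` and as the
  lowercase-marked FASTA text the parser accepts.
* :func:`gen_training_dataset` — guides drawn uniformly with efficacies computed
  from a known feature -> efficacy map plus Gaussian noise, and gene labels with
  skewed sizes (including genes with fewer than 10 records, so the small-gene
  pooling rule is exercised).  The latent map is retrievable for oracle tests.
* :func:`gen_genome_with_planted_sites` — a random background genome with seed
  complements or distance-d mutated full sites planted at known positions, plus
  a truth table; rejection sampling guarantees the background contains no
  accidental seed matches for the planted guide.

Effect models operate on the package's own encoders, so parameter-recovery tests
exercise the real feature path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import binary_encoding, kmer_composition
from .model import TrainingDataset
from .offtarget import SEED_SLICES, seed_of
from .sequence import GUIDE_LEN, AllelePair, reverse_complement

__all__ = [
    "EFFECT_MODELS",
    "effect_function",
    "gen_allele_pair",
    "gen_training_dataset",
    "gen_genome_with_planted_sites",
    "PlantSpec",
]

_BASES = "ACGU"

# Fixed weights of the latent dinucleotide effect (percentage points per unit
# frequency).  The spread gives the latent efficacy a standard deviation of
# about 20 points on uniform random 19-mers, a strong but not saturating signal
# relative to the default measurement noise (sd 5).
_DINUC_WEIGHTS = np.array(
    [150.0, -70.0, 30.0, -130.0, 110.0, -30.0, 130.0, -110.0,
     -150.0, 70.0, -50.0, 90.0, 10.0, -90.0, 50.0, -10.0]
)

# per-(position, base) contributions of the positional effect model
_POS_WEIGHTS = np.array(
    [[(-1) ** (p + b) * (2.0 + 1.5 * ((p * 4 + b) % 5)) for b in range(4)]
     for p in range(GUIDE_LEN)]
).ravel()


def _f_linear_dinuc(guide: str) -> float:
    comp = kmer_composition(guide, 2).values
    return 50.0 + float(_DINUC_WEIGHTS @ comp)


def _f_positional(guide: str) -> float:
    return 50.0 + float(_POS_WEIGHTS @ binary_encoding(guide).values)


EFFECT_MODELS: dict[str, Callable[[str], float]] = {
    "linear_dinuc": _f_linear_dinuc,
    "positional": _f_positional,
    # gene_shifted uses _f_linear_dinuc plus a +30 offset for the first gene;
    # the shift is applied inside gen_training_dataset
    "gene_shifted": _f_linear_dinuc,
}

GENE_SHIFT = 30.0  # offset of gene G01 under the gene_shifted model


def effect_function(model_id: str) -> Callable[[str], float]:
    """The latent efficacy map f(guide) of an effect model (before noise/clamping)."""
    try:
        return EFFECT_MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown effect model {model_id!r}") from None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def gen_allele_pair(context_len: int, seed: int) -> tuple[AllelePair, str]:
    """Random allele pair with one central substitution, plus its FASTA text.

    ``context_len`` must be >= 37 so the variant can carry full 18-nt flanks and
    all 19 candidate guides exist.  The FASTA marks the variant in lower case.
    """
    if context_len < 37:
        raise ValueError("context_len must be >= 37 (full flanks for a 19-mer)")
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, context_len)
    offset = context_len // 2
    wild_nt = seq[offset]
    mutant_nt = rng.choice([b for b in _BASES if b != wild_nt])
    mutant_seq = seq[:offset] + mutant_nt + seq[offset + 1 :]
    pair = AllelePair(
        mutant_seq=mutant_seq,
        wild_seq=seq,
        variant_offset=offset,
        mutant_nt=mutant_nt,
        wild_nt=wild_nt,
    )

    def _marked(s: str) -> str:
        return s[:offset] + s[offset].lower() + s[offset + 1 :]

    fasta = (
        f">mutant variant_offset={offset}\n{_marked(mutant_seq)}\n"
        f">wild variant_offset={offset}\n{_marked(seq)}\n"
    )
    return pair, fasta


def _gene_sizes(n: int, n_genes: int) -> list[int]:
    """Skewed gene sizes summing to n; the last two genes are kept below 10 records."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    weights = np.array([1.0 / (k + 1) for k in range(n_genes)])
    raw = np.floor(weights / weights.sum() * n).astype(int)
    raw[0] += n - raw.sum()
    if n_genes >= 3 and n >= 30:
        # force two small genes (<10 records) so pooled-group handling is exercised
        for idx, small in ((n_genes - 1, 4), (n_genes - 2, 7)):
            raw[0] += raw[idx] - small
            raw[idx] = small
    return raw.tolist()


def gen_training_dataset(
    n: int,
    n_genes: int,
    effect_model: str = "linear_dinuc",
    noise_sd: float = 5.0,
    seed: int = 0,
) -> TrainingDataset:
    """Training table of random guides with efficacies from a known latent map.

    efficacy = clamp(f(guide) + Normal(0, noise_sd), 0, 100), with f given by
    ``effect_model`` (see :data:`EFFECT_MODELS`; retrieve f via
    :func:`effect_function` for oracle tests).  Under ``gene_shifted`` the first
    gene's efficacies are offset by +30 before clamping, creating a distribution
    shift that leave-one-gene-out evaluation must expose.  Gene sizes are skewed
    and include genes with fewer than 10 records.
    """
    if n < 30:
        raise ValueError("n must be >= 30")
    f = effect_function(effect_model)
    rng = np.random.default_rng(seed)
    sizes = _gene_sizes(n, n_genes)
    genes = [f"G{k + 1:02d}" for k in range(n_genes) for _ in range(sizes[k])]
    guides, effs = [], []
    seen = set()
    for gene in genes:
        while True:
            g = _random_seq(rng, GUIDE_LEN)
            if g not in seen:
                seen.add(g)
                break
        val = f(g)
        if effect_model == "gene_shifted" and gene == "G01":
            val += GENE_SHIFT
        val += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        guides.append(g)
        effs.append(float(np.clip(val, 0.0, 100.0)))
    df = pd.DataFrame(
        {"guide": guides, "efficacy": effs, "gene": genes,
         "source": f"synthetic:{effect_model}:seed={seed}"}
    )
    # shuffle record order so gene blocks are not contiguous
    order = rng.permutation(n)
    return TrainingDataset(df.iloc[order])


@dataclass(frozen=True)
class PlantSpec:
    """One planted site: 0-based genome position and plant type.

    Types: ``seed6`` / ``seed7`` (exact seed complement) or ``full_d0`` ...
    ``full_d3`` (19-nt guide complement mutated at d positions).
    """

    position: int
    kind: str

    _KINDS = ("seed6", "seed7", "full_d0", "full_d1", "full_d2", "full_d3")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.position < 0:
            raise ValueError("plant position must be >= 0")

    @property
    def length(self) -> int:
        if self.kind == "seed6":
            return 6
        if self.kind == "seed7":
            return 7
        return GUIDE_LEN


def _mutate_window(
    window: str, d: int, protected_free: Sequence[int], rng: np.random.Generator
) -> str:
    """Substitute d distinct positions; at least one inside ``protected_free``."""
    if d == 0:
        return window
    positions = set()
    # one substitution forced into the seed-complement region so the mutated
    # full site never doubles as an unplanned seed hit
    positions.add(int(rng.choice(list(protected_free))))
    while len(positions) < d:
        positions.add(int(rng.integers(0, len(window))))
    chars = list(window)
    for p in positions:
        chars[p] = rng.choice([b for b in _BASES if b != chars[p]])
    return "".join(chars)


def gen_genome_with_planted_sites(
    genome_len: int,
    guide: str,
    plants: Sequence[PlantSpec],
    seed: int,
    record_id: str = "synthetic_genome",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with off-target sites for ``guide`` planted at known positions.

    Returns ({record_id: sequence}, truth_table).  The truth table has one row
    per plant: position (0-based), start (1-based), kind, site.  Background is
    rejection-sampled so that, outside planted intervals, neither the seed6 nor
    the seed7 complement of the guide occurs anywhere; full_d{1..3} plants carry
    at least one substitution inside the seed7-complement region, so seed
    searches recover exactly the seed-type (and full_d0) plants.
    """
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt")
    rng = np.random.default_rng(seed)
    intervals = sorted((p.position, p.position + p.length) for p in plants)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("overlapping plants")
    if intervals and intervals[-1][1] > genome_len:
        raise ValueError("genome too short for the requested plants")

    chars = list(_random_seq(rng, genome_len))

    # guide pos 2-7 pairs with window indices 12..17 (pos p <-> index 19-p); a
    # substitution there destroys both the seed6 and the seed7 complement
    seed6_lo, seed6_hi = SEED_SLICES["seed6"]
    protected_free = [GUIDE_LEN - p for p in range(seed6_lo, seed6_hi + 1)]

    truth_rows = []
    for plant in plants:
        if plant.kind in ("seed6", "seed7"):
            site = reverse_complement(seed_of(guide, plant.kind))
        else:
            d = int(plant.kind[-1])
            site = _mutate_window(
                reverse_complement(guide), d, protected_free, rng
            )
        chars[plant.position : plant.position + plant.length] = site
        truth_rows.append(
            {"position": plant.position, "start": plant.position + 1,
             "kind": plant.kind, "site": site}
        )

    planted = [(p.position, p.position + p.length) for p in plants]

    def _contained(i: int, j: int) -> bool:
        return any(i >= s and j <= e for s, e in planted)

    def _in_plant(i: int) -> bool:
        return any(s <= i < e for s, e in planted)

    # rejection: remove accidental seed complements not contained in a plant
    # (occurrences straddling a plant boundary are cleaned by mutating their
    # background bases only)
    seeds = {mode: reverse_complement(seed_of(guide, mode)) for mode in SEED_SLICES}
    for _ in range(10_000):
        genome = "".join(chars)
        offender = None
        for mode, site in seeds.items():
            pos = genome.find(site)
            while pos != -1:
                if not _contained(pos, pos + len(site)):
                    offender = (pos, pos + len(site))
                    break
                pos = genome.find(site, pos + 1)
            if offender:
                break
        if offender is None:
            break
        lo, hi = offender
        free = [i for i in range(lo, hi) if not _in_plant(i)]
        i = int(rng.choice(free))
        chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
    else:
        raise RuntimeError("rejection sampling failed to clean the background")

    truth = pd.DataFrame(truth_rows, columns=["position", "start", "kind", "site"])
    return {record_id: "".join(chars)}, truth
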