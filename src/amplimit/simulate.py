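"""Amplicon-library simulator.

Generates labeled pyrosequencing-style reads from a :class:`~amplimit.community.CommunitySpec`:
taxon labels are drawn multinomially from the (optionally copy-number-adjusted)
abundances, each read is excised from its taxon's reference amplicon in
reverse orientation, read lengths follow a truncated normal, homopolymer runs
are perturbed with a length-dependent normal model, and substitution/indel
errors follow a linear 5'->3' positional ramp.  A 5-base multiplex identifier
(MID) is carried per library.

All randomness flows from one integer seed; each read gets its own child
stream so libraries are reproducible byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .community import CommunitySpec, adjust_for_copy_number

__all__ = [
    "ReadLengthModel",
    "ErrorModel",
    "Read",
    "AmpliconLibrary",
    "simulate_library",
    "draw_taxon_counts",
    "apply_positional_errors",
    "apply_homopolymer_errors",
    "trim_and_length_filter",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadLengthModel:
    """Normal read-length model with a downstream uniform trim length.

    Defaults are pyrosequencing-like: mean 250 bp, sd 50 bp, reads later
    trimmed to a uniform 230 bp (shorter reads discarded).  Non-positive
    length draws are redrawn.
    """

    mean: float = 250.0
    sd: float = 50.0
    trim_length: int = 230

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean read length must be positive")
        if self.sd < 0:
            raise ValueError("read length sd must be non-negative")
        if self.trim_length <= 0:
            raise ValueError("trim length must be positive")

    def draw(self, rng: np.random.Generator) -> int:
        """One positive integer length; zero/negative draws are redrawn."""
        while True:
            length = int(round(rng.normal(self.mean, self.sd)))
            if length > 0:
                return length


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error model.

    ``rate_5prime``/``rate_3prime`` set a per-base error probability that
    ramps linearly along the read (defaults 0.004 -> 0.005).  A drawn error is
    a substitution with probability ``substitution_fraction``, else an indel
    (insertion or deletion, equiprobable).  Homopolymer runs of true length n
    are re-drawn with sd sigma(n) = homopolymer_sigma_intercept +
    homopolymer_sigma_slope * n (flow-signal-style noise; defaults
    0.03494 + 0.06856 n).
    """

    rate_5prime: float = 0.004
    rate_3prime: float = 0.005
    substitution_fraction: float = 0.9
    homopolymer_sigma_intercept: float = 0.03494
    homopolymer_sigma_slope: float = 0.06856

    def __post_init__(self) -> None:
        for name in ("rate_5prime", "rate_3prime", "substitution_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def positional_rates(self, length: int) -> np.ndarray:
        """Per-base error probabilities, linear from 5' to 3'."""
        if length == 1:
            return np.array([self.rate_5prime])
        return np.linspace(self.rate_5prime, self.rate_3prime, length)

    def homopolymer_sigma(self, n: np.ndarray | int) -> np.ndarray | float:
        sigma = (
            self.homopolymer_sigma_intercept
            + self.homopolymer_sigma_slope * np.asarray(n, dtype=float)
        )
        if np.any(sigma < 0):
            raise ValueError("homopolymer sigma must be non-negative for n >= 1")
        return sigma


@dataclass(frozen=True)
class Read:
    sequence: str
    true_taxon: str
    mid: str


@dataclass
class AmpliconLibrary:
    """Simulated reads plus the ground-truth taxon count vector."""

    reads: list[Read]
    counts: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != len(self.reads):
            raise ValueError("counts do not sum to the number of reads")

    @property
    def size(self) -> int:
        return len(self.reads)

    def fractions(self) -> dict[str, float]:
        total = self.size
        return {t: c / total for t, c in self.counts.items()} if total else {}


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def apply_positional_errors(
    sequence: str,
    error_model: ErrorModel,
    seed: int | np.random.Generator,
) -> str:
    """Mutate a read with position-ramped substitution/indel errors.

    Error probability at base i interpolates linearly from ``rate_5prime`` at
    the first base to ``rate_3prime`` at the last.  Substitutions replace the
    base with a uniformly chosen different base; indels delete the base or
    insert a random base before it.
    """
    if not sequence:
        raise ValueError("empty sequence")
    rng = _as_rng(seed)
    rates = error_model.positional_rates(len(sequence))
    hits = np.flatnonzero(rng.random(len(sequence)) < rates)
    if hits.size == 0:
        return sequence
    out: list[str] = []
    prev = 0
    for i in hits:
        out.append(sequence[prev:i])
        base = sequence[i]
        if rng.random() < error_model.substitution_fraction:
            choices = "ACGT".replace(base, "") or "ACGT"
            out.append(choices[rng.integers(len(choices))])
        elif rng.random() < 0.5:  # deletion
            pass
        else:  # insertion before the base
            out.append("ACGT"[rng.integers(4)] + base)
        prev = i + 1
    out.append(sequence[prev:])
    return "".join(out)


def apply_homopolymer_errors(
    sequence: str,
    error_model: ErrorModel,
    seed: int | np.random.Generator,
) -> str:
    """Resample every maximal homopolymer run length.

    A run of true length n becomes round(max(0, Normal(n, sigma(n)))) copies
    of the same base; bases between runs are untouched (runs of length 1 are
    runs too, but with sigma(1) small they almost always survive intact).
    """
    if not sequence:
        raise ValueError("empty sequence")
    rng = _as_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    boundaries = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    lengths = np.diff(np.concatenate((starts, [arr.size])))
    sigma = error_model.homopolymer_sigma(lengths)
    new_lengths = np.rint(
        np.maximum(0.0, rng.normal(lengths.astype(float), sigma))
    ).astype(int)
    return b"".join(np.repeat(arr[starts], new_lengths)).decode()


def draw_taxon_counts(
    spec: CommunitySpec,
    n_reads: int,
    seed: int | np.random.Generator,
    copy_number_bias: bool = True,
) -> dict[str, int]:
    """Multinomial taxon label counts for a library of ``n_reads`` reads."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not spec.taxa:
        raise ValueError("empty community spec")
    rng = _as_rng(seed)
    probs = (
        adjust_for_copy_number(spec) if copy_number_bias else spec.abundances
    )
    ids = spec.taxon_ids
    draws = rng.multinomial(n_reads, [probs[t] for t in ids])
    return dict(zip(ids, (int(c) for c in draws)))


def _random_mid(rng: np.random.Generator, length: int = 5) -> str:
    return b"".join(rng.choice(_BASES, size=length)).decode()


def simulate_library(
    spec: CommunitySpec,
    n_reads: int,
    seed: int,
    copy_number_bias: bool = True,
    error_model: ErrorModel | None = None,
    length_model: ReadLengthModel | None = None,
) -> AmpliconLibrary:
    """Simulate a labeled amplicon library.

    Taxon labels are multinomial in the adjusted abundances; each read is the
    reverse-complement of its taxon's reference amplicon (sequencing proceeds
    from the reverse primer), truncated to a length drawn from
    ``length_model``, then passed through the homopolymer and positional error
    models.  One 5-base MID identifies the library.  Identical arguments give
    byte-identical output.
    """
    spec.validate_for_simulation()
    error_model = error_model or ErrorModel()
    length_model = length_model or ReadLengthModel()

    top = np.random.default_rng(np.random.SeedSequence(seed))
    counts = draw_taxon_counts(spec, n_reads, top, copy_number_bias)
    mid = _random_mid(top)

    templates = {
        t.taxon_id: reverse_complement(t.reference_amplicon) for t in spec.taxa
    }
    labels = np.repeat(
        np.arange(len(spec.taxa)), [counts[t] for t in spec.taxon_ids]
    )
    top.shuffle(labels)
    ids = spec.taxon_ids

    error_free = (
        error_model.rate_5prime == 0.0
        and error_model.rate_3prime == 0.0
        and error_model.homopolymer_sigma_intercept == 0.0
        and error_model.homopolymer_sigma_slope == 0.0
    )

    reads: list[Read] = []
    for i, lab in enumerate(labels):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        )
        template = templates[ids[lab]]
        length = length_model.draw(rng)
        seq = template[: min(length, len(template))]
        if not error_free:
            seq = apply_homopolymer_errors(seq, error_model, rng)
            seq = apply_positional_errors(seq, error_model, rng)
        reads.append(Read(sequence=seq, true_taxon=ids[lab], mid=mid))
    return AmpliconLibrary(reads=reads, counts=counts, seed=seed)


def trim_and_length_filter(
    library: AmpliconLibrary, trim_length: int = 230
) -> AmpliconLibrary:
    """Trim reads to a uniform length, discarding shorter reads.

    Deterministic: every surviving read is exactly ``trim_length`` bases and
    the count vector is recomputed from the survivors.
    """
    if trim_length <= 0:
        raise ValueError("trim length must be positive")
    kept = [
        Read(r.sequence[:trim_length], r.true_taxon, r.mid)
        for r in library.reads
        if len(r.sequence) >= trim_length
    ]
    counts: dict[str, int] = {t: 0 for t in library.counts}
    for r in kept:
        counts[r.true_taxon] = counts.get(r.true_taxon, 0) + 1
    if not kept:
        logger.warning(
            "trim_and_length_filter: no reads of length >= %d", trim_length
        )
    return AmpliconLibrary(reads=kept, counts=counts, seed=library.seed)
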