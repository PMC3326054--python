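"""Mock-community specifications.

A :class:`CommunitySpec` is the ground truth for everything downstream: it
names the taxa in a constructed (mock) community, their input relative
abundances, their 16S rRNA gene copy numbers, and a reference amplicon
sequence per taxon from which reads are simulated.  The default
:func:`mock_community` mirrors a twelve-strain community of respiratory
organisms spanning five orders of magnitude in abundance, which is what makes
it useful for probing detection limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Taxon",
    "CommunitySpec",
    "adjust_for_copy_number",
    "mock_community",
    "random_amplicon",
    "MOCK_ABUNDANCES",
    "MOCK_COPY_NUMBERS",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_amplicon(length: int, seed: int) -> str:
    """Return a seeded random nucleotide sequence over {A,C,G,T}.

    Used to build synthetic reference amplicons so that the simulator is
    self-contained (no genome downloads); taxonomy travels as ground-truth
    labels, not by sequence similarity.
    """
    if length <= 0:
        raise ValueError("amplicon length must be positive")
    rng = np.random.default_rng(seed)
    return b"".join(rng.choice(_BASES, size=length)).decode()


@dataclass(frozen=True)
class Taxon:
    """One member of a mock community.

    Parameters
    ----------
    taxon_id
        Unique identifier (species-level label).
    genus
        Genus used for contaminant classification.
    input_abundance
        Specified relative abundance before copy-number adjustment, in [0, 1].
    copy_number
        16S rRNA gene copies per genome (>= 1).
    reference_amplicon
        Nucleotide sequence the simulator reads from.
    """

    taxon_id: str
    genus: str
    input_abundance: float
    copy_number: int = 1
    reference_amplicon: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.input_abundance <= 1.0:
            raise ValueError(f"abundance of {self.taxon_id} outside [0, 1]")
        if self.copy_number < 1:
            raise ValueError(f"copy number of {self.taxon_id} must be >= 1")
        if self.reference_amplicon and (
            set(self.reference_amplicon) - set("ACGT")
        ):
            raise ValueError(
                f"reference amplicon of {self.taxon_id} has non-ACGT characters"
            )


@dataclass
class CommunitySpec:
    """A named collection of taxa with abundances summing to one.

    Input abundances are stored as given; :attr:`abundances` exposes the
    normalized vector.  Taxon ids must be unique and every taxon needs a
    non-empty reference amplicon for simulation.
    """

    taxa: list[Taxon] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.taxon_id for t in self.taxa]
        if len(ids) != len(set(ids)):
            raise ValueError("taxon_ids must be unique")
        if self.taxa and sum(t.input_abundance for t in self.taxa) <= 0:
            raise ValueError("all input abundances are zero")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def genera(self) -> set[str]:
        return {t.genus for t in self.taxa}

    @property
    def abundances(self) -> dict[str, float]:
        """Input abundances normalized to sum to one."""
        total = sum(t.input_abundance for t in self.taxa)
        return {t.taxon_id: t.input_abundance / total for t in self.taxa}

    def validate_for_simulation(self) -> None:
        if not self.taxa:
            raise ValueError("empty community spec")
        for t in self.taxa:
            if not t.reference_amplicon:
                raise ValueError(f"taxon {t.taxon_id} has no reference amplicon")


def adjust_for_copy_number(spec: CommunitySpec) -> dict[str, float]:
    """Copy-number-adjusted relative abundances.

    Amplicon yield scales with the number of 16S gene copies per genome, so
    the fraction of reads a taxon contributes is a_i * c_i / sum_j a_j * c_j.
    Returns a mapping taxon_id -> adjusted fraction summing to one.
    """
    if not spec.taxa:
        raise ValueError("empty community spec")
    weights = {
        t.taxon_id: t.input_abundance * t.copy_number for t in spec.taxa
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all input abundances are zero")
    return {tid: w / total for tid, w in weights.items()}


#: Input relative abundances of the twelve-strain mock community
#: (five orders of magnitude; the three rarest genera sit near or below
#: typical per-sample sequencing depths).
MOCK_ABUNDANCES: dict[str, tuple[str, float]] = {
    "P_aeruginosa": ("Pseudomonas", 0.75),
    "B_cenocepacia": ("Burkholderia", 0.075),
    "S_aureus": ("Staphylococcus", 0.075),
    "H_influenzae": ("Haemophilus", 0.075),
    "M_catarrhalis": ("Moraxella", 0.0075),
    "K_pneumoniae": ("Klebsiella", 0.0075),
    "S_epidermidis": ("Staphylococcus", 0.0075),
    "N_meningitidis": ("Neisseria", 0.00075),
    "B_multivorans": ("Burkholderia", 0.00075),
    "L_pneumophila": ("Legionella", 0.000075),
    "S_pneumoniae": ("Streptococcus", 0.000075),
    "N_gonorrhoeae": ("Neisseria", 0.0000075),
}

#: Typical 16S rRNA gene copy numbers per genome (rrnDB-style literature
#: values; configurable — simulations that matter for thresholds run with
#: copy-number bias off).
MOCK_COPY_NUMBERS: dict[str, int] = {
    "P_aeruginosa": 4,
    "B_cenocepacia": 6,
    "S_aureus": 5,
    "H_influenzae": 6,
    "M_catarrhalis": 4,
    "K_pneumoniae": 8,
    "S_epidermidis": 5,
    "N_meningitidis": 4,
    "B_multivorans": 6,
    "L_pneumophila": 3,
    "S_pneumoniae": 4,
    "N_gonorrhoeae": 4,
}


def mock_community(
    amplicon_length: int = 350,
    seed: int = 2012,
    copy_numbers: dict[str, int] | None = None,
) -> CommunitySpec:
    """The default twelve-taxon mock community over nine genera.

    Reference amplicons are seeded random sequences of ``amplicon_length``
    bases, deterministic for a given ``seed``.  ``copy_numbers`` overrides the
    default per-taxon 16S copy numbers (pass ``{tid: 1 for tid in ...}`` for
    an unbiased community).
    """
    cn = dict(MOCK_COPY_NUMBERS)
    if copy_numbers:
        cn.update(copy_numbers)
    taxa = [
        Taxon(
            taxon_id=tid,
            genus=genus,
            input_abundance=ab,
            copy_number=cn[tid],
            reference_amplicon=random_amplicon(amplicon_length, seed + i),
        )
        for i, (tid, (genus, ab)) in enumerate(MOCK_ABUNDANCES.items())
    ]
    return CommunitySpec(taxa=taxa)
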