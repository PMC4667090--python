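"""Model of what Sanger sequencing observes for a multi-copy amplicon.

A sequencing read of a locus that is present in several copies (homoeologs
within a tetraploid, or paralogs within one genome) superposes the copies:
positions where the copies agree show a canonical base, positions where they
differ show an IUPAC ambiguity letter (the abstraction of a double peak in a
trace). An :class:`AmpliconObservation` is that superposed consensus plus a
zygosity flag.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

CANONICAL_BASES = frozenset("ACGT")

#: frozenset of canonical bases -> IUPAC letter (15 nonempty subsets)
SET_TO_IUPAC: dict[frozenset[str], str] = {
    frozenset(bases): letter
    for letter, bases in ambiguous_dna_values.items()
    if letter != "X"
}

#: IUPAC letter -> frozenset of canonical bases
IUPAC_TO_SET: dict[str, frozenset[str]] = {v: k for k, v in SET_TO_IUPAC.items()}

IUPAC_LETTERS = frozenset(IUPAC_TO_SET)


def iupac_superpose(bases: Iterable[str]) -> str:
    """Return the IUPAC letter encoding a nonempty set of canonical bases.

    Singleton sets return the base itself; the full set returns ``N``.
    """
    base_set = frozenset(b.upper() for b in bases)
    if not base_set:
        raise ValueError("cannot superpose an empty base set")
    bad = base_set - CANONICAL_BASES
    if bad:
        raise ValueError(f"non-canonical symbols in base set: {sorted(bad)}")
    return SET_TO_IUPAC[base_set]


def iupac_decompose(letter: str) -> frozenset[str]:
    """Return the set of canonical bases encoded by an IUPAC letter.

    Inverse of :func:`iupac_superpose` on all 15 letters.
    """
    try:
        return IUPAC_TO_SET[letter.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide letter: {letter!r}") from None


@dataclass(frozen=True)
class AmpliconObservation:
    """One genotype's consensus sequence for one locus.

    ``ambiguity_positions`` are exactly the 0-based offsets whose letter is
    not a canonical base; the observation is heterozygous iff that list is
    nonempty.
    """

    locus_id: str
    genotype_id: str
    sequence: str
    ambiguity_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise ValueError(f"invalid letters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        positions = tuple(
            i for i, letter in enumerate(seq) if letter not in CANONICAL_BASES
        )
        object.__setattr__(self, "ambiguity_positions", positions)

    @property
    def zygosity(self) -> str:
        return "heterozygous" if self.ambiguity_positions else "homozygous"

    @property
    def is_heterozygous(self) -> bool:
        return bool(self.ambiguity_positions)

    def base_set(self, position: int) -> frozenset[str]:
        """Canonical bases superposed at ``position`` (0-based)."""
        return IUPAC_TO_SET[self.sequence[position]]

    def __len__(self) -> int:
        return len(self.sequence)


def observe_amplicon(
    copies: Sequence[str], locus_id: str = "", genotype_id: str = ""
) -> AmpliconObservation:
    """Superpose equal-length copies of a locus into one IUPAC consensus.

    The observed letter at each position is the IUPAC code for the set of
    bases the copies carry there. Invariant to copy order; idempotent when
    re-applied to the resulting consensus.
    """
    if not copies:
        raise ValueError("at least one copy is required")
    length = len(copies[0])
    if any(len(c) != length for c in copies):
        raise ValueError("copies must have equal length (substitution-only model)")
    letters = []
    for column in zip(*(c.upper() for c in copies)):
        bases: set[str] = set()
        for letter in column:
            bases |= IUPAC_TO_SET[letter]
        letters.append(SET_TO_IUPAC[frozenset(bases)])
    return AmpliconObservation(locus_id, genotype_id, "".join(letters))


def zygosity_rates(
    observations: Sequence[AmpliconObservation],
    group_by: Mapping[str, str] | Callable[[AmpliconObservation], str] | None = None,
) -> pd.DataFrame:
    """Fraction heterozygous / homozygous per group of observations.

    ``group_by`` maps a locus id to a group label (e.g. EST vs GSS), or is a
    callable on the observation; by default all observations form one group.
    Fractions sum to 1 within each group.
    """
    if not observations:
        raise ValueError("no observations given")
    if group_by is None:
        keyfn = lambda obs: "all"  # noqa: E731
    elif callable(group_by):
        keyfn = group_by
    else:
        mapping = group_by
        keyfn = lambda obs: mapping[obs.locus_id]  # noqa: E731

    het: dict[str, int] = defaultdict(int)
    total: dict[str, int] = defaultdict(int)
    for obs in observations:
        group = keyfn(obs)
        total[group] += 1
        het[group] += int(obs.is_heterozygous)

    rows = []
    for group in sorted(total):
        n = total[group]
        frac_het = het[group] / n
        rows.append(
            {
                "group": group,
                "n": n,
                "frac_heterozygous": frac_het,
                "frac_homozygous": 1.0 - frac_het,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def observations_to_table(observations: Sequence[AmpliconObservation]) -> pd.DataFrame:
    """Metadata table (locus, genotype, zygosity, n_ambiguity) for export."""
    return pd.DataFrame(
        {
            "locus": [o.locus_id for o in observations],
            "genotype": [o.genotype_id for o in observations],
            "zygosity": [o.zygosity for o in observations],
            "n_ambiguity": [len(o.ambiguity_positions) for o in observations],
        }
    )
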