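"""Genetic-code model: synonymous families, degeneracy classes, codon sets.

Everything downstream (RSCU, ENC, PR2, ordination) is defined relative to a
genetic code.  Chloroplast protein genes are translated with the
bacterial/plastid code (NCBI translation table 11), whose codon -> amino acid
map coincides with the standard code; both are available by ``code_id``.

DNA alphabet (T, not U) is canonical throughout the package; RNA input is
transliterated on read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

BASES = ("T", "C", "A", "G")
STOP = "*"

#: all 64 codons in TCAG order (codonW/GenBank ordering)
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)


def normalize_codon(codon: str) -> str:
    """Uppercase a trinucleotide and transliterate U -> T."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise ValueError(f"not a DNA codon: {codon!r}")
    return c


@dataclass(frozen=True)
class CodonSet:
    """A named collection of distinct uppercase DNA codons."""

    name: str
    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        norm = tuple(normalize_codon(c) for c in self.codons)
        if len(set(norm)) != len(norm):
            raise ValueError(f"duplicate codons in set {self.name!r}")
        object.__setattr__(self, "codons", norm)

    def __contains__(self, codon: str) -> bool:
        return normalize_codon(codon) in self.codons

    def __iter__(self):
        return iter(self.codons)

    def __len__(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class CodonTable:
    """A genetic code with its synonymous-family structure.

    Attributes
    ----------
    code_id : int
        NCBI genetic-code identifier (11 = bacterial/plastid, 1 = standard).
    codon_to_aa : dict
        Maps each of the 64 codons to a three-letter amino-acid symbol or
        ``"*"`` for stop.
    families : dict
        Amino acid -> ordered tuple of synonymous codons (TCAG order).
    degeneracy_classes : dict
        Fold class (2, 3, 4, 6) -> tuple of amino acids with that many
        synonymous codons.  Single-codon amino acids (Met, Trp) are not in
        any class.
    """

    code_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)
    degeneracy_classes: dict[int, tuple[str, ...]] = field(default_factory=dict)
    stop_codons: tuple[str, ...] = ()
    start_codons: tuple[str, ...] = ()

    @classmethod
    def from_ncbi_id(cls, code_id: int = 11) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[code_id]
        three = _aa_one_to_three()
        codon_to_aa: dict[str, str] = {}
        for codon in ALL_CODONS:
            if codon in bio.stop_codons:
                codon_to_aa[codon] = STOP
            else:
                codon_to_aa[codon] = three[bio.forward_table[codon]]
        families: dict[str, tuple[str, ...]] = {}
        for codon in ALL_CODONS:
            aa = codon_to_aa[codon]
            if aa == STOP:
                continue
            families[aa] = families.get(aa, ()) + (codon,)
        classes: dict[int, tuple[str, ...]] = {}
        for aa, codons in families.items():
            k = len(codons)
            if k >= 2:
                classes[k] = classes.get(k, ()) + (aa,)
        return cls(
            code_id=code_id,
            codon_to_aa=dict(codon_to_aa),
            families=families,
            degeneracy_classes=classes,
            stop_codons=tuple(c for c in ALL_CODONS if codon_to_aa[c] == STOP),
            start_codons=tuple(sorted(bio.start_codons)),
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    def amino_acid(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    def degeneracy(self, codon: str) -> int:
        aa = self.amino_acid(codon)
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon")
        return len(self.families[aa])

    def validate(self) -> None:
        """Assert the structural invariants of a sensible genetic code."""
        if len(self.codon_to_aa) != 64:
            raise AssertionError("codon map must cover exactly 64 codons")
        n_sense = len(self.sense_codons)
        if sum(len(v) for v in self.families.values()) != n_sense:
            raise AssertionError("families must partition the sense codons")
        seen: set[str] = set()
        for codons in self.families.values():
            if seen & set(codons):
                raise AssertionError("families overlap")
            seen.update(codons)


def standard_table(code_id: int = 11) -> CodonTable:
    """The default code used throughout: NCBI table 11 (bacterial/plastid)."""
    return CodonTable.from_ncbi_id(code_id)


def informative_codons(table: CodonTable) -> CodonSet:
    """The sense codons that carry synonymous-choice information.

    Excludes the stop codons and the single-codon amino acids Met (ATG) and
    Trp (TGG); for the standard/plastid code this is exactly 59 codons, the
    dimensionality of the RSCU ordination space.
    """
    codons = tuple(
        c
        for c in table.sense_codons
        if len(table.families[table.codon_to_aa[c]]) >= 2
    )
    return CodonSet(name="informative", codons=codons)


def fourfold_pr2_families(table: CodonTable) -> list[CodonSet]:
    """The eight four-codon blocks used for parity-rule-2 analysis.

    Each block is four codons sharing their first two bases whose third
    position is fully degenerate: the five strict fourfold families (Ala,
    Gly, Pro, Thr, Val) plus the CGN, CTN and TCN sub-blocks of the sixfold
    Arg, Leu and Ser families.
    """
    blocks: dict[tuple[str, str], list[str]] = {}
    for codon in table.sense_codons:
        aa = table.codon_to_aa[codon]
        blocks.setdefault((aa, codon[:2]), []).append(codon)
    out = []
    for (aa, prefix), codons in blocks.items():
        if len(codons) == 4:
            out.append(CodonSet(name=f"{aa}({prefix}N)", codons=tuple(codons)))
    out.sort(key=lambda s: s.name)
    return out


def _aa_one_to_three() -> dict[str, str]:
    return {
        "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
        "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
        "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
        "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    }
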