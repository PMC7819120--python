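"""Reading coding sequences and the QC filter chain.

The analysis operates on complete, spliced CDSs.  Gene sets extracted from an
organellar genome typically contain short conserved genes, exact duplicates
from the inverted repeat, and entries that are not clean reading frames; the
filter chain removes these in a fixed, reportable order:

1. length < ``min_len`` (default 300 nt) -> ``TOO_SHORT``
2. exact full-length duplicate of an earlier record -> ``DUPLICATE``
3. not a clean ORF (length not a multiple of 3, internal in-frame stop, or —
   under ``strict_start`` — a non-start first codon) -> ``NOT_ORF``

Rejections are reported, never raised.  A terminal stop codon is tolerated
and trimmed from accepted sequences by default so that downstream codon
statistics never see stop codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .codon_model import CodonTable, STOP

TOO_SHORT = "TOO_SHORT"
DUPLICATE = "DUPLICATE"
NOT_ORF = "NOT_ORF"


@dataclass(frozen=True)
class CodingSequence:
    """One gene sequence with its QC verdict.

    ``qc_flags`` is empty iff the record passed the filter chain.
    """

    gene_id: str
    seq: str
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    @property
    def accepted(self) -> bool:
        return not self.qc_flags


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_after_length: int
    n_after_dedup: int
    n_accepted: int
    rejected: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if not (
            self.n_input
            >= self.n_after_length
            >= self.n_after_dedup
            >= self.n_accepted
        ):
            raise ValueError("filter counts must be non-increasing")
        if self.n_input != self.n_accepted + len(self.rejected):
            raise ValueError("rejections do not account for every drop")


def _clean_seq(raw: str) -> str:
    return raw.upper().replace("U", "T").replace(" ", "").replace("\n", "")


def read_sequences(
    path: str | Path, format: str = "fasta"
) -> list[CodingSequence]:
    """Read gene sequences from a FASTA or GenBank file.

    FASTA: one record per entry, id taken from the header word.  GenBank:
    CDS features are extracted, identified by their ``gene`` qualifier
    (falling back to ``locus_tag`` or a positional label).  Sequences are
    uppercased with U transliterated to T.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format: {format!r}")
    records: list[CodingSequence] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(CodingSequence(rec.id, _clean_seq(str(rec.seq))))
    else:
        for rec in SeqIO.parse(str(path), "genbank"):
            n_cds = 0
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                n_cds += 1
                quals = feat.qualifiers
                gene_id = (
                    quals.get("gene", quals.get("locus_tag", [None]))[0]
                    or f"{rec.id}_CDS{n_cds}"
                )
                seq = str(feat.extract(rec.seq))
                records.append(CodingSequence(gene_id, _clean_seq(seq)))
    if not records:
        warnings.warn(f"no sequence records read from {path}", stacklevel=2)
    return records


def is_clean_orf(
    seq: str,
    table: CodonTable,
    strict_start: bool = False,
) -> bool:
    """True if ``seq`` is an in-frame coding sequence.

    Requires length divisible by 3, a pure ACGT alphabet and no internal
    in-frame stop; a terminal stop is allowed but not required (some plastid
    CDS extractions omit it).  Under ``strict_start`` the first codon must
    additionally be a recognized start codon of the genetic code.
    """
    if len(seq) < 3 or len(seq) % 3:
        return False
    if any(b not in "ACGT" for b in seq):
        return False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for codon in codons[:-1]:
        if table.codon_to_aa[codon] == STOP:
            return False
    if strict_start and codons[0] not in table.start_codons:
        return False
    return True


def trim_terminal_stop(seq: str, table: CodonTable) -> str:
    if len(seq) >= 3 and not len(seq) % 3:
        if table.codon_to_aa.get(seq[-3:]) == STOP:
            return seq[:-3]
    return seq


def annotate_qc(
    records: Sequence[CodingSequence],
    table: CodonTable,
    min_len: int = 300,
    strict_start: bool = False,
    keep_terminal_stop: bool = False,
) -> list[CodingSequence]:
    """Run the QC chain, returning every record with its flags set.

    Accepted records come back with empty flags and (by default) their
    terminal stop trimmed; rejected records keep their original sequence and
    carry the flag of the first stage that dropped them.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    out: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.length_nt < min_len:
            out.append(replace(rec, qc_flags=frozenset({TOO_SHORT})))
            continue
        if rec.seq in seen:
            out.append(replace(rec, qc_flags=frozenset({DUPLICATE})))
            continue
        seen.add(rec.seq)
        if not is_clean_orf(rec.seq, table, strict_start=strict_start):
            out.append(replace(rec, qc_flags=frozenset({NOT_ORF})))
            continue
        seq = rec.seq if keep_terminal_stop else trim_terminal_stop(rec.seq, table)
        out.append(replace(rec, seq=seq, qc_flags=frozenset()))
    return out


def filter_cds(
    records: Sequence[CodingSequence],
    table: CodonTable,
    min_len: int = 300,
    strict_start: bool = False,
    keep_terminal_stop: bool = False,
) -> tuple[list[CodingSequence], FilterReport]:
    """Apply the QC chain; return accepted CDSs and a full accounting.

    The filter is idempotent: re-filtering its accepted output (with the
    same settings) accepts everything unchanged.
    """
    annotated = annotate_qc(
        records,
        table,
        min_len=min_len,
        strict_start=strict_start,
        keep_terminal_stop=keep_terminal_stop,
    )
    accepted = [r for r in annotated if r.accepted]
    rejected = [(r.gene_id, r.qc_flags) for r in annotated if not r.accepted]
    n_short = sum(1 for _, f in rejected if TOO_SHORT in f)
    n_dup = sum(1 for _, f in rejected if DUPLICATE in f)
    report = FilterReport(
        n_input=len(records),
        n_after_length=len(records) - n_short,
        n_after_dedup=len(records) - n_short - n_dup,
        n_accepted=len(accepted),
        rejected=tuple(rejected),
    )
    return accepted, report


def write_fasta(records: Iterable[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def write_filter_report(
    annotated: Sequence[CodingSequence], path: str | Path
) -> None:
    """Per-record TSV: gene_id, length_nt, status, flags."""
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_nt\tstatus\tflags\n")
        for rec in annotated:
            status = "accepted" if rec.accepted else "rejected"
            fh.write(
                f"{rec.gene_id}\t{rec.length_nt}\t{status}\t"
                f"{','.join(sorted(rec.qc_flags))}\n"
            )
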