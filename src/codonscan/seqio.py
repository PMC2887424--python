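"""Reading, writing and validation of coding sequences and alignments.

Coding sequences (CDS) are the only required input to the pipeline: they are
normalized (upper case, ``U`` -> ``T``), validated against the active genetic
code and translated natively, so protein and DNA can never get out of sync.
Alignments can be exported as FASTA, Clustal, Phylip (sequential and
interleaved) and a hybrid protein/DNA codon-delimited layout that shows each
residue above its source codon.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("codonscan")

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
GAP_CODON = "---"
STOP = "*"

#: alignment export/import formats understood by :func:`write_alignment`
ALIGNMENT_FORMATS = (
    "fasta",
    "clustal",
    "phylip-sequential",
    "phylip-interleaved",
    "codon-hybrid",
)


class SequenceFormatError(ValueError):
    """Malformed input: bad FASTA syntax, illegal characters, duplicate names."""


class TranslationError(ValueError):
    """A CDS cannot be translated: frame error or internal stop codon."""


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table (64 codons -> amino acid letter or ``*``)."""

    name: str
    table: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.table)}")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        """Build from an NCBI translation table (1 = standard nuclear code)."""
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(bio.forward_table)
        for codon in bio.stop_codons:
            table[codon] = STOP
        return cls(name=bio.names[0], table=table)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa != STOP))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == STOP))

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == STOP

    def translate_codon(self, codon: str) -> str:
        return self.table[codon]


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


# ---------------------------------------------------------------------------
# Sequence containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence: in-frame, no internal stops, stop stripped."""

    name: str
    nucleotides: str

    @property
    def length(self) -> int:
        return len(self.nucleotides)

    @property
    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]

    @classmethod
    def from_nucleotides(
        cls, name: str, raw: str, code: GeneticCode = STANDARD_CODE
    ) -> "CodingSequence":
        """Normalize and validate raw nucleotides into a CodingSequence.

        Upper-cases, maps U->T, rejects non-ACGT characters (ambiguity codes
        included: downstream counting and likelihood math assumes unambiguous
        codons), requires length divisible by 3, strips one terminal stop and
        rejects internal stops.
        """
        if not name:
            raise SequenceFormatError("sequence name must be non-empty")
        seq = raw.upper().replace("U", "T")
        for pos, ch in enumerate(seq):
            if ch not in NUCLEOTIDES:
                raise SequenceFormatError(
                    f"sequence {name!r}: illegal nucleotide {ch!r} at position {pos + 1}"
                )
        if len(seq) == 0:
            raise SequenceFormatError(f"sequence {name!r} is empty")
        if len(seq) % 3:
            raise TranslationError(
                f"sequence {name!r}: length {len(seq)} is not a multiple of 3"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and code.is_stop(codons[-1]):
            codons = codons[:-1]
        for idx, codon in enumerate(codons):
            if code.is_stop(codon):
                raise TranslationError(
                    f"sequence {name!r}: internal stop codon {codon} at codon {idx + 1}"
                )
        if not codons:
            raise SequenceFormatError(f"sequence {name!r} has no sense codons")
        return cls(name=name, nucleotides="".join(codons))


@dataclass(frozen=True)
class ProteinSequence:
    name: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def translate_cds(cds: CodingSequence, code: GeneticCode = STANDARD_CODE) -> ProteinSequence:
    """Translate a validated CDS codon-by-codon (terminal stop already stripped)."""
    return ProteinSequence(cds.name, "".join(code.translate_codon(c) for c in cds.codons))


def translate_codon_row(row: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a gapped codon row; the gap codon ``---`` becomes ``-``."""
    if len(row) % 3:
        raise TranslationError(f"codon row length {len(row)} is not a multiple of 3")
    out = []
    for i in range(0, len(row), 3):
        codon = row[i : i + 3]
        out.append(GAP if codon == GAP_CODON else code.translate_codon(codon))
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _parse_fasta_text(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise SequenceFormatError(f"line {lineno}: empty FASTA header")
            chunks = []
        else:
            if name is None:
                raise SequenceFormatError(f"line {lineno}: sequence data before first '>' header")
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise SequenceFormatError("no FASTA records found")
    seen: set[str] = set()
    for nm, _ in records:
        if nm in seen:
            raise SequenceFormatError(f"duplicate sequence name {nm!r}")
        seen.add(nm)
    return records


def read_fasta(source: str | Path, moltype: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into (name, sequence) pairs in file order.

    ``moltype='dna'`` upper-cases, maps U->T and rejects anything outside
    A/C/G/T; ``moltype='protein'`` upper-cases and accepts the 20 amino-acid
    letters plus ``-`` (pre-aligned guide proteins may be gapped).

    Raises :class:`SequenceFormatError` on duplicate names, empty files and
    illegal characters (with position).
    """
    path = Path(source)
    text = path.read_text()
    records = _parse_fasta_text(text)
    out = []
    for name, seq in records:
        seq = seq.upper()
        if moltype == "dna":
            seq = seq.replace("U", "T")
            allowed = set(NUCLEOTIDES)
        elif moltype == "protein":
            allowed = set(AMINO_ACIDS) | {GAP}
        else:
            raise ValueError(f"unknown moltype {moltype!r}")
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise SequenceFormatError(
                    f"sequence {name!r}: illegal character {ch!r} at position {pos + 1}"
                )
        out.append((name, seq))
    return out


def read_cds_fasta(source: str | Path, code: GeneticCode = STANDARD_CODE) -> list[CodingSequence]:
    """Read and validate a CDS FASTA file."""
    return [CodingSequence.from_nucleotides(n, s, code) for n, s in read_fasta(source, "dna")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path | None = None, width: int = 60) -> str:
    """Render records as FASTA text (wrapped); optionally also write to path."""
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Alignment export / import
# ---------------------------------------------------------------------------


def _rows(aln) -> list[tuple[str, str]]:
    """Accept either a list of (name, seq) pairs or an object with .rows."""
    rows = list(aln.rows) if hasattr(aln, "rows") else list(aln)
    if not rows:
        raise ValueError("empty alignment")
    ncols = len(rows[0][1])
    for name, seq in rows:
        if len(seq) != ncols:
            raise ValueError(f"ragged alignment: row {name!r} has length {len(seq)} != {ncols}")
    return rows


def phylip_safe_names(names: Sequence[str]) -> dict[str, str]:
    """Truncate names to 10 characters, forcing uniqueness with numeric suffixes."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        short = name[:10]
        if short in used:
            k = 1
            while True:
                suffix = str(k)
                cand = name[: 10 - len(suffix)] + suffix
                if cand not in used:
                    short = cand
                    break
                k += 1
        used.add(short)
        mapping[name] = short
    return mapping


def _to_msa(rows: list[tuple[str, str]]) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=name, description="") for name, seq in rows
    )


def write_alignment(aln, format: str = "fasta", code: GeneticCode = STANDARD_CODE) -> str:
    """Render an alignment in one of :data:`ALIGNMENT_FORMATS`.

    The codon-hybrid layout shows, per sequence: the name, then the protein
    residues one per codon column (space-separated), then the codon triplets
    (gap codon ``---``, gap residue ``-``).
    """
    rows = _rows(aln)
    if format == "fasta":
        return write_fasta(rows)
    if format == "clustal":
        buf = io.StringIO()
        AlignIO.write(_to_msa(rows), buf, "clustal")
        return buf.getvalue()
    if format in ("phylip-sequential", "phylip-interleaved"):
        mapping = phylip_safe_names([n for n, _ in rows])
        msa = _to_msa([(mapping[n], s) for n, s in rows])
        buf = io.StringIO()
        AlignIO.write(msa, buf, "phylip" if format == "phylip-interleaved" else "phylip-sequential")
        return buf.getvalue()
    if format == "codon-hybrid":
        blocks = []
        for name, seq in rows:
            if len(seq) % 3:
                raise ValueError(f"codon-hybrid requires codon rows; {name!r} has {len(seq)} nt")
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            protein = translate_codon_row(seq, code)
            blocks.append("\n".join([name, " ".join(protein), " ".join(codons)]))
        return "\n\n".join(blocks) + "\n"
    raise ValueError(f"unknown alignment format {format!r}; expected one of {ALIGNMENT_FORMATS}")


def read_alignment(text: str, format: str = "fasta") -> list[tuple[str, str]]:
    """Parse alignment text produced by :func:`write_alignment` (same formats)."""
    if format == "fasta":
        rows = _parse_fasta_text(text)
    elif format == "clustal":
        msa = AlignIO.read(io.StringIO(text), "clustal")
        rows = [(rec.id, str(rec.seq)) for rec in msa]
    elif format in ("phylip-sequential", "phylip-interleaved"):
        fmt = "phylip" if format == "phylip-interleaved" else "phylip-sequential"
        msa = AlignIO.read(io.StringIO(text), fmt)
        rows = [(rec.id, str(rec.seq)) for rec in msa]
    elif format == "codon-hybrid":
        rows = []
        for block in [b for b in text.strip().split("\n\n") if b.strip()]:
            lines = block.splitlines()
            if len(lines) != 3:
                raise SequenceFormatError("codon-hybrid block must have 3 lines")
            name, _protein, codons = lines
            rows.append((name.strip(), "".join(codons.split())))
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    ncols = len(rows[0][1])
    for name, seq in rows:
        if len(seq) != ncols:
            raise SequenceFormatError(f"ragged alignment row {name!r}")
    return rows


def degap(seq: str) -> str:
    return seq.replace(GAP, "")
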