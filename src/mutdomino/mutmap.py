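"""Mutation-table parsing and genomic-to-protein coordinate mapping.

Somatic mutation calls arrive either as genomic SNVs (MAF-like tables with
chromosome/position/alleles) or already lifted to protein coordinates.  This
module normalises both dialects into :class:`MutationRecord` objects, selects a
representative transcript per gene (the longest protein-coding one), and maps
genomic substitutions onto codons and residues with a consequence class
(missense / synonymous / nonsense / frameshift or in-frame indel).

Coordinates are 1-based inclusive throughout, matching the MAF and GFF
conventions of the input formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "MutationRecord",
    "TranscriptModel",
    "ParseReport",
    "read_mutation_table",
    "select_representative_transcript",
    "map_genomic_to_protein",
    "classify_consequence",
    "classify_indel",
    "translate_cds",
]

#: Consequence vocabulary used across the package.
CONSEQUENCES = (
    "missense",
    "synonymous",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "other",
)

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
_VALID_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_STOP = "*"
_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop_codon in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop_codon] = _STOP


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic mutation event in one sample.

    ``residue_position`` is 1-based on the protein; ``genomic`` carries the
    original (chromosome, position, ref_base, alt_base) when known.
    """

    sample_id: str
    tumor_type: str
    gene_id: str
    residue_position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    consequence: str = "other"
    genomic: Optional[Tuple[str, int, str, str]] = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.consequence == "missense":
            if (
                self.ref_aa not in _VALID_AA
                or self.alt_aa not in _VALID_AA
                or self.ref_aa == self.alt_aa
            ):
                raise ValueError(
                    f"missense record requires distinct ref/alt amino acids, "
                    f"got {self.ref_aa!r}->{self.alt_aa!r}"
                )
        if self.consequence == "synonymous" and self.ref_aa is not None:
            if self.alt_aa is not None and self.ref_aa != self.alt_aa:
                raise ValueError("synonymous record must keep the amino acid")


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript with CDS intervals in transcription order and its protein.

    Invariants: CDS intervals are non-overlapping and sorted in transcription
    order (descending genomic coordinates on the minus strand); total CDS
    length is divisible by 3; the translated CDS (standard code, stop trimmed)
    equals ``protein_sequence``.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    cds_intervals: Tuple[Tuple[int, int], ...]
    protein_sequence: str

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = tuple((int(a), int(b)) for a, b in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", ivs)
        for a, b in ivs:
            if a > b:
                raise ValueError(f"interval ({a},{b}) has start > end")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_intervals)

    @property
    def protein_length(self) -> int:
        return len(self.protein_sequence)

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in transcription (5'→3' coding) orientation."""
        chrom = _chrom_seq(genome, self.chromosome)
        parts = []
        for a, b in self.cds_intervals:
            piece = chrom[a - 1 : b].upper()
            if self.strand == "-":
                piece = piece.translate(_COMPLEMENT)[::-1]
            parts.append(piece)
        return "".join(parts)

    def validate(self, genome: Mapping[str, str]) -> None:
        """Check that the translated CDS reproduces ``protein_sequence``."""
        prot = translate_cds(self.cds_sequence(genome))
        if prot != self.protein_sequence:
            raise ValueError(
                f"{self.transcript_id}: translated CDS does not match the "
                f"declared protein sequence"
            )


@dataclass
class ParseReport:
    """Row accounting for a parsed mutation table."""

    n_input: int = 0
    n_records: int = 0
    n_dropped: int = 0
    n_duplicates: int = 0
    dropped_rows: list = field(default_factory=list)

    def conserves(self) -> bool:
        return self.n_input == self.n_records + self.n_dropped + self.n_duplicates


_GENOMIC_COLUMNS = {
    "gene": ["Hugo_Symbol", "gene"],
    "chromosome": ["Chromosome", "chromosome"],
    "position": ["Start_Position", "position"],
    "ref_base": ["Reference_Allele", "ref_base"],
    "alt_base": ["Tumor_Seq_Allele2", "alt_base"],
    "sample": ["Tumor_Sample_Barcode", "sample"],
    "tumor_type": ["tumor_type"],
}

_PROTEIN_COLUMNS = {
    "gene": ["gene", "Hugo_Symbol"],
    "position": ["position", "residue_position"],
    "ref_aa": ["ref_aa"],
    "alt_aa": ["alt_aa"],
    "sample": ["sample", "Tumor_Sample_Barcode"],
    "tumor_type": ["tumor_type"],
    "consequence": ["consequence"],  # optional
}


def _resolve_columns(df: pd.DataFrame, wanted: Mapping[str, Sequence[str]],
                     optional: Iterable[str] = ()) -> Mapping[str, str]:
    resolved = {}
    for key, candidates in wanted.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is None:
            if key in optional:
                continue
            raise KeyError(
                f"required column for {key!r} missing; accepted names: {list(candidates)}"
            )
        resolved[key] = found
    return resolved


def read_mutation_table(path, dialect: str = "protein") -> Tuple[list, ParseReport]:
    """Read a TSV mutation table into :class:`MutationRecord` objects.

    ``dialect='genomic'`` expects MAF-like columns (Hugo_Symbol, Chromosome,
    Start_Position, Reference_Allele, Tumor_Seq_Allele2, Tumor_Sample_Barcode,
    tumor_type); ``dialect='protein'`` expects gene, position, ref_aa, alt_aa,
    sample, tumor_type (plus an optional consequence column, defaulting to
    missense when ref and alt differ).

    Rows with unparseable coordinates are dropped and counted; duplicate
    (sample, gene, position, alt) rows are collapsed to one.  Returns the
    record list together with a :class:`ParseReport`.
    """
    if dialect not in {"genomic", "protein"}:
        raise ValueError(f"dialect must be 'genomic' or 'protein', got {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    report = ParseReport(n_input=len(df))
    if dialect == "genomic":
        cols = _resolve_columns(df, _GENOMIC_COLUMNS)
    else:
        cols = _resolve_columns(df, _PROTEIN_COLUMNS, optional=["consequence"])

    records: list[MutationRecord] = []
    seen = set()
    for idx, row in df.iterrows():
        try:
            pos = int(str(row[cols["position"]]))
            if pos < 1:
                raise ValueError
        except (ValueError, TypeError):
            report.n_dropped += 1
            report.dropped_rows.append(idx)
            continue
        if dialect == "genomic":
            ref_b = str(row[cols["ref_base"]]).upper()
            alt_b = str(row[cols["alt_base"]]).upper()
            key = (row[cols["sample"]], row[cols["gene"]], row[cols["chromosome"]], pos, alt_b)
            if key in seen:
                report.n_duplicates += 1
                continue
            seen.add(key)
            records.append(
                MutationRecord(
                    sample_id=str(row[cols["sample"]]),
                    tumor_type=str(row[cols["tumor_type"]]),
                    gene_id=str(row[cols["gene"]]),
                    consequence="other",
                    genomic=(str(row[cols["chromosome"]]), pos, ref_b, alt_b),
                )
            )
        else:
            ref_aa = str(row[cols["ref_aa"]]).upper()
            alt_aa = str(row[cols["alt_aa"]]).upper()
            key = (row[cols["sample"]], row[cols["gene"]], pos, alt_aa)
            if key in seen:
                report.n_duplicates += 1
                continue
            seen.add(key)
            if "consequence" in cols and pd.notna(row[cols["consequence"]]):
                consequence = str(row[cols["consequence"]])
            elif ref_aa == alt_aa:
                consequence = "synonymous"
            elif alt_aa == "*":
                consequence = "nonsense"
            else:
                consequence = "missense"
            records.append(
                MutationRecord(
                    sample_id=str(row[cols["sample"]]),
                    tumor_type=str(row[cols["tumor_type"]]),
                    gene_id=str(row[cols["gene"]]),
                    residue_position=pos,
                    ref_aa=ref_aa if ref_aa in _VALID_AA | {_STOP} else None,
                    alt_aa=alt_aa if alt_aa in _VALID_AA | {_STOP} else None,
                    consequence=consequence,
                )
            )
    report.n_records = len(records)
    return records, report


def select_representative_transcript(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick the representative (longest-CDS) transcript of a gene.

    Ties are broken by lexicographically smallest transcript id so the choice
    is deterministic across runs.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    genes = {t.gene_id for t in transcripts}
    if len(genes) > 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(genes)}")
    return min(transcripts, key=lambda t: (-t.cds_length, t.transcript_id))


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, trimming one trailing stop."""
    protein = str(Seq(cds).translate(table="Standard"))
    if protein.endswith(_STOP):
        protein = protein[:-1]
    return protein


def classify_consequence(ref_codon: str, alt_codon: str) -> str:
    """Classify a codon substitution under the standard genetic code."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or not set(codon) <= _VALID_BASES:
            raise ValueError(f"invalid codon {codon!r}")
    ref_aa = _CODON_TABLE[ref_codon]
    alt_aa = _CODON_TABLE[alt_codon]
    if alt_aa == _STOP and ref_aa != _STOP:
        return "nonsense"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def classify_indel(length: int) -> str:
    """Frameshift unless the inserted/deleted length is a multiple of 3."""
    if length <= 0:
        raise ValueError("indel length must be positive")
    return "inframe_indel" if length % 3 == 0 else "frameshift_indel"


def _chrom_seq(genome, chromosome: str) -> str:
    try:
        seq = genome[chromosome]
    except KeyError as exc:
        raise KeyError(f"chromosome {chromosome!r} not in genome source") from exc
    return str(seq)


def _cds_offset(tx: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """1-based offset of a genomic position within the spliced CDS, or None."""
    offset = 0
    for a, b in tx.cds_intervals:
        if a <= genomic_pos <= b:
            if tx.strand == "+":
                return offset + (genomic_pos - a + 1)
            return offset + (b - genomic_pos + 1)
        offset += b - a + 1
    return None


def map_genomic_to_protein(
    mut: MutationRecord, tx: TranscriptModel, genome: Mapping[str, str]
) -> MutationRecord:
    """Map a genomic SNV onto its protein residue and consequence.

    Positions outside the CDS are mapped with consequence ``other`` and no
    residue.  A reference-base mismatch against the genome flags the record
    (``ref_mismatch``) rather than dropping it, so QC stays auditable.
    Alleles are reverse-complemented on minus-strand transcripts.
    """
    if mut.genomic is None:
        raise ValueError("record has no genomic coordinates")
    chrom, pos, ref_base, alt_base = mut.genomic
    if not ({ref_base, alt_base} <= _VALID_BASES):
        raise ValueError(f"invalid alleles {ref_base!r}/{alt_base!r}")

    offset = _cds_offset(tx, pos)
    if offset is None:
        return replace(mut, consequence="other", residue_position=None)

    genome_base = _chrom_seq(genome, chrom)[pos - 1].upper()
    flags = set(mut.flags)
    if genome_base != ref_base:
        flags.add("ref_mismatch")

    cds_ref, cds_alt = ref_base, alt_base
    if tx.strand == "-":
        cds_ref = cds_ref.translate(_COMPLEMENT)
        cds_alt = cds_alt.translate(_COMPLEMENT)

    residue = math.ceil(offset / 3)
    codon_start = (residue - 1) * 3
    cds = tx.cds_sequence(genome)
    ref_codon = cds[codon_start : codon_start + 3]
    within = (offset - 1) % 3
    alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
    if ref_codon[within] != cds_ref:
        flags.add("ref_mismatch")

    consequence = classify_consequence(ref_codon, alt_codon)
    ref_aa = _CODON_TABLE[ref_codon]
    alt_aa = _CODON_TABLE[alt_codon]
    return replace(
        mut,
        residue_position=residue,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        flags=frozenset(flags),
    )
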