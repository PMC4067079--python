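"""FASTA ingest, annotation serialization, and the shared coordinate model.

Internal coordinates are 0-based half-open on the forward strand of the
sequence they index.  Conversion to 1-based inclusive (GFF3) happens only at
serialization time.  Minus-strand features are analysed on the extracted
reverse-complemented sequence but emitted on the forward assembly with
``strand='-'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence, Union

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .structure import ElementAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "FastaError",
    "IngestError",
    "GenomicInterval",
    "SequenceRecord",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "write_annotations",
]

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
# IUPAC nucleotide ambiguity codes other than N are collapsed to N on ingest.
_AMBIGUITY = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Malformed FASTA input."""


class IngestError(ValueError):
    """A record failed alphabet validation."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.seqid}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.seqid, self.start + offset, self.end + offset, self.strand)


@dataclass
class SequenceRecord:
    """A named sequence with a declared alphabet ('dna' or 'protein')."""

    id: str
    seq: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.seq:
            raise IngestError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _normalize_dna(record_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    if set(seq) <= DNA_ALPHABET:
        return seq
    cleaned = []
    n_ambiguous = 0
    for ch in seq:
        if ch in DNA_ALPHABET:
            cleaned.append(ch)
        elif ch in _AMBIGUITY:
            cleaned.append("N")
            n_ambiguous += 1
        else:
            raise IngestError(f"record {record_id!r}: illegal DNA residue {ch!r}")
    if n_ambiguous:
        log.warning(
            "record %r: %d IUPAC ambiguity base(s) mapped to N", record_id, n_ambiguous
        )
    return "".join(cleaned)


def _normalize_protein(record_id: str, raw: str) -> str:
    seq = raw.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise IngestError(
            f"record {record_id!r}: illegal protein residue(s) {sorted(bad)}"
        )
    return seq


def _precheck_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected FASTA header, got {stripped[:30]!r}"
                )
            return
    raise FastaError(f"{path}: empty file")


def read_fasta(path: Union[str, Path], alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    DNA records are uppercased, U is mapped to T, and IUPAC ambiguity codes
    other than N are mapped to N (with a logged warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    _precheck_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise IngestError(f"record {rec.id!r}: empty sequence")
        if alphabet == "dna":
            seq = _normalize_dna(rec.id, raw)
        else:
            seq = _normalize_protein(rec.id, raw)
        records.append(SequenceRecord(id=rec.id, seq=seq, alphabet=alphabet))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def as_mapping(
    genome: Union[str, SequenceRecord, Sequence[SequenceRecord], Mapping[str, SequenceRecord]],
) -> Mapping[str, SequenceRecord]:
    """Coerce the accepted genome argument shapes into ``{seqid: record}``."""
    if isinstance(genome, str):
        return {"genome": SequenceRecord("genome", genome)}
    if isinstance(genome, SequenceRecord):
        return {genome.id: genome}
    if isinstance(genome, Mapping):
        return genome
    return {rec.id: rec for rec in genome}


# ---------------------------------------------------------------------------
# annotation serialization


_FEATURE_ORDER = ("subtir5", "subtir3", "palindrome3", "ir", "pal5")
_FEATURE_TYPES = {
    "subtir5": "subTIR_5p",
    "subtir3": "subTIR_3p",
    "palindrome3": "palindrome_3p",
    "pal5": "palindrome_5p",
    "ir": "IR",
}


def _local_to_genome(element: GenomicInterval, start: int, end: int) -> GenomicInterval:
    """Map element-local (oriented) coordinates onto the forward assembly."""
    if element.strand == "+":
        return GenomicInterval(element.seqid, element.start + start, element.start + end, "+")
    return GenomicInterval(element.seqid, element.end - end, element.end - start, "-")


def _check_bounds(interval: GenomicInterval, lengths: Mapping[str, int] | None) -> None:
    if lengths is not None and interval.seqid in lengths:
        if interval.end > lengths[interval.seqid]:
            raise ValueError(
                f"interval {interval.seqid}:{interval.start}-{interval.end} exceeds "
                f"sequence length {lengths[interval.seqid]}"
            )


def _iter_rows(annotations: Iterable["ElementAnnotation"], lengths=None):
    for idx, ann in enumerate(annotations, start=1):
        elem = ann.element
        _check_bounds(elem, lengths)
        elem_id = getattr(ann, "name", None) or f"element{idx:05d}"
        yield elem_id, None, "element", elem, ann
        for key in _FEATURE_ORDER:
            local = ann.features.get(key)
            if local is None:
                continue
            gi = _local_to_genome(elem, local.start, local.end)
            _check_bounds(gi, lengths)
            yield f"{elem_id}.{key}", elem_id, _FEATURE_TYPES[key], gi, ann
        for j, orf in enumerate(getattr(ann, "orfs", []) or [], start=1):
            gi = _local_to_genome(elem, orf.nuc_interval.start, orf.nuc_interval.end)
            _check_bounds(gi, lengths)
            yield f"{elem_id}.orf{j}", elem_id, "ORF", gi, ann


def write_annotations(
    annotations: Sequence["ElementAnnotation"],
    path: Union[str, Path],
    format: str = "gff3",
    lengths: Mapping[str, int] | None = None,
    header_meta: Mapping[str, str] | None = None,
) -> None:
    """Write element annotations as GFF3 (1-based inclusive), BED6, or TSV.

    ``lengths`` (optional) enables bounds checking against sequence lengths.
    """
    if format not in ("gff3", "bed", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    meta = "".join(f"# {k}={v}\n" for k, v in (header_meta or {}).items())
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(meta)
            for fid, parent, ftype, gi, ann in _iter_rows(annotations, lengths):
                attrs = f"ID={fid}"
                if parent:
                    attrs += f";Parent={parent}"
                else:
                    attrs += f";structure_type={ann.structure_type}"
                fh.write(
                    "\t".join(
                        [
                            gi.seqid,
                            "helentron-scan",
                            ftype,
                            str(gi.start + 1),
                            str(gi.end),
                            f"{getattr(ann, 'score', 0.0):.1f}" if not parent else ".",
                            gi.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
        elif format == "bed":
            fh.write("# BED6: chrom start end name score strand\n")
            fh.write(meta)
            for fid, parent, ftype, gi, ann in _iter_rows(annotations, lengths):
                if parent is not None:
                    continue  # BED carries element rows only
                fh.write(
                    "\t".join(
                        [
                            gi.seqid,
                            str(gi.start),
                            str(gi.end),
                            f"{fid}|{ann.structure_type}",
                            str(int(getattr(ann, "score", 0))),
                            gi.strand,
                        ]
                    )
                    + "\n"
                )
        else:
            fh.write(meta)
            fh.write(
                "element_id\tseqid\tstart\tend\tstrand\tstructure_type\tfeature\t"
                "feature_start\tfeature_end\n"
            )
            for fid, parent, ftype, gi, ann in _iter_rows(annotations, lengths):
                root = parent if parent else fid
                fh.write(
                    f"{root}\t{gi.seqid}\t{gi.start}\t{gi.end}\t{gi.strand}\t"
                    f"{ann.structure_type}\t{ftype}\t{gi.start}\t{gi.end}\n"
                )
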