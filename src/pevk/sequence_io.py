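"""Sequence and annotation I/O plus three-frame translation.

The scanner operates on translated genomic DNA, so this module pins down the
exact correspondence between amino-acid and nucleotide coordinates: frame
``f`` maps amino-acid index ``i`` to the half-open nucleotide interval
``[f + 3i, f + 3i + 3)``.  All internal coordinates are 0-based, half-open;
BED output keeps that convention while GFF3 output is 1-based inclusive.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = frozenset("ACGTN")

__all__ = [
    "GenomicSequence",
    "FrameTranslation",
    "read_fasta",
    "write_fasta",
    "translate_three_frames",
    "translate_frame",
    "aa_to_nt",
    "nt_to_aa",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_annotation",
]


@dataclass(frozen=True)
class GenomicSequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues) if c in bad
            )
            raise ValueError(
                f"illegal character {self.residues[pos]!r} at position "
                f"{pos + 1} in record {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FrameTranslation:
    """Forward-frame translation with an exact aa↔nt coordinate map."""

    frame: int
    aa_seq: str
    origin: str

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")

    def __len__(self) -> int:
        return len(self.aa_seq)


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"illegal character {seq[pos]!r} at position {pos + 1} "
            f"in record {record_id!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a FASTA file into :class:`GenomicSequence` records.

    Residues are uppercased and U is mapped to T; any character outside
    {A, C, G, T, N, U} raises :class:`ValueError` naming the offending
    record and 1-based position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomicSequence(rec.id, _normalize(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 70
) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate_frame(seq: GenomicSequence, frame: int) -> FrameTranslation:
    """Translate one forward frame; N-containing codons become 'X'."""
    if len(seq) < 3:
        raise ValueError(f"sequence {seq.id!r} shorter than 3 nt")
    sub = seq.residues[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    aa = str(Seq(sub).translate())
    # Biopython translates N-containing codons to 'X' where ambiguous and
    # to a residue where the ambiguity is synonymous; force 'X' for any N.
    if "N" in sub:
        aa = "".join(
            "X" if "N" in sub[3 * i : 3 * i + 3] else c for i, c in enumerate(aa)
        )
    return FrameTranslation(frame=frame, aa_seq=aa, origin=seq.id)


def translate_three_frames(seq: GenomicSequence) -> list[FrameTranslation]:
    """Translate the three forward reading frames (no reverse strand)."""
    return [translate_frame(seq, f) for f in (0, 1, 2)]


def aa_to_nt(frame: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map an amino-acid interval in a frame to its nucleotide interval."""
    if not 0 <= aa_start < aa_end:
        raise ValueError(f"invalid aa interval [{aa_start}, {aa_end})")
    return frame + 3 * aa_start, frame + 3 * aa_end


def nt_to_aa(frame: int, nt_start: int, nt_end: int) -> tuple[int, int]:
    """Inverse of :func:`aa_to_nt`; requires frame-aligned codon bounds."""
    if (nt_start - frame) % 3 or (nt_end - frame) % 3:
        raise ValueError(
            f"nt interval [{nt_start}, {nt_end}) is not codon-aligned in frame {frame}"
        )
    return (nt_start - frame) // 3, (nt_end - frame) // 3


# ---------------------------------------------------------------------------
# Annotation tables (BED 0-based half-open; GFF3 1-based inclusive)


@dataclass
class AnnotationRecord:
    """One annotated interval on a sequence (internal 0-based half-open)."""

    seqid: str
    start: int
    end: int
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def read_bed(path: str | Path) -> list[AnnotationRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"malformed BED line: {line!r}")
        score = None
        if len(f) > 4 and f[4] not in (".", ""):
            score = float(f[4])
        records.append(
            AnnotationRecord(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ".", score)
        )
    records.sort(key=lambda r: (r.seqid, r.start))
    return records


def write_bed(path: str | Path, records: Sequence[AnnotationRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            score = "." if r.score is None else str(int(round(r.score)))
            fh.write(f"{r.seqid}\t{r.start}\t{r.end}\t{r.name}\t{score}\t+\n")


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        name = "."
        for kv in f[8].split(";"):
            if kv.startswith(("ID=", "Name=")):
                name = kv.split("=", 1)[1]
                break
        score = None if f[5] == "." else float(f[5])
        # GFF3 is 1-based inclusive
        records.append(AnnotationRecord(f[0], int(f[3]) - 1, int(f[4]), name, score))
    records.sort(key=lambda r: (r.seqid, r.start))
    return records


def write_gff3(
    path: str | Path,
    records: Sequence[AnnotationRecord],
    source: str = "pevk",
    feature: str = "exon",
    attributes: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(records):
            score = "." if r.score is None else f"{r.score:g}"
            attr = attributes[i] if attributes is not None else f"ID={r.name}"
            fh.write(
                f"{r.seqid}\t{source}\t{feature}\t{r.start + 1}\t{r.end}\t"
                f"{score}\t+\t.\t{attr}\n"
            )


def read_annotation(path: str | Path, fmt: str | None = None) -> list[AnnotationRecord]:
    """Read BED or GFF3, auto-detected by extension unless ``fmt`` is given."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".gff", ".gff3"):
            fmt = "gff3"
        elif suffix == ".bed":
            fmt = "bed"
        else:
            raise ValueError(
                f"cannot infer annotation format from {path.name!r}; pass fmt="
            )
    if fmt == "bed":
        return read_bed(path)
    if fmt == "gff3":
        return read_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")
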