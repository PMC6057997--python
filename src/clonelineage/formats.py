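"""Readers and writers for the standard formats the pipeline touches.

All coordinates inside the package are 0-based, half-open. SAM and VCF are
1-based on disk; the conversion happens here (via pysam) and nowhere else.
Reads are stored in reference orientation (SAM already stores SEQ that way),
so downstream phasing logic never sees strand.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

# pysam numeric CIGAR codes for the ops we handle
_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CIGAR_OP = {v: k for k, v in _CIGAR_CODE.items()}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, optionally with per-base Phred scores."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LocusAnnotation:
    """Location of a locus on a scaffold: sorted, non-overlapping intervals."""

    locus_id: str
    scaffold_id: str
    intervals: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"locus {self.locus_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.intervals:
            if start < 0 or end <= start:
                raise FormatError(f"locus {self.locus_id}: bad interval ({start},{end})")
            if start < prev_end:
                raise FormatError(f"locus {self.locus_id}: intervals overlap or unsorted")
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class AlignedRead:
    """One read of a pair, aligned to a locus or scaffold.

    ``start`` is the 0-based reference start; ``cigar`` is a list of
    (op, length) with ops M/I/D/S. Sequence is in reference orientation.
    """

    read_id: str
    pair_id: str
    locus_id: str
    start: int
    sequence: str
    qualities: np.ndarray
    cigar: list[tuple[str, int]] = field(default_factory=list)
    source: str = "unknown"
    is_read1: bool = True

    def __post_init__(self) -> None:
        if not self.cigar:
            self.cigar = [("M", len(self.sequence))]
        qlen = sum(n for op, n in self.cigar if op in "MIS")
        if qlen != len(self.sequence):
            raise FormatError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases, "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def ref_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in "MD")

    def aligned_blocks(self) -> list[tuple[int, int, int]]:
        """Ungapped match blocks as (ref_start, query_start, length)."""
        blocks = []
        rpos, qpos = self.start, 0
        for op, n in self.cigar:
            if op == "M":
                blocks.append((rpos, qpos, n))
                rpos += n
                qpos += n
            elif op == "I" or op == "S":
                qpos += n
            elif op == "D":
                rpos += n
        return blocks

    def indel_events(self) -> list[tuple[int, str]]:
        """Indel alleles as (anchor_ref_pos, edit) with VCF-style left anchor.

        ``edit`` is ``I:<bases>`` for an insertion after the anchor position,
        ``D:<length>`` for a deletion starting just after the anchor.
        """
        events = []
        rpos, qpos = self.start, 0
        for op, n in self.cigar:
            if op == "M":
                rpos += n
                qpos += n
            elif op == "I":
                events.append((rpos - 1, f"I:{self.sequence[qpos:qpos + n]}"))
                qpos += n
            elif op == "D":
                events.append((rpos - 1, f"D:{n}"))
                rpos += n
            elif op == "S":
                qpos += n
        return events

    def base_at(self, ref_pos: int) -> tuple[str, int] | None:
        """Observed base and quality at a reference position, if aligned."""
        for rs, qs, n in self.aligned_blocks():
            if rs <= ref_pos < rs + n:
                i = qs + (ref_pos - rs)
                return self.sequence[i], int(self.qualities[i])
        return None


@dataclass
class VcfVariant:
    """A single VCF record mapped to internal coordinates."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _validate_fasta_lines(path: str) -> None:
    with open(path) as fh:
        in_record = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if not line[1:].split():
                    raise FormatError(f"{path}:{lineno}: FASTA header without id")
                in_record = True
            else:
                if not in_record:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                bad = set(line.upper()) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC characters {sorted(bad)}"
                    )


def read_fasta(path: str) -> list[SequenceRecord]:
    _validate_fasta_lines(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: list[SequenceRecord], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(path, "fastq"):
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def write_fastq(records: list[SequenceRecord], path: str) -> None:
    out = []
    for rec in records:
        if rec.qualities is None:
            raise FormatError(f"record {rec.id}: FASTQ requires qualities")
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        sr.letter_annotations["phred_quality"] = list(rec.qualities)
        out.append(sr)
    SeqIO.write(out, path, "fastq")


# ---------------------------------------------------------------------------
# SAM


def _sam_header(reference_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
        }
    )


def write_sam(
    reads: list[AlignedRead], reference_lengths: dict[str, int], path: str
) -> None:
    """Write aligned reads as text SAM, pairing mates by pair_id."""
    header = _sam_header(reference_lengths)
    mates: dict[str, list[AlignedRead]] = {}
    for read in reads:
        mates.setdefault(read.pair_id, []).append(read)
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for read in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = read.pair_id
            a.query_sequence = read.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                pysam.qualities_to_qualitystring(list(read.qualities))
            )
            a.reference_id = header.get_tid(read.locus_id)
            a.reference_start = read.start
            a.cigartuples = [(_CIGAR_CODE[op], n) for op, n in read.cigar]
            a.mapping_quality = 60
            flag = 0x1 | 0x2  # paired, proper pair
            flag |= 0x40 if read.is_read1 else 0x80
            pair = mates.get(read.pair_id, [])
            mate = next((m for m in pair if m is not read), None)
            if mate is not None:
                a.next_reference_id = header.get_tid(mate.locus_id)
                a.next_reference_start = mate.start
            a.flag = flag
            a.set_tag("XS", read.source)
            sam.write(a)


def read_sam(path: str) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for i, rec in enumerate(sam):
            if rec.is_unmapped:
                continue
            cigar = [(_CIGAR_OP.get(code, "?"), n) for code, n in rec.cigartuples or []]
            if "?" in {op for op, _ in cigar}:
                raise FormatError(f"read {rec.query_name}: unsupported CIGAR op")
            quals = rec.query_qualities
            seq = rec.query_sequence or ""
            try:
                read = AlignedRead(
                    read_id=f"{rec.query_name}/{1 if rec.is_read1 else 2}",
                    pair_id=rec.query_name,
                    locus_id=rec.reference_name,
                    start=rec.reference_start,
                    sequence=seq.upper(),
                    qualities=np.asarray(quals if quals is not None else [30] * len(seq),
                                         dtype=np.uint8),
                    cigar=cigar,
                    source=rec.get_tag("XS") if rec.has_tag("XS") else "unknown",
                    is_read1=not rec.is_read2,
                )
            except FormatError as exc:
                raise FormatError(f"{path}: record {i}: {exc}") from exc
            reads.append(read)
    return reads


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: list[VcfVariant],
    contig_lengths: dict[str, int],
    path: str,
    sample: str | None = None,
    genotypes: list[tuple[int, int]] | None = None,
) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "clonelineage")
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("GT", 1, "String", "Genotype")
    if sample is not None:
        header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i, var in enumerate(variants):
            rec = vcf.new_record(
                contig=var.chrom,
                start=var.pos,
                stop=var.pos + len(var.ref),
                alleles=(var.ref,) + tuple(var.alts),
                qual=var.qual,
            )
            if "DP" in var.info:
                rec.info["DP"] = int(var.info["DP"])
            if sample is not None and genotypes is not None:
                rec.samples[sample]["GT"] = genotypes[i]
            vcf.write(rec)


def read_vcf(path: str) -> list[VcfVariant]:
    variants = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            variants.append(
                VcfVariant(
                    chrom=rec.chrom,
                    pos=rec.start,  # pysam converts to 0-based
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=rec.qual,
                    info=dict(rec.info),
                )
            )
    return variants


# ---------------------------------------------------------------------------
# BED / GFF3 (read-only, for locus coordinates)


def read_bed(path: str) -> list[LocusAnnotation]:
    loci = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 columns")
            scaffold, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{scaffold}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 else "+"
            loci.append(
                LocusAnnotation(
                    locus_id=name,
                    scaffold_id=scaffold,
                    intervals=[(start, end)],
                    strand=strand,
                )
            )
    return loci


def write_bed(loci: list[LocusAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            for start, end in locus.intervals:
                fh.write(
                    f"{locus.scaffold_id}\t{start}\t{end}\t{locus.locus_id}\t0\t{locus.strand}\n"
                )


def read_gff_cds(path: str) -> list[LocusAnnotation]:
    """Collect CDS features from a GFF3 file, grouped by their Parent (or ID)."""
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line with {len(cols)} columns")
            if cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            key = attrs.get("Parent", attrs.get("ID", f"cds_{lineno}"))
            grp = groups.setdefault(
                key, {"scaffold": cols[0], "strand": cols[6], "intervals": []}
            )
            # GFF3 is 1-based inclusive; convert at this boundary only.
            grp["intervals"].append((int(cols[3]) - 1, int(cols[4])))
    loci = []
    for key, grp in groups.items():
        loci.append(
            LocusAnnotation(
                locus_id=key,
                scaffold_id=grp["scaffold"],
                intervals=sorted(grp["intervals"]),
                strand=grp["strand"],
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Report writers


def write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_tsv(rows: list[dict], path: str) -> None:
    import pandas as pd

    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
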