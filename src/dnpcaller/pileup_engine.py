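"""Per-read, per-position pileup over the 4-base DNP window.

A DNP (double nucleotide polymorphism) is a pair of adjacent variant
positions that segregate as a single two-base allele.  Genotyping one
requires knowing, for every read, which base it carries at *both*
positions — so the pileup here always tags each observation with its
read identifier, exactly what ``samtools mpileup --output-QNAME``
exposes in its text dialect.

Two interchangeable backends are provided:

* :func:`pileup_window` — native pileup over an indexed BAM via pysam
  (the default path);
* :func:`parse_mpileup_line` — a parser for the standard mpileup text
  dialect with the read-name column enabled, used both as an
  independent oracle in tests and for users who pre-generate pileups.

All coordinates are 1-based inclusive, matching the mpileup convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

#: Marker used as the ``base`` of a pileup entry whose position is
#: spanned by a deletion on that read ('*' in the mpileup dialect).
DELETION = "*"

_VALID_DINUC_CHARS = set("ACGT")

# unmapped | secondary | qc-fail | duplicate | supplementary
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

DEFAULT_MIN_BASEQ = 13
DEFAULT_MIN_MAPQ = 0
DEFAULT_MAX_DEPTH = 100_000


class PileupParseError(ValueError):
    """Raised when an mpileup text record cannot be decoded consistently."""


@dataclass(frozen=True)
class DNPSite:
    """One putative DNP: two adjacent positions and their two dinucleotide alleles.

    Positions are 1-based; ``pos2`` must equal ``pos1 + 1`` (adjacency is
    definitional).  Alleles are 2-character uppercase strings over ACGT and
    must differ.
    """

    chrom: str
    pos1: int
    pos2: int
    ref_dinuc: str
    alt_dinuc: str

    def __post_init__(self) -> None:
        if self.pos2 != self.pos1 + 1:
            raise ValueError(
                f"DNP positions must be adjacent: got pos1={self.pos1}, "
                f"pos2={self.pos2} on {self.chrom}"
            )
        if self.pos1 < 1:
            raise ValueError(f"positions must be >= 1, got pos1={self.pos1}")
        for name, allele in (("ref", self.ref_dinuc), ("alt", self.alt_dinuc)):
            if len(allele) != 2 or not set(allele) <= _VALID_DINUC_CHARS:
                raise ValueError(
                    f"{name} allele must be 2 uppercase ACGT characters, "
                    f"got {allele!r}"
                )
        if self.ref_dinuc == self.alt_dinuc:
            raise ValueError(
                f"ref and alt dinucleotides are identical ({self.ref_dinuc}) "
                f"at {self.chrom}:{self.pos1}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.chrom}:{self.pos1}-{self.pos2} "
            f"{self.ref_dinuc}>{self.alt_dinuc}"
        )


@dataclass
class PileupEntry:
    """One read's observation at one position.

    ``base`` is the aligned base on the forward reference strand
    (reverse-strand reads are already reverse-complemented by the
    aligner), normalized to uppercase, or :data:`DELETION` when the
    position is spanned by a deletion in this read.  ``indel_after``
    flags an insertion or deletion recorded immediately *after* this
    position on this read.
    """

    read_id: str
    base: str
    qual: int
    indel_after: bool = False
    is_deletion: bool = False
    strand: str = "+"


@dataclass
class PileupColumn:
    """All per-read observations at one genomic position."""

    chrom: str
    pos: int
    ref_base: str
    entries: list[PileupEntry] = field(default_factory=list)


def build_window(site: DNPSite, contig_length: int) -> list[int]:
    """Return the pileup window for *site*: both DNP positions plus the
    directly upstream and downstream flanks (four bases in total),
    clamped to ``[1, contig_length]``.

    The flanks exist so reads carrying sequencing-error indels next to
    the DNP can be recognized and discarded; at a contig edge a missing
    flank is simply absent from the window.
    """
    if site.pos2 > contig_length:
        raise ValueError(
            f"site {site} extends past the end of contig "
            f"{site.chrom} (length {contig_length})"
        )
    window = [site.pos1 - 1, site.pos1, site.pos2, site.pos2 + 1]
    return [p for p in window if 1 <= p <= contig_length]


def pileup_window(
    alignment_file: str,
    reference: str,
    site: DNPSite,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> list[PileupColumn]:
    """Native pileup over the 4-base window of *site* in an indexed BAM.

    Every entry carries the read name.  Unmapped, secondary,
    supplementary, duplicate and QC-fail alignments are excluded, as are
    reads below the mapping-quality floor; bases below the base-quality
    floor are dropped (the read then does not cover that position).
    Overlapping mate pairs are *not* collapsed here — the caller module
    resolves them by read identifier — and no BAQ recomputation is done.

    A contig absent from the BAM header is logged and yields
    zero-coverage columns rather than an error.
    """
    with pysam.AlignmentFile(alignment_file, "rb") as bam, pysam.FastaFile(
        reference
    ) as fasta:
        if site.chrom not in bam.references:
            logger.warning(
                "contig %s absent from %s header; skipping site %s",
                site.chrom,
                alignment_file,
                site,
            )
            window = build_window(site, fasta.get_reference_length(site.chrom))
            return [
                PileupColumn(site.chrom, p, fasta.fetch(site.chrom, p - 1, p).upper())
                for p in window
            ]
        contig_length = bam.get_reference_length(site.chrom)
        window = build_window(site, contig_length)
        columns: dict[int, PileupColumn] = {
            p: PileupColumn(
                site.chrom, p, fasta.fetch(site.chrom, p - 1, p).upper()
            )
            for p in window
        }
        for col in bam.pileup(
            site.chrom,
            window[0] - 1,
            window[-1],
            truncate=True,
            stepper="samtools",
            fastafile=fasta,
            min_base_quality=min_baseq,
            min_mapping_quality=min_mapq,
            max_depth=max_depth,
            compute_baq=False,
            ignore_overlaps=False,
            flag_filter=_EXCLUDE_FLAGS,
        ):
            pos = col.reference_pos + 1
            if pos not in columns:
                continue
            target = columns[pos]
            for pr in col.pileups:
                if pr.is_refskip:
                    continue
                aln = pr.alignment
                strand = "-" if aln.is_reverse else "+"
                if pr.is_del:
                    target.entries.append(
                        PileupEntry(
                            read_id=aln.query_name,
                            base=DELETION,
                            qual=0,
                            indel_after=pr.indel != 0,
                            is_deletion=True,
                            strand=strand,
                        )
                    )
                else:
                    qpos = pr.query_position
                    target.entries.append(
                        PileupEntry(
                            read_id=aln.query_name,
                            base=aln.query_sequence[qpos].upper(),
                            qual=aln.query_qualities[qpos],
                            indel_after=pr.indel != 0,
                            is_deletion=False,
                            strand=strand,
                        )
                    )
        return [columns[p] for p in window]


def parse_mpileup_line(
    line: str, qname_field_present: bool = True, line_number: int | None = None
) -> PileupColumn:
    """Decode one record of the mpileup text dialect into a :class:`PileupColumn`.

    Expects the tab-delimited fields chrom, pos, ref base, depth, base
    string, quality string and — when *qname_field_present* — a
    comma-separated read-name string aligned positionally with the base
    string.  The base-string grammar handled here:

    ``.``/``,``
        match to the reference on the forward/reverse strand;
    ``ACGTN``/``acgtn``
        mismatch on the forward/reverse strand;
    ``^X``
        read start (the following character is a mapping quality, skipped);
    ``$``
        read end;
    ``+N<seq>`` / ``-N<seq>``
        insertion/deletion *following* this position: sets
        ``indel_after`` on the preceding entry and consumes N characters;
    ``*`` (or ``#``)
        position spanned by a deletion: entry kept with
        ``is_deletion=True``.  The classic ``*`` token does not encode
        the strand (``#`` appears only when the producing tool is asked
        to mark reverse-strand deletions), so deletion entries default
        to strand ``+``;
    ``>`` / ``<``
        reference skip: consumes a quality/name slot but yields no entry.

    Per-entry quality is ``ord(char) - 33``.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    min_fields = 7 if qname_field_present else 6
    # zero-depth records may omit trailing columns entirely
    if len(fields) < 4:
        raise PileupParseError(f"too few fields in mpileup record{where}")
    chrom, pos_s, ref_base = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_s)
        depth = int(fields[3])
    except ValueError as exc:
        raise PileupParseError(f"bad pos/depth field{where}: {exc}") from exc
    column = PileupColumn(chrom, pos, ref_base.upper())
    if depth == 0:
        return column
    if len(fields) < min_fields:
        raise PileupParseError(f"missing base/quality/name columns{where}")
    bases, quals = fields[4], fields[5]
    names = fields[6].split(",") if qname_field_present else None

    entries: list[PileupEntry | None] = []  # None marks a refskip slot
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            # indel following the previous entry's position
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"malformed indel token{where}")
            length = int(bases[i + 1 : j])
            i = j + length
            for prev in reversed(entries):
                if prev is not None:
                    prev.indel_after = True
                    break
            continue
        slot = len(entries)
        qual = ord(quals[slot]) - 33 if slot < len(quals) else 0
        if c in "><":
            entries.append(None)
        elif c in "*#":
            entries.append(
                PileupEntry(
                    read_id="",
                    base=DELETION,
                    qual=0,
                    is_deletion=True,
                    strand="-" if c == "#" else "+",
                )
            )
        elif c == ".":
            entries.append(
                PileupEntry(read_id="", base=ref_base.upper(), qual=qual, strand="+")
            )
        elif c == ",":
            entries.append(
                PileupEntry(read_id="", base=ref_base.upper(), qual=qual, strand="-")
            )
        elif c.upper() in "ACGTN":
            entries.append(
                PileupEntry(
                    read_id="",
                    base=c.upper(),
                    qual=qual,
                    strand="-" if c.islower() else "+",
                )
            )
        else:
            raise PileupParseError(f"unexpected pileup character {c!r}{where}")
        i += 1

    if len(entries) != depth:
        raise PileupParseError(
            f"decoded {len(entries)} entries but depth field says {depth}{where}"
        )
    if len(quals) != depth:
        raise PileupParseError(
            f"quality string length {len(quals)} != depth {depth}{where}"
        )
    if names is not None:
        if len(names) != depth:
            raise PileupParseError(
                f"read-name count {len(names)} != depth {depth}{where}"
            )
        for slot, entry in enumerate(entries):
            if entry is not None:
                entry.read_id = names[slot]
    column.entries = [e for e in entries if e is not None]
    return column


def parse_mpileup(
    text: str, qname_field_present: bool = True
) -> list[PileupColumn]:
    """Parse a whole mpileup document (one column per non-empty line)."""
    return [
        parse_mpileup_line(line, qname_field_present, line_number=k + 1)
        for k, line in enumerate(text.splitlines())
        if line.strip()
    ]
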