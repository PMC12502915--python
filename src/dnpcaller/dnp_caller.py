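"""Core DNP genotyping: read-backed dinucleotide reconstruction.

The method joins the four pileup columns of a DNP window by read
identifier, so each read contributes a two-base microhaplotype observed
on a single chromosome.  Reads carrying indels anywhere in the window
are discarded (sequencing-error indels bias the call, typically toward
the reference), the remaining dinucleotides are tallied against the
reference and alternative alleles, and a biallelic diploid genotype is
assigned from log10 likelihoods.

Because the two derived bases of a true DNP travel together on one
haplotype, a heterozygote shows reads matching the reference or the
alternative dinucleotide.  Two adjacent SNPs in trans instead put one
derived base on each haplotype: no read matches either allele, every
read lands in ``N_Other``, and the call is refused — this is what lets
the method discriminate single-event DNPs from independent adjacent
SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .pileup_engine import (
    DEFAULT_MAX_DEPTH,
    DEFAULT_MIN_BASEQ,
    DEFAULT_MIN_MAPQ,
    DNPSite,
    PileupColumn,
    pileup_window,
)

logger = logging.getLogger(__name__)

#: Reads whose dinucleotide matches neither allele must stay below this
#: fraction of the informative (ref + alt) reads for a call to be made.
OTHER_RATIO_THRESHOLD = 0.1

_LOG10_HALF = math.log10(0.5)


@dataclass
class ReadObservation:
    """One read's joined view across the DNP window.

    ``base1``/``base2`` are the bases at the two DNP positions (``None``
    when the read has no usable base there: not covered, deletion, or
    below the quality floor).  ``indel_any`` is true when an indel
    annotation was seen on this read at *any* window position it covers,
    flanks included.
    """

    read_id: str
    base1: str | None = None
    base2: str | None = None
    qual1: int = 0
    qual2: int = 0
    indel_any: bool = False

    @property
    def covers_both(self) -> bool:
        return self.base1 is not None and self.base2 is not None

    @property
    def dinucleotide(self) -> str | None:
        if not self.covers_both:
            return None
        return self.base1 + self.base2


@dataclass
class DNPCounts:
    """Per-site read tallies after indel filtering."""

    n_ref: int = 0
    n_alt: int = 0
    n_other: int = 0
    combined: dict[str, int] = field(default_factory=dict)
    reads_discarded_for_indels: int = 0
    total_considered: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_ref + self.n_alt + self.n_other

    @property
    def ratio_discarded(self) -> float:
        if self.total_considered == 0:
            return 0.0
        return self.reads_discarded_for_indels / self.total_considered


@dataclass
class GenotypeCall:
    """Assigned genotype plus the three log10 genotype likelihoods.

    ``gt`` is "0/0", "0/1", "1/1" or "NA"; ``other_ratio`` is
    N_Other/(N_ref+N_alt), ``None`` when the denominator is zero.
    ``na_reason`` records *why* a call was refused (the table output
    prints plain "NA" either way).
    """

    gt: str
    gl0: float
    gl1: float
    gl2: float
    other_ratio: float | None
    na_reason: str | None = None


@dataclass
class DNPCallRecord:
    """Result for one sample at one site."""

    site: DNPSite
    counts: DNPCounts
    call: GenotypeCall

    @property
    def ratio_discarded(self) -> float:
        return self.counts.ratio_discarded


def group_reads(
    columns: list[PileupColumn], site: DNPSite
) -> list[ReadObservation]:
    """Join window pileup columns by read identifier.

    Returns one observation per distinct read name seen anywhere in the
    window, in order of first appearance.  When overlapping mates give
    the same read name two entries at one position, they are merged into
    a consensus if the bases agree (keeping the higher quality); a base
    disagreement between mates drops the read entirely — the fragment is
    one chromosome, and neither double-counting nor guessing is safe.
    """
    obs: dict[str, ReadObservation] = {}
    dropped: set[str] = set()
    for col in columns:
        # collapse overlapping-mate duplicates within this column first;
        # slot layout: [base, qual, indel_after, is_deletion]
        merged: dict[str, list] = {}
        order: list[str] = []
        for entry in col.entries:
            rid = entry.read_id
            if rid not in merged:
                merged[rid] = [entry.base, entry.qual, entry.indel_after, entry.is_deletion]
                order.append(rid)
            else:
                slot = merged[rid]
                slot[2] = slot[2] or entry.indel_after
                slot[3] = slot[3] or entry.is_deletion
                if entry.base != slot[0]:
                    dropped.add(rid)
                elif entry.qual > slot[1]:
                    slot[1] = entry.qual
        for rid in order:
            base, qual, indel_after, is_deletion = merged[rid]
            ob = obs.setdefault(rid, ReadObservation(read_id=rid))
            if indel_after or is_deletion:
                ob.indel_any = True
            if is_deletion:
                continue
            if col.pos == site.pos1:
                ob.base1, ob.qual1 = base, qual
            elif col.pos == site.pos2:
                ob.base2, ob.qual2 = base, qual
    if dropped:
        logger.debug(
            "site %s: dropped %d read(s) with disagreeing overlapping mates",
            site,
            len(dropped),
        )
    return [ob for rid, ob in obs.items() if rid not in dropped]


def filter_reads(
    observations: list[ReadObservation],
) -> tuple[list[ReadObservation], int, int]:
    """Apply the coverage and indel discard rules.

    Only reads with a usable base at both DNP positions are considered;
    among those, any read with an indel annotation anywhere in its
    window footprint is discarded and counted.  Returns
    ``(retained, n_discarded_indels, total_considered)``.
    """
    considered = [ob for ob in observations if ob.covers_both]
    retained = [ob for ob in considered if not ob.indel_any]
    n_discarded = len(considered) - len(retained)
    return retained, n_discarded, len(considered)


def count_dinucleotides(
    retained: list[ReadObservation],
    site: DNPSite,
    reads_discarded_for_indels: int = 0,
    total_considered: int | None = None,
) -> DNPCounts:
    """Tally each retained read's dinucleotide against the two alleles.

    Dinucleotides containing N support neither allele and count as
    *other*.  ``combined`` keeps every distinct dinucleotide observed
    with its read count.
    """
    counts = DNPCounts(
        reads_discarded_for_indels=reads_discarded_for_indels,
        total_considered=(
            len(retained) + reads_discarded_for_indels
            if total_considered is None
            else total_considered
        ),
    )
    for ob in retained:
        dinuc = ob.dinucleotide
        counts.combined[dinuc] = counts.combined.get(dinuc, 0) + 1
        if dinuc == site.ref_dinuc:
            counts.n_ref += 1
        elif dinuc == site.alt_dinuc:
            counts.n_alt += 1
        else:
            counts.n_other += 1
    return counts


def genotype_likelihoods(
    retained: list[ReadObservation], site: DNPSite
) -> tuple[float, float, float]:
    """Log10 likelihoods of 0, 1 and 2 copies of the alternative dinucleotide.

    A biallelic diploid model in the style of single-base genotype
    likelihoods, adapted to dinucleotide alleles: only reads matching
    the reference or alternative dinucleotide are informative, and each
    read's error probability comes from the arithmetic mean of its two
    phred base qualities, eps = 10**(-(q1+q2)/20).  For a read showing
    the reference, the factor for g alt copies is
    ((2-g)(1-eps) + g*eps)/2; for a read showing the alternative, the
    complementary form.  With no informative reads all three
    likelihoods are 0 (the empty product).
    """
    gl0 = gl1 = gl2 = 0.0
    for ob in retained:
        dinuc = ob.dinucleotide
        if dinuc == site.ref_dinuc:
            is_alt = False
        elif dinuc == site.alt_dinuc:
            is_alt = True
        else:
            continue
        mean_q = (ob.qual1 + ob.qual2) / 2.0
        eps = 10.0 ** (-mean_q / 10.0)
        p_match = 1.0 - eps
        if is_alt:
            gl0 += math.log10(eps)
            gl2 += math.log10(p_match)
        else:
            gl0 += math.log10(p_match)
            gl2 += math.log10(eps)
        gl1 += _LOG10_HALF
    return gl0, gl1, gl2


def assign_genotype(
    counts: DNPCounts, gls: tuple[float, float, float]
) -> GenotypeCall:
    """Assign a genotype from the tallies and likelihoods, or refuse.

    No call is made when no read supports either allele, when
    N_Other/(N_ref+N_alt) exceeds 0.1 (strictly), or when the maximum
    likelihood is tied.
    """
    gl0, gl1, gl2 = gls
    n_informative = counts.n_ref + counts.n_alt
    if n_informative == 0:
        return GenotypeCall("NA", gl0, gl1, gl2, None, na_reason="no_informative_reads")
    other_ratio = counts.n_other / n_informative
    if other_ratio > OTHER_RATIO_THRESHOLD:
        return GenotypeCall(
            "NA", gl0, gl1, gl2, other_ratio, na_reason="other_ratio_exceeded"
        )
    best = max(gl0, gl1, gl2)
    winners = [g for g, gl in enumerate((gl0, gl1, gl2)) if gl == best]
    if len(winners) > 1:
        return GenotypeCall(
            "NA", gl0, gl1, gl2, other_ratio, na_reason="likelihood_tie"
        )
    gt = ("0/0", "0/1", "1/1")[winners[0]]
    return GenotypeCall(gt, gl0, gl1, gl2, other_ratio)


def call_from_columns(columns: list[PileupColumn], site: DNPSite) -> DNPCallRecord:
    """Run the calling chain on pre-computed window columns."""
    observations = group_reads(columns, site)
    retained, n_discarded, total = filter_reads(observations)
    counts = count_dinucleotides(retained, site, n_discarded, total)
    gls = genotype_likelihoods(retained, site)
    call = assign_genotype(counts, gls)
    return DNPCallRecord(site=site, counts=counts, call=call)


def call_dnp(
    alignment_file: str,
    reference: str,
    site: DNPSite,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> DNPCallRecord:
    """Genotype one DNP site in one sample, end to end.

    Orchestrates pileup -> read grouping -> indel filtering ->
    dinucleotide counting -> likelihoods -> genotype assignment.
    Deterministic for fixed inputs.  A site that fails in the pileup
    stage yields a zero-count "NA" record and a logged warning.
    """
    try:
        columns = pileup_window(
            alignment_file,
            reference,
            site,
            min_baseq=min_baseq,
            min_mapq=min_mapq,
            max_depth=max_depth,
        )
    except (OSError, ValueError) as exc:
        logger.warning("site %s failed during pileup: %s", site, exc)
        counts = DNPCounts()
        call = GenotypeCall("NA", 0.0, 0.0, 0.0, None, na_reason="pileup_error")
        return DNPCallRecord(site=site, counts=counts, call=call)
    return call_from_columns(columns, site)


def call_sample(
    alignment_file: str,
    reference: str,
    sites: list[DNPSite],
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> list[DNPCallRecord]:
    """Genotype every site of a panel in one sample, preserving panel order."""
    return [
        call_dnp(
            alignment_file,
            reference,
            site,
            min_baseq=min_baseq,
            min_mapq=min_mapq,
            max_depth=max_depth,
        )
        for site in sites
    ]
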