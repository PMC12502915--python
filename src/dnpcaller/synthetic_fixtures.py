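"""Self-contained synthetic test worlds with known genotypic truth.

Generates a random reference FASTA, a panel of putative DNP sites and
sorted, indexed BAMs of simulated reads, covering every read signature
the caller must distinguish:

* ``hom_ref`` / ``het_dnp`` / ``hom_alt`` — true DNPs in cis; a
  heterozygote draws each read's haplotype (reference or alternative
  dinucleotide) with probability 1/2;
* ``adjacent_snp_trans`` — two independent adjacent SNPs with one
  derived base per haplotype; every read shows a mixed dinucleotide,
  never the reference or alternative allele;
* ``triallelic`` — a third dinucleotide segregates alongside ref/alt;
* ``indel_contaminated`` — homozygous-reference reads with planted
  1-bp insertions/deletions inside the 4-base window (correct CIGARs);
* ``low_coverage`` — a heterozygous DNP at reduced depth.

Fixtures are real coordinate-sorted BAMs so the pileup engine is
exercised end to end, never mocked.  Everything is deterministic given
the seed.  Base qualities are constant per scenario — the phred
equivalent of the base error rate (phred 30 by default) — which keeps
likelihood examples closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pysam

from .pileup_engine import DNPSite

SCENARIO_KINDS = (
    "hom_ref",
    "het_dnp",
    "hom_alt",
    "adjacent_snp_trans",
    "triallelic",
    "indel_contaminated",
    "low_coverage",
)

_BASES = "ACGT"

#: triallelic mixture: ref / alt / third-allele haplotype frequencies.
#: The third allele is a clear minority yet frequent enough that the
#: expected other-ratio (~0.43) sits well above the 0.1 call threshold.
_TRIALLELIC_WEIGHTS = (0.35, 0.35, 0.30)

#: minimum spacing between consecutive panel sites; reads are 100 bp by
#: default, so this guarantees no read of one site reaches another
#: site's window.
PANEL_SPACING = 250


@dataclass(frozen=True)
class Scenario:
    """Simulation settings for one site.

    coverage is the number of reads spanning the whole 4-base window
    (every window position sees all of them); base_error_rate is the
    per-base miscall probability; indel_rate the per-read probability of
    a planted 1-bp indel inside the window (used by the
    ``indel_contaminated`` kind).
    """

    kind: str
    coverage: int = 20
    read_length: int = 100
    base_error_rate: float = 0.001
    indel_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for name in ("base_error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")

    @property
    def base_quality(self) -> int:
        """Constant phred quality consistent with the base error rate."""
        if self.base_error_rate <= 0.0:
            return 30
        return min(41, round(-10.0 * math.log10(self.base_error_rate)))

    @property
    def expected_gt(self) -> str:
        """The genotype the caller should report (truth)."""
        return {
            "hom_ref": "0/0",
            "het_dnp": "0/1",
            "hom_alt": "1/1",
            "adjacent_snp_trans": "NA",
            "triallelic": "NA",
            "indel_contaminated": "0/0",
            "low_coverage": "0/1",
        }[self.kind]


@dataclass
class SiteTruth:
    """Ground truth attached to one simulated site."""

    site: DNPSite
    scenario: Scenario
    expected_gt: str
    planted_indel_reads: list[str]


def make_reference(
    n_contigs: int, contig_length: int, seed: int, out_dir: str
) -> str:
    """Write a random (seeded) reference FASTA plus its .fai index."""
    if contig_length < 10:
        raise ValueError("contig_length must be >= 10")
    rng = np.random.default_rng(seed)
    path = f"{out_dir}/reference.fa"
    with open(path, "w") as fh:
        for k in range(n_contigs):
            seq = "".join(rng.choice(list(_BASES), size=contig_length))
            fh.write(f">contig{k + 1}\n")
            for i in range(0, contig_length, 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)
    return path


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(0, 3)]


def make_panel(
    reference: str,
    n_sites: int,
    seed: int,
    out_path: str,
    spacing: int = PANEL_SPACING,
) -> tuple[str, list[DNPSite]]:
    """Create a headerless tab-delimited DNP panel over *reference*.

    Sites are adjacent position pairs with the reference dinucleotide
    read from the FASTA and an alternative differing at both positions;
    windows never overlap (consecutive sites are >= *spacing* apart).
    """
    rng = np.random.default_rng(seed)
    sites: list[DNPSite] = []
    with pysam.FastaFile(reference) as fasta:
        contigs = list(fasta.references)
        per_contig: dict[str, int] = {}
        capacity = 0
        for c in contigs:
            per_contig[c] = max(0, (fasta.get_reference_length(c) - 2 * spacing) // spacing)
            capacity += per_contig[c]
        if n_sites > capacity:
            raise ValueError(
                f"cannot place {n_sites} non-overlapping sites on this "
                f"reference (capacity {capacity} at spacing {spacing})"
            )
        remaining = n_sites
        for c in contigs:
            take = min(remaining, per_contig[c])
            for k in range(take):
                pos1 = spacing + k * spacing + int(rng.integers(0, spacing // 4))
                ref_dinuc = fasta.fetch(c, pos1 - 1, pos1 + 1).upper()
                if "N" in ref_dinuc:
                    ref_dinuc = "AC"
                alt_dinuc = _other_base(ref_dinuc[0], rng) + _other_base(
                    ref_dinuc[1], rng
                )
                sites.append(DNPSite(c, pos1, pos1 + 1, ref_dinuc, alt_dinuc))
            remaining -= take
            if remaining == 0:
                break
    with open(out_path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos1}\t{s.pos2}\t{s.ref_dinuc}\t{s.alt_dinuc}\n")
    return out_path, sites


def _third_dinuc(site: DNPSite, rng: np.random.Generator) -> str:
    while True:
        d = _other_base(site.ref_dinuc[0], rng) + _other_base(site.ref_dinuc[1], rng)
        if d != site.alt_dinuc:
            return d


def _reads_for_site(
    fasta: pysam.FastaFile,
    header: pysam.AlignmentHeader,
    tid: int,
    site: DNPSite,
    scenario: Scenario,
    rng: np.random.Generator,
) -> tuple[list[pysam.AlignedSegment], list[str]]:
    """Build aligned segments for one site; returns (reads, planted_indel_read_names)."""
    L = scenario.read_length
    contig_len = fasta.get_reference_length(site.chrom)
    # 0-based start range such that the read spans the whole clamped window
    win_lo0 = max(0, site.pos1 - 2)  # upstream flank, 0-based
    win_hi0 = min(contig_len - 1, site.pos2)  # downstream flank, 0-based
    lo = max(0, win_hi0 - L + 1)
    hi = min(win_lo0, contig_len - L)
    if hi < lo:
        raise ValueError(f"read_length {L} too short to span the window of {site}")

    if scenario.kind == "adjacent_snp_trans":
        haplotypes = [
            site.ref_dinuc[0] + site.alt_dinuc[1],
            site.alt_dinuc[0] + site.ref_dinuc[1],
        ]
        weights = [0.5, 0.5]
    elif scenario.kind == "hom_ref" or scenario.kind == "indel_contaminated":
        haplotypes, weights = [site.ref_dinuc], [1.0]
    elif scenario.kind == "hom_alt":
        haplotypes, weights = [site.alt_dinuc], [1.0]
    elif scenario.kind in ("het_dnp", "low_coverage"):
        haplotypes = [site.ref_dinuc, site.alt_dinuc]
        weights = [0.5, 0.5]
    elif scenario.kind == "triallelic":
        haplotypes = [site.ref_dinuc, site.alt_dinuc, _third_dinuc(site, rng)]
        weights = list(_TRIALLELIC_WEIGHTS)
    else:  # pragma: no cover - guarded by Scenario validation
        raise AssertionError(scenario.kind)

    qual = scenario.base_quality
    reads: list[pysam.AlignedSegment] = []
    planted: list[str] = []
    for i in range(scenario.coverage):
        start0 = int(rng.integers(lo, hi + 1))
        seq = list(fasta.fetch(site.chrom, start0, start0 + L).upper())
        hap = haplotypes[rng.choice(len(haplotypes), p=weights)]
        seq[site.pos1 - 1 - start0] = hap[0]
        seq[site.pos2 - 1 - start0] = hap[1]
        # sequencing errors: per-base miscalls at the scenario rate
        if scenario.base_error_rate > 0:
            err_mask = rng.random(L) < scenario.base_error_rate
            for j in np.flatnonzero(err_mask):
                seq[j] = _other_base(seq[j], rng)
        name = f"{site.chrom}_{site.pos1}_r{i:04d}"
        a = pysam.AlignedSegment(header=header)
        a.query_name = name
        a.reference_id = tid
        a.mapping_quality = 60
        a.flag = 16 if i % 2 else 0  # alternate strands

        cigar = [(0, L)]
        if scenario.kind == "indel_contaminated" and rng.random() < scenario.indel_rate:
            planted.append(name)
            k_del = site.pos1 - 2 - start0  # matched bases before the flank
            if rng.random() < 0.5 or k_del < 1:
                # 1-bp insertion immediately after pos1
                k = site.pos1 - start0  # bases consumed up to and incl. pos1
                seq = seq[:k] + [_BASES[rng.integers(0, 4)]] + seq[k:]
                cigar = [(0, k), (1, 1), (0, L - k)]
            else:
                # deletion of the upstream flank base (pos1-1)
                del seq[k_del]
                cigar = [(0, k_del), (2, 1), (0, L - k_del - 1)]
        a.reference_start = start0
        a.cigartuples = cigar
        a.query_sequence = "".join(seq)
        a.query_qualities = [qual] * len(seq)
        reads.append(a)
    return reads, planted


def simulate_sample(
    reference: str,
    site_scenarios: list[tuple[DNPSite, Scenario]],
    out_bam: str,
    seed: int,
) -> tuple[str, list[SiteTruth]]:
    """Simulate one sample covering many sites in a single sorted, indexed BAM."""
    rng = np.random.default_rng(seed)
    truths: list[SiteTruth] = []
    with pysam.FastaFile(reference) as fasta:
        header = pysam.AlignmentHeader.from_references(
            list(fasta.references),
            [fasta.get_reference_length(c) for c in fasta.references],
        )
        tid_of = {c: k for k, c in enumerate(fasta.references)}
        all_reads: list[pysam.AlignedSegment] = []
        for site, scenario in site_scenarios:
            reads, planted = _reads_for_site(
                fasta, header, tid_of[site.chrom], site, scenario, rng
            )
            all_reads.extend(reads)
            truths.append(
                SiteTruth(site, scenario, scenario.expected_gt, planted)
            )
        all_reads.sort(
            key=lambda a: (a.reference_id, a.reference_start, a.query_name)
        )
        with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
            for a in all_reads:
                bam.write(a)
    pysam.index(out_bam)
    return out_bam, truths


def simulate_reads(
    reference: str, site: DNPSite, scenario: Scenario, out_bam: str
) -> tuple[str, SiteTruth]:
    """Simulate reads for a single site into a sorted, indexed BAM."""
    path, truths = simulate_sample(
        reference, [(site, scenario)], out_bam, seed=scenario.seed
    )
    return path, truths[0]


def panel_scenarios(
    sites: list[DNPSite], kind: str, seed: int, **overrides
) -> list[tuple[DNPSite, Scenario]]:
    """Attach one scenario of *kind* to each site, varying only the seed."""
    base = Scenario(kind=kind, seed=seed, **overrides)
    return [(s, replace(base, seed=seed + k)) for k, s in enumerate(sites)]
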