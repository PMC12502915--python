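"""Shared fixtures: a small synthetic world (reference + panel) and
helpers to simulate scenario BAMs and to run the external mpileup tool
as an independent oracle."""

from __future__ import annotations

import subprocess

import pytest

from dnpcaller.pileup_engine import DNPSite, PileupColumn, build_window, parse_mpileup
from dnpcaller.synthetic_fixtures import (
    Scenario,
    make_panel,
    make_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """A seeded reference FASTA and a 6-site DNP panel."""
    root = tmp_path_factory.mktemp("world")
    reference = make_reference(n_contigs=1, contig_length=5000, seed=42, out_dir=str(root))
    panel_path, sites = make_panel(reference, n_sites=6, seed=7, out_path=str(root / "panel.tsv"))
    return {"root": root, "reference": reference, "panel": panel_path, "sites": sites}


@pytest.fixture
def make_bam(world, tmp_path):
    """Factory: simulate one scenario BAM for a panel site; returns (bam, truth, site)."""

    counter = {"n": 0}

    def _make(kind: str, site_index: int = 0, **kw) -> tuple[str, object, DNPSite]:
        counter["n"] += 1
        site = world["sites"][site_index]
        scenario = Scenario(kind=kind, **kw)
        out = str(tmp_path / f"{kind}_{counter['n']}.bam")
        bam, truth = simulate_reads(world["reference"], site, scenario, out)
        return bam, truth, site

    return _make


def mpileup_oracle(
    bam: str, reference: str, site: DNPSite, contig_length: int, min_baseq: int = 13
) -> list[PileupColumn]:
    """Window pileup computed by the external samtools mpileup tool.

    Run with BAQ and mate-overlap detection disabled to match the
    native backend's contract (no BAQ; overlapping mates are resolved
    downstream by read identifier, not in the pileup).  Positions the
    tool omits are returned as zero-coverage columns.
    """
    window = build_window(site, contig_length)
    region = f"{site.chrom}:{window[0]}-{window[-1]}"
    out = subprocess.run(
        [
            "samtools",
            "mpileup",
            "-f",
            reference,
            "-r",
            region,
            "-aa",
            "-B",
            "-x",
            "--output-QNAME",
            "--min-BQ",
            str(min_baseq),
            bam,
        ],
        capture_output=True,
        text=True,
        check=True,
    )
    by_pos = {c.pos: c for c in parse_mpileup(out.stdout)}
    return [
        by_pos.get(p, PileupColumn(site.chrom, p, "N")) for p in window
    ]


def entry_key(entry, ignore_deletion_strand: bool = True):
    """Canonical tuple for comparing pileup entries across backends.

    The classic mpileup '*' token carries no strand, so deletion-entry
    strands are not compared.
    """
    strand = (
        "?"
        if (entry.is_deletion and ignore_deletion_strand)
        else entry.strand
    )
    return (
        entry.read_id,
        entry.base,
        entry.qual,
        entry.indel_after,
        entry.is_deletion,
        strand,
    )


def assert_columns_equal(native: list[PileupColumn], oracle: list[PileupColumn]):
    assert [c.pos for c in native] == [c.pos for c in oracle]
    for nc, oc in zip(native, oracle):
        assert sorted(entry_key(e) for e in nc.entries) == sorted(
            entry_key(e) for e in oc.entries
        ), f"pileup mismatch at {nc.chrom}:{nc.pos}"
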