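"""Input readers, output tables, cohort summaries and diagnostic plots.

Inputs follow the published conventions for this kind of pipeline: a
*bamlist* (one BAM path per line, sample names taken from file
basenames) and a headerless tab-delimited DNP panel with columns
chromosome, position #1, position #2, reference allele, alternative
allele.

Outputs are, per sample, a ``full_output_<sample>.txt`` table with read
tallies, combined dinucleotide counts, genotype likelihoods and the
assigned genotype; cohort-wide, an ``<out>_AllGenotypes.txt`` genotype
matrix, summary counters, and diagnostic PDF plots (per-sample read
count histograms and genotype tallies, a cohort UpSet-style coverage
plot, and a per-site unassigned-genotype bar chart).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .dnp_caller import DNPCallRecord
from .pileup_engine import DNPSite

logger = logging.getLogger(__name__)

GENOTYPES = ("0/0", "0/1", "1/1", "NA")

FULL_OUTPUT_COLUMNS = [
    "chrom",
    "pos1",
    "pos2",
    "ref",
    "alt",
    "N_ref",
    "N_alt",
    "N_other",
    "combined_bases",
    "combined_counts",
    "GT",
    "GL0",
    "GL1",
    "GL2",
    "reads_discarded_for_indels",
    "ratio_reads_discarded_for_indels",
]


def sample_name_from_path(path: str) -> str:
    """Sample name = file basename minus its extension."""
    base = os.path.basename(path)
    return base[: -len(".bam")] if base.endswith(".bam") else os.path.splitext(base)[0]


def read_bamlist(path: str) -> list[str]:
    """Read a bamlist: one alignment-file path per non-empty line.

    Validates that every BAM exists and that derived sample names are
    unique; an empty list is an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"bamlist not found: {path}")
    paths: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            p = line.strip()
            if not p:
                continue
            if not os.path.exists(p):
                raise FileNotFoundError(
                    f"bamlist line {lineno}: alignment file not found: {p}"
                )
            paths.append(p)
    if not paths:
        raise ValueError(f"bamlist {path} contains no paths")
    names = [sample_name_from_path(p) for p in paths]
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValueError(
                f"duplicate sample name {name!r} in bamlist {path}; "
                "rename the files to disambiguate"
            )
        seen.add(name)
    return paths


def read_dnp_list(path: str) -> list[DNPSite]:
    """Parse the headerless DNP panel into validated sites.

    Alleles are uppercased; when the same (chrom, pos1, pos2) appears on
    more than one line only the first occurrence is kept (a logged
    warning notes each drop).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"DNP panel not found: {path}")
    sites: list[DNPSite] = []
    seen: set[tuple[str, int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path} line {lineno}: expected 5 tab-delimited columns, "
                    f"got {len(fields)}"
                )
            chrom, p1, p2, ref, alt = fields
            try:
                site = DNPSite(
                    chrom, int(p1), int(p2), ref.strip().upper(), alt.strip().upper()
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            key = (site.chrom, site.pos1, site.pos2)
            if key in seen:
                logger.warning(
                    "%s line %d: duplicate site %s:%d-%d, keeping first occurrence",
                    path,
                    lineno,
                    *key,
                )
                continue
            seen.add(key)
            sites.append(site)
    return sites


@dataclass
class CohortMatrix:
    """Sites x samples table of assigned genotypes."""

    sites: list[DNPSite]
    samples: list[str]
    gt: dict[tuple[tuple[str, int], str], str] = field(default_factory=dict)

    @staticmethod
    def _key(site: DNPSite) -> tuple[str, int]:
        return (site.chrom, site.pos1)

    def set(self, site: DNPSite, sample: str, gt: str) -> None:
        if gt not in GENOTYPES:
            raise ValueError(f"invalid genotype string {gt!r}")
        self.gt[(self._key(site), sample)] = gt

    def get(self, site: DNPSite, sample: str) -> str:
        return self.gt[(self._key(site), sample)]

    @classmethod
    def from_records(
        cls, records_by_sample: dict[str, list[DNPCallRecord]]
    ) -> "CohortMatrix":
        samples = list(records_by_sample)
        sites = [r.site for r in next(iter(records_by_sample.values()))]
        matrix = cls(sites=sites, samples=samples)
        for sample, records in records_by_sample.items():
            for rec in records:
                matrix.set(rec.site, sample, rec.call.gt)
        return matrix


@dataclass
class CohortSummary:
    """Cohort-level site counters.

    ``n_sites_called_in_all`` — sites with a non-NA genotype in every
    sample; ``n_polymorphic`` — among those, sites with >= 2 distinct
    genotypes across samples; ``n_na_in_any`` — sites with at least one
    NA; ``n_with_other_allele`` — sites where at least one sample saw a
    read supporting neither allele.
    """

    n_sites_called_in_all: int
    n_polymorphic: int
    n_na_in_any: int
    n_with_other_allele: int


def _fmt(x: float) -> str:
    """6 significant digits, matching the table convention."""
    return format(x, ".6g")


def write_full_output(
    sample_name: str, records: list[DNPCallRecord], out_dir: str
) -> str:
    """Write the per-sample table ``full_output_<sample>.txt``.

    ``combined_bases`` lists the observed dinucleotides sorted by
    descending count then lexicographically; ``combined_counts`` is the
    parallel count list.  Floats use 6 significant digits; empty fields
    print as "NA".
    """
    rows = []
    for rec in records:
        combined = sorted(rec.counts.combined.items(), key=lambda kv: (-kv[1], kv[0]))
        rows.append(
            {
                "chrom": rec.site.chrom,
                "pos1": rec.site.pos1,
                "pos2": rec.site.pos2,
                "ref": rec.site.ref_dinuc,
                "alt": rec.site.alt_dinuc,
                "N_ref": rec.counts.n_ref,
                "N_alt": rec.counts.n_alt,
                "N_other": rec.counts.n_other,
                "combined_bases": ",".join(d for d, _ in combined) or "NA",
                "combined_counts": ",".join(str(c) for _, c in combined) or "NA",
                "GT": rec.call.gt,
                "GL0": _fmt(rec.call.gl0),
                "GL1": _fmt(rec.call.gl1),
                "GL2": _fmt(rec.call.gl2),
                "reads_discarded_for_indels": rec.counts.reads_discarded_for_indels,
                "ratio_reads_discarded_for_indels": _fmt(rec.counts.ratio_discarded),
            }
        )
    df = pd.DataFrame(rows, columns=FULL_OUTPUT_COLUMNS)
    path = os.path.join(out_dir, f"full_output_{sample_name}.txt")
    df.to_csv(path, sep="\t", index=False)
    return path


def write_all_genotypes(out_name: str, matrix: CohortMatrix, out_dir: str) -> str:
    """Write the cohort genotype matrix ``<out_name>_AllGenotypes.txt``."""
    rows = []
    for site in matrix.sites:
        row = {
            "chrom": site.chrom,
            "pos1": site.pos1,
            "pos2": site.pos2,
            "ref": site.ref_dinuc,
            "alt": site.alt_dinuc,
        }
        for sample in matrix.samples:
            row[f"GT_{sample}"] = matrix.get(site, sample)
        rows.append(row)
    columns = ["chrom", "pos1", "pos2", "ref", "alt"] + [
        f"GT_{s}" for s in matrix.samples
    ]
    df = pd.DataFrame(rows, columns=columns)
    path = os.path.join(out_dir, f"{out_name}_AllGenotypes.txt")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_all_genotypes(path: str) -> CohortMatrix:
    """Parse an ``*_AllGenotypes.txt`` file back into a CohortMatrix."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    samples = [c[len("GT_") :] for c in df.columns if c.startswith("GT_")]
    sites = [
        DNPSite(row["chrom"], int(row["pos1"]), int(row["pos2"]), row["ref"], row["alt"])
        for _, row in df.iterrows()
    ]
    matrix = CohortMatrix(sites=sites, samples=samples)
    for site, (_, row) in zip(sites, df.iterrows()):
        for sample in samples:
            matrix.set(site, sample, row[f"GT_{sample}"])
    return matrix


def summarize_cohort(
    matrix: CohortMatrix, records_by_sample: dict[str, list[DNPCallRecord]]
) -> CohortSummary:
    """Compute the cohort-level site counters from the genotype matrix."""
    n_all = n_poly = n_na = 0
    for site in matrix.sites:
        gts = [matrix.get(site, s) for s in matrix.samples]
        if "NA" in gts:
            n_na += 1
        else:
            n_all += 1
            if len(set(gts)) >= 2:
                n_poly += 1
    other_sites: set[tuple[str, int]] = set()
    for records in records_by_sample.values():
        for rec in records:
            if rec.counts.n_other > 0:
                other_sites.add((rec.site.chrom, rec.site.pos1))
    return CohortSummary(
        n_sites_called_in_all=n_all,
        n_polymorphic=n_poly,
        n_na_in_any=n_na,
        n_with_other_allele=len(other_sites),
    )


def _hist(ax, values, title, xlabel):
    vmax = max(values) if values else 1
    ax.hist(values, bins=range(0, int(vmax) + 2), color="#4878a8", edgecolor="black")
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("number of sites")


def _save(fig, path: str, paths: list[str]) -> None:
    fig.savefig(path)
    plt.close(fig)
    paths.append(path)


def _upset_coverage_plot(matrix: CohortMatrix, path: str) -> None:
    """UpSet-style view of which samples have a called genotype at which sites.

    Bars show the size of every non-empty sample-set intersection
    (exclusive membership), with a dot matrix underneath marking the
    sets in each intersection.  With a single sample this degrades to a
    plain bar chart of called vs uncalled sites.
    """
    samples = matrix.samples
    if len(samples) == 1:
        s = samples[0]
        called = sum(1 for site in matrix.sites if matrix.get(site, s) != "NA")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(["called", "NA"], [called, len(matrix.sites) - called], color="#4878a8")
        ax.set_ylabel("number of sites")
        ax.set_title(f"sites covered: {s}")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        return
    membership: dict[frozenset, int] = {}
    for site in matrix.sites:
        covered = frozenset(s for s in samples if matrix.get(site, s) != "NA")
        if covered:
            membership[covered] = membership.get(covered, 0) + 1
    combos = sorted(membership.items(), key=lambda kv: -kv[1])
    fig, (ax_bar, ax_dot) = plt.subplots(
        2,
        1,
        figsize=(max(4, 0.6 * len(combos) + 2), 2.4 + 0.3 * len(samples) + 2),
        sharex=True,
        gridspec_kw={"height_ratios": [2, 1]},
    )
    xs = range(len(combos))
    ax_bar.bar(xs, [c for _, c in combos], color="#303030")
    ax_bar.set_ylabel("sites")
    ax_bar.set_title("sample coverage intersections (non-NA genotypes)")
    for x, (combo, _) in enumerate(combos):
        for y, s in enumerate(samples):
            in_set = s in combo
            ax_dot.plot(
                x,
                y,
                "o",
                color="#303030" if in_set else "#d0d0d0",
                markersize=6,
            )
    ax_dot.set_yticks(range(len(samples)))
    ax_dot.set_yticklabels(samples)
    ax_dot.set_xticks(list(xs))
    ax_dot.set_xticklabels([""] * len(combos))
    ax_dot.set_ylim(-0.5, len(samples) - 0.5)
    ax_dot.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def make_plots(
    matrix: CohortMatrix,
    records_by_sample: dict[str, list[DNPCallRecord]],
    out_dir: str,
) -> list[str]:
    """Render the diagnostic PDFs.

    Per sample: histograms of N_ref / N_alt / N_other across sites and a
    bar chart of assigned genotypes.  Cohort-wide: the UpSet-style
    coverage plot and a bar chart of per-site NA occurrences.  A
    plotting failure is a warning, never fatal — the tables are the
    primary output.
    """
    paths: list[str] = []
    for sample, records in records_by_sample.items():
        try:
            for label, attr in (("Ref", "n_ref"), ("Alt", "n_alt"), ("Other", "n_other")):
                fig, ax = plt.subplots(figsize=(4, 3))
                _hist(
                    ax,
                    [getattr(r.counts, attr) for r in records],
                    f"{sample}: N_{label.lower()} per site",
                    f"{label} read count",
                )
                fig.tight_layout()
                _save(fig, os.path.join(out_dir, f"{sample}_{label}_read_count.pdf"), paths)
            tallies = {g: 0 for g in GENOTYPES}
            for r in records:
                tallies[r.call.gt] += 1
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar(list(tallies), list(tallies.values()), color="#4878a8")
            ax.set_ylabel("number of sites")
            ax.set_title(f"assigned genotypes: {sample}")
            fig.tight_layout()
            _save(fig, os.path.join(out_dir, f"{sample}_N_genotypes.pdf"), paths)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("plotting failed for sample %s: %s", sample, exc)
    try:
        upset_path = os.path.join(out_dir, "DNPs_covered_UpSet_plot.pdf")
        _upset_coverage_plot(matrix, upset_path)
        paths.append(upset_path)

        na_per_site = [
            sum(1 for s in matrix.samples if matrix.get(site, s) == "NA")
            for site in matrix.sites
        ]
        fig, ax = plt.subplots(figsize=(5, 3))
        counts = pd.Series(na_per_site).value_counts().sort_index()
        ax.bar(counts.index, counts.values, color="#a85048")
        ax.set_xticks(list(counts.index))
        ax.set_xlabel("samples with unassigned genotype at a site")
        ax.set_ylabel("number of sites")
        ax.set_title("unassigned genotypes per DNP")
        fig.tight_layout()
        _save(fig, os.path.join(out_dir, "Unassigned_genotypes.pdf"), paths)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("cohort plotting failed: %s", exc)
    return paths
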