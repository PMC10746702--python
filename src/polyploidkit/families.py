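"""Gene-family copy numbers, the twofold-amplification filter, pathway
rollup, and the true-ortholog intersection rule.

A gene family that kept both homoeologous copies after allopolyploidy
shows roughly twice the copy number of either diploid relative; the
filter keeps families whose tetraploid count is at least ``fold`` times
EACH diploid count, with both diploid counts >= 1 (so a zero diploid
count never manufactures an infinite ratio). True orthologs are pairs
that are each other's best homology hit AND share a family assignment —
the intersection of sequence-search and family-database evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import FamilyCountRow

log = logging.getLogger("polyploidkit")

UNASSIGNED = "unassigned"


def count_by_family(
    gene_to_family_by_species: dict[str, dict[str, str]],
) -> tuple[list[FamilyCountRow], dict[str, int]]:
    """Per-family, per-species copy numbers from gene->family maps.

    Returns the count rows plus a per-species tally of genes without a
    family assignment (the "unassigned" bucket).
    """
    if not any(gene_to_family_by_species.values()):
        log.warning("empty gene->family mapping: empty count table")
    counts: dict[str, dict[str, int]] = {}
    unassigned = {sp: 0 for sp in gene_to_family_by_species}
    for sp, mapping in gene_to_family_by_species.items():
        for gene, fam in mapping.items():
            if not fam or fam == UNASSIGNED:
                unassigned[sp] += 1
                continue
            counts.setdefault(fam, {})[sp] = counts.setdefault(fam, {}).get(sp, 0) + 1
    rows = [
        FamilyCountRow(fam,
                       {sp: counts[fam].get(sp, 0)
                        for sp in gene_to_family_by_species})
        for fam in sorted(counts)
    ]
    return rows, unassigned


@dataclass
class AmplifiedFamilyReport:
    family_id: str
    counts: dict[str, int]
    ratios: dict[str, float]
    amplified: bool


def amplified_families(
    rows: list[FamilyCountRow],
    tetraploid: str,
    diploids: tuple[str, str],
    fold: float = 2.0,
    allow_zero_diploid: bool = False,
) -> list[AmplifiedFamilyReport]:
    """Apply the twofold-increase rule to every family count row."""
    d1, d2 = diploids
    reports = []
    for row in rows:
        for sp in (tetraploid, d1, d2):
            if sp not in row.counts:
                raise ValueError(f"{row.family_id}: missing species {sp!r}")
        t = row.counts[tetraploid]
        c1, c2 = row.counts[d1], row.counts[d2]
        ratios = {
            d1: t / c1 if c1 else float("inf"),
            d2: t / c2 if c2 else float("inf"),
        }
        present = (c1 >= 1 and c2 >= 1) or allow_zero_diploid
        amplified = present and t >= fold * c1 and t >= fold * c2
        reports.append(AmplifiedFamilyReport(row.family_id, dict(row.counts),
                                             ratios, bool(amplified)))
    return reports


def pathway_rollup(
    amplified: set[str],
    family_to_pathway: dict[str, str],
) -> tuple[list[tuple[str, int]], list[str]]:
    """Count amplified families per pathway, sorted descending.

    A family mapped to several pathways (separated by commas in the map
    value) counts once in each. Families without a pathway are returned
    separately.
    """
    counts: dict[str, int] = {}
    unmapped = []
    for fam in sorted(amplified):
        entry = family_to_pathway.get(fam)
        if not entry:
            unmapped.append(fam)
            continue
        for pathway in entry.split(","):
            pathway = pathway.strip()
            counts[pathway] = counts.get(pathway, 0) + 1
    table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return table, unmapped


def true_orthologs(
    best_hits: dict[str, str],
    family_of: dict[str, str],
) -> list[tuple[str, str]]:
    """Keep (gene, best hit) pairs whose members share a family."""
    pairs = []
    for g in sorted(best_hits):
        h = best_hits[g]
        fg, fh = family_of.get(g), family_of.get(h)
        if fg is not None and fg == fh:
            pairs.append((g, h))
    return pairs


def write_family_counts(rows: list[FamilyCountRow], path) -> None:
    species = sorted({sp for r in rows for sp in r.counts})
    with open(path, "w") as fh:
        fh.write("family_id\t" + "\t".join(species) + "\n")
        for r in rows:
            fh.write(r.family_id + "\t"
                     + "\t".join(str(r.counts.get(sp, 0)) for sp in species)
                     + "\n")


def read_family_counts(path) -> list[FamilyCountRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = header[1:]
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} columns")
            rows.append(FamilyCountRow(
                fields[0], {sp: int(v) for sp, v in zip(species, fields[1:])}
            ))
    return rows


def write_amplified(reports: list[AmplifiedFamilyReport], path) -> None:
    with open(path, "w") as fh:
        species = sorted(reports[0].counts) if reports else []
        fh.write("family_id\t" + "\t".join(species) + "\tamplified\n")
        for r in reports:
            fh.write(r.family_id + "\t"
                     + "\t".join(str(r.counts.get(sp, 0)) for sp in species)
                     + f"\t{int(r.amplified)}\n")
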