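"""Gene-neighborhood analysis and phyletic-distribution census.

Neighborhoods are gene-index windows (default +/-5 genes on the same contig,
both strands, both directions). Intergenic distances follow the 1-based
inclusive convention ``distance = downstream.start - upstream.end - 1``, so
book-ended genes are 0 bp apart and overlapping genes have negative
distances. Operon co-membership requires a same-strand run with every
consecutive intergenic gap at most ``max_gap_bp`` (default 100 bp, a common
prokaryotic heuristic).

The phyletic census applies the display and horizontal-gene-transfer (HGT)
rules used for family-distribution figures: a phylum is displayed when it has
at least 10 genomes available and at least 5 of them contain a functional
family gene; a phylum with more than zero but fewer than five carrier genomes
is flagged as a likely HGT recipient.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthdata import GeneRecord

DISPLAY_MIN_GENOMES = 10
DISPLAY_MIN_CARRIERS = 5


@dataclass
class NeighborhoodReport:
    focal: GeneRecord
    #: (gene, index offset, intergenic distance to the focal gene in bp,
    #: same-operon flag)
    neighbors: list[tuple[GeneRecord, int, int, bool]]
    category_present: dict[str, bool]


@dataclass
class PhylumSummary:
    phylum: str
    genomes_total: int
    genomes_with_functional_pyp: int
    percentage: float
    displayed: bool
    hgt_flagged: bool


# --------------------------------------------------------------------------
# Neighborhoods
# --------------------------------------------------------------------------


def _same_gene(a: GeneRecord, b: GeneRecord) -> bool:
    return (
        a.genome_id == b.genome_id and a.contig == b.contig and a.index == b.index
    )


def neighbors_within(
    gene: GeneRecord,
    table,
    window: int = 5,
) -> list[GeneRecord]:
    """Genes on the same contig within ``window`` index positions (excluding
    the focal gene itself), clipped at contig ends."""
    table = list(table)
    if not any(_same_gene(gene, g) for g in table):
        raise ValueError(
            f"focal gene {gene.genome_id}:{gene.contig}:{gene.index} not in table"
        )
    out = [
        g
        for g in table
        if g.genome_id == gene.genome_id
        and g.contig == gene.contig
        and 1 <= abs(g.index - gene.index) <= window
    ]
    out.sort(key=lambda g: g.index)
    return out


def intergenic_distance(g1: GeneRecord, g2: GeneRecord) -> int:
    """Base pairs between two genes on one contig (negative = overlap).

    The genes are ordered by start coordinate internally; with 1-based
    inclusive coordinates the distance is ``downstream.start - upstream.end
    - 1``.
    """
    if g1.genome_id != g2.genome_id or g1.contig != g2.contig:
        raise ValueError("genes on different contigs have no intergenic distance")
    up, down = (g1, g2) if g1.start <= g2.start else (g2, g1)
    return down.start - up.end - 1


def same_operon(
    g1: GeneRecord,
    g2: GeneRecord,
    max_gap_bp: int = 100,
    table=None,
) -> bool:
    """True iff both genes (and any genes between them) lie on the same
    strand and every consecutive intergenic gap on the path is <= the
    threshold. With no ``table``, the two genes are treated as adjacent."""
    if g1.genome_id != g2.genome_id or g1.contig != g2.contig:
        raise ValueError("operon test requires genes on the same contig")
    if g1.strand != g2.strand:
        return False
    lo, hi = sorted((g1.index, g2.index))
    if table is not None:
        path = sorted(
            (
                g
                for g in table
                if g.genome_id == g1.genome_id
                and g.contig == g1.contig
                and lo <= g.index <= hi
            ),
            key=lambda g: g.index,
        )
    else:
        path = sorted((g1, g2), key=lambda g: g.index)
    for a, b in zip(path, path[1:]):
        if a.strand != b.strand:
            return False
        if intergenic_distance(a, b) > max_gap_bp:
            return False
    return True


def neighborhood_report(
    gene: GeneRecord,
    table,
    window: int = 5,
    max_gap_bp: int = 100,
    categories=None,
) -> NeighborhoodReport:
    neigh = neighbors_within(gene, table, window)
    entries = []
    for g in neigh:
        entries.append(
            (
                g,
                g.index - gene.index,
                intergenic_distance(gene, g),
                same_operon(gene, g, max_gap_bp, table=table),
            )
        )
    cats = categories or sorted({g.category for g in neigh})
    present = {c: any(g.category == c for g in neigh) for c in cats}
    return NeighborhoodReport(focal=gene, neighbors=entries, category_present=present)


def category_fractions(
    pyp_genes,
    tables: dict,
    categories,
    window: int = 5,
) -> dict[str, float]:
    """Fraction of (functional) family genes with at least one neighbor of
    each category within the window. ``tables`` maps genome id to its gene
    list."""
    pyp_genes = list(pyp_genes)
    if not pyp_genes:
        raise ValueError("no family genes supplied")
    counts = {c: 0 for c in categories}
    for gene in pyp_genes:
        neigh = neighbors_within(gene, tables[gene.genome_id], window)
        seen = {g.category for g in neigh}
        for c in categories:
            if c in seen:
                counts[c] += 1
    return {c: counts[c] / len(pyp_genes) for c in categories}


# --------------------------------------------------------------------------
# Phyletic census
# --------------------------------------------------------------------------


def phyletic_summary(
    genomes: pd.DataFrame,
    functional_genome_ids,
) -> list[PhylumSummary]:
    """Per-phylum census of genomes and functional-family carriers.

    ``genomes`` needs columns ``genome_id`` and ``phylum``. Functional ids
    not present in the table raise an error naming them.
    """
    known = set(genomes["genome_id"])
    functional = set(functional_genome_ids)
    orphans = sorted(functional - known)
    if orphans:
        raise ValueError(f"functional genome ids missing from taxonomy: {orphans}")
    out = []
    for phylum, sub in genomes.groupby("phylum", sort=True):
        total = len(sub)
        with_pyp = len(set(sub["genome_id"]) & functional)
        pct = 100.0 * with_pyp / total if total else 0.0
        out.append(
            PhylumSummary(
                phylum=phylum,
                genomes_total=total,
                genomes_with_functional_pyp=with_pyp,
                percentage=pct,
                displayed=(
                    total >= DISPLAY_MIN_GENOMES and with_pyp >= DISPLAY_MIN_CARRIERS
                ),
                hgt_flagged=0 < with_pyp < DISPLAY_MIN_CARRIERS,
            )
        )
    out.sort(key=lambda s: (-s.genomes_with_functional_pyp, s.phylum))
    return out


def write_phyletic_summary(summaries, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "phylum\tgenomes_total\tgenomes_with_functional_pyp\t"
            "percentage\tdisplayed\thgt_flagged\n"
        )
        for s in summaries:
            fh.write(
                f"{s.phylum}\t{s.genomes_total}\t{s.genomes_with_functional_pyp}\t"
                f"{s.percentage:.2f}\t{s.displayed}\t{s.hgt_flagged}\n"
            )


def write_neighborhoods(reports, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tcontig\tfocal_index\tneighbor_index\toffset\t"
            "neighbor_category\tdistance_bp\tsame_operon\n"
        )
        for rep in reports:
            f = rep.focal
            for g, off, dist, operon in rep.neighbors:
                fh.write(
                    f"{f.genome_id}\t{f.contig}\t{f.index}\t{g.index}\t{off}\t"
                    f"{g.category}\t{dist}\t{operon}\n"
                )
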