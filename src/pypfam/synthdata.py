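"""Synthetic protein families, taxonomy, and genome gene tables.

This generator emulates the statistical structure of the inputs the PYP-family
analysis consumes, so every downstream stage (similarity network, residue
classification, profile HMM, gene-neighborhood census, phyletic census,
phylogeny) can be exercised and validated against planted ground truth without
any database downloads.

What is emulated
----------------
* One planted "PYP" family evolved from a single root ancestor, split into
  three clades (A, B, C) that diverge from the root before diversifying
  within each clade. Reference-numbered motif positions are constrained:
  all clades keep Tyr42/Glu46/Ser50/Cys69 (the chromophore-binding triad plus
  the position-50 site), clades A and B additionally keep Phe92/Phe96/Trp119,
  and clade C keeps Met100 instead - mirroring the clade-specific conservation
  signatures of the real family.
* Labeled substitutions (Y42F, E46Q, C69S, ...) planted at configured per-
  sequence probabilities. A 42-substitution and a 46-substitution are never
  planted together in the same sequence, emulating the observed mutual
  exclusion of those two sites in functional PYPs.
* Decoy families: unrelated families with the same length scale and internal
  divergence but no motif constraints (the stand-ins for non-PYP PAS domains).
* Genomes grouped into phyla, with a configured number of genomes per phylum
  and a per-phylum probability that a genome carries a PYP gene. Carrier
  genomes receive a gene table in which category-labeled neighbors (TAL,
  pCL, HMOX, DLD, MCP, GGDEF, EAL, HK, RR) are placed within the +/-5-gene
  window of the PYP gene at configured frequencies. Coordinates are 1-based
  inclusive; intergenic gaps are drawn uniformly from [-30, 300] bp so that
  gene overlaps (negative distances) occur.

Determinism: every random draw flows from named ``numpy`` generators derived
from ``SynthConfig.seed``, so a fixed config reproduces byte-identical output
files. Hidden ground-truth labels (``planted_family``, ``planted_clade``) are
carried on the records for tests and reports only; no analysis stage reads
them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AA, BACKGROUND

# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A protein sequence with genome/taxonomy metadata.

    ``planted_family``/``planted_clade`` are hidden ground truth for tests
    and reports; analysis stages never consume them.
    """

    id: str
    residues: str
    genome_id: str = ""
    phylum: str = ""
    order: str = ""
    planted_family: str | None = None
    planted_clade: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AA)
        if bad:
            raise ValueError(f"sequence {self.id!r} has illegal residues {bad}")


@dataclass
class GeneRecord:
    """A gene on a contig; 1-based inclusive coordinates, ``index`` is the
    1-based ordinal position of the gene on its contig in coordinate order."""

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    index: int
    category: str
    sequence_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene with start > end: {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")


#: Neighbor categories the generator knows how to place.
NEIGHBOR_CATEGORIES = [
    "TAL", "pCL", "HMOX", "DLD", "MCP", "GGDEF", "EAL", "HK", "RR",
]

_DEFAULT_MOTIFS = {
    "A": {42: "Y", 46: "E", 50: "S", 69: "C", 92: "F", 96: "F", 119: "W"},
    "B": {42: "Y", 46: "E", 50: "S", 69: "C", 92: "F", 96: "F", 119: "W"},
    "C": {42: "Y", 46: "E", 50: "S", 69: "C", 100: "M"},
}

#: Motif of the reference sequence itself: union of the clade motifs.
REFERENCE_MOTIF = {
    42: "Y", 46: "E", 50: "S", 69: "C", 92: "F", 96: "F", 100: "M", 119: "W",
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data.

    Probabilities must lie in [0, 1] and counts must be non-negative; the
    defaults are the conditions every test and report in this package runs
    under (rationale in the methods note).
    """

    seed: int = 0
    reference_length: int = 125
    clade_sizes: dict = field(default_factory=lambda: {"A": 25, "B": 20, "C": 15})
    n_decoy_families: int = 4
    decoy_family_size: int = 50
    #: expected substitutions per site, root-to-leaf, within a family/clade
    family_tree_depth: float = 0.15
    #: substitutions per site on the branch from the PYP root to each clade
    clade_divergence: float = 0.35
    #: multiplier on branch lengths (0 disables evolution entirely)
    site_mutation_rate: float = 1.0
    #: extra substitutions/site applied to sequences that lose Cys69,
    #: emulating the overall divergence of the real family's
    #: Cys69-substituted subgroup (whose members drifted as a group, not at
    #: the single chromophore-binding site alone)
    nonfunctional_extra_divergence: float = 0.30
    motif_spec: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MOTIFS.items()})
    substitution_rates: dict = field(
        default_factory=lambda: {"Y42F": 0.10, "E46Q": 0.05, "C69S": 0.16}
    )
    genomes_per_phylum: dict = field(
        default_factory=lambda: {
            "Proteobacteria": 120,
            "Myxococcota": 30,
            "Spirochaetota": 40,
            "Bacteroidota": 40,
            "Gemmatimonadota": 12,
            "Actinobacteria": 60,
            "Acidobacteria": 15,
            "Armatimonadota": 12,
            "Thermoplasmatota": 10,
            "Bdellovibrionota": 10,
            "Firmicutes": 50,
            "Cyanobacteria": 9,
        }
    )
    pyp_prevalence: dict = field(
        default_factory=lambda: {
            "Proteobacteria": 0.15,
            "Myxococcota": 0.60,
            "Spirochaetota": 0.25,
            "Bacteroidota": 0.25,
            "Gemmatimonadota": 0.25,
            "Actinobacteria": 0.05,
            "Acidobacteria": 0.20,
            "Armatimonadota": 0.25,
            "Thermoplasmatota": 0.30,
            "Bdellovibrionota": 0.30,
            "Firmicutes": 0.0,
            "Cyanobacteria": 0.0,
        }
    )
    clade_affinity: dict = field(
        default_factory=lambda: {
            "Proteobacteria": {"A": 0.6, "C": 0.4},
            "Myxococcota": {"A": 1.0},
            "Spirochaetota": {"B": 1.0},
            "Bacteroidota": {"B": 1.0},
        }
    )
    neighbor_freqs: dict = field(
        default_factory=lambda: {
            "TAL": 0.30,
            "pCL": 0.40,
            "HMOX": 0.20,
            "DLD": 0.20,
            "MCP": 0.25,
            "GGDEF": 0.30,
            "EAL": 0.15,
            "HK": 0.25,
            "RR": 0.25,
        }
    )
    genes_per_contig: int = 15
    neighbor_window: int = 5
    orders_per_phylum: int = 3
    operon_gap_bp: int = 100

    def __post_init__(self) -> None:
        for name, probs in (
            ("substitution_rates", self.substitution_rates),
            ("pyp_prevalence", self.pyp_prevalence),
            ("neighbor_freqs", self.neighbor_freqs),
        ):
            for key, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{key!r}] = {p} outside [0, 1]")
        for phylum, n in self.genomes_per_phylum.items():
            if n < 0:
                raise ValueError(f"genomes_per_phylum[{phylum!r}] negative")
        for clade, size in self.clade_sizes.items():
            if size < 0:
                raise ValueError(f"clade_sizes[{clade!r}] negative")
        for clade, motif in self.motif_spec.items():
            for pos in motif:
                if not 1 <= pos <= self.reference_length:
                    raise ValueError(
                        f"motif position {pos} outside reference (clade {clade!r})"
                    )
        for label in self.substitution_rates:
            _parse_substitution_label(label)
        if self.family_tree_depth < 0 or self.clade_divergence < 0:
            raise ValueError("divergence scales must be non-negative")
        if self.site_mutation_rate < 0:
            raise ValueError("site_mutation_rate must be non-negative")

    @property
    def clade_labels(self) -> list[str]:
        return sorted(self.motif_spec)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("synthetic-data config must set an explicit seed")
        return cls(**data)


_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def _parse_substitution_label(label: str) -> tuple[str, int, str]:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed substitution label {label!r} (want e.g. 'Y42F')")
    return m.group(1), int(m.group(2)), m.group(3)


# --------------------------------------------------------------------------
# Sequence evolution
# --------------------------------------------------------------------------


def _rng(config: SynthConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *tags])


def _draw_ancestor(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(20, size=length, p=BACKGROUND).astype(np.int8)


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of uniform (Jukes-Cantor-style) amino-acid replacement:
    each site substitutes with probability 1 - exp(-t) to one of the 19
    other residues, uniformly."""
    out = seq.copy()
    if t <= 0:
        return out
    p = 1.0 - math.exp(-t)
    hit = np.nonzero(rng.random(seq.shape[0]) < p)[0]
    if hit.size:
        shift = rng.integers(1, 20, size=hit.size)
        out[hit] = (out[hit] + shift) % 20
    return out


def _coalescent_tree(size: int, rng: np.random.Generator):
    """Random coalescent-shaped bifurcating tree over ``size`` leaves.

    Returns (children, heights): nodes 0..size-1 are leaves at height 0;
    internal nodes follow. Heights are rescaled so the root height is exactly
    1 (the caller multiplies by the divergence scale).
    """
    children: dict[int, tuple[int, int]] = {}
    heights = [0.0] * size
    active = list(range(size))
    h = 0.0
    nxt = size
    k = size
    while len(active) > 1:
        h += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        heights.append(h)
        active[i] = nxt
        active.pop(j)
        nxt += 1
        k -= 1
    root_h = heights[-1] if len(heights) > size else 1.0
    if root_h > 0:
        heights = [x / root_h for x in heights]
    return children, heights


def _evolve_tree(
    ancestor: np.ndarray,
    size: int,
    depth: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Evolve ``size`` leaf sequences from ``ancestor`` along a random
    coalescent tree with root-to-leaf depth ``depth`` substitutions/site."""
    if size == 1:
        return [_evolve(ancestor, depth, rng)]
    children, heights = _coalescent_tree(size, rng)
    root = len(heights) - 1
    seqs: dict[int, np.ndarray] = {root: ancestor}
    # walk from root down (internal nodes were appended in increasing height)
    for node in range(root, size - 1, -1):
        a, b = children[node]
        for child in (a, b):
            t = (heights[node] - heights[child]) * depth
            seqs[child] = _evolve(seqs[node], t, rng)
    return [seqs[i] for i in range(size)]


def _decode(seq: np.ndarray) -> str:
    return "".join(AA[i] for i in seq)


def pyp_root(config: SynthConfig) -> np.ndarray:
    """The planted family's root ancestor, with the full reference motif."""
    rng = _rng(config, 1)
    root = _draw_ancestor(config.reference_length, rng)
    for pos, res in REFERENCE_MOTIF.items():
        root[pos - 1] = AA.index(res)
    return root


def reference_record(config: SynthConfig) -> SequenceRecord:
    """The reference sequence (the planted family's root; reference numbering
    is simply 1..reference_length on this sequence)."""
    return SequenceRecord(
        id="PYP_REF",
        residues=_decode(pyp_root(config)),
        planted_family="PYP",
        planted_clade=None,
    )


def _plant_motif_and_substitutions(
    leaf: np.ndarray,
    clade: str,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    motif = config.motif_spec.get(clade, {})
    planted: list[str] = []
    has42or46 = False
    for label in sorted(config.substitution_rates):
        ref_res, pos, new_res = _parse_substitution_label(label)
        if pos not in motif:
            continue
        draw = rng.random()  # always drawn, keeps the stream aligned
        if draw < config.substitution_rates[label]:
            if pos in (42, 46):
                if has42or46:
                    continue  # 42- and 46-substitutions never co-occur
                has42or46 = True
            planted.append(label)
    out = leaf.copy()
    if any(_parse_substitution_label(lab)[1] == 69 for lab in planted):
        out = _evolve(out, config.nonfunctional_extra_divergence, rng)
    for pos, res in motif.items():
        out[pos - 1] = AA.index(res)
    for label in planted:
        _ref_res, pos, new_res = _parse_substitution_label(label)
        out[pos - 1] = AA.index(new_res)
    return out, planted


def generate_family(
    config: SynthConfig,
    clade: str,
    size: int,
) -> list[SequenceRecord]:
    """Generate one family/clade of ``size`` sequences.

    PYP clades (those present in ``config.motif_spec``) evolve from the shared
    family root through a clade ancestor; decoy clades (labels like
    ``decoy1``) evolve from independent random ancestors. Motif positions are
    restored after evolution, except where a labeled substitution is planted.
    """
    if size < 1:
        raise ValueError("family size must be >= 1")
    is_pyp = clade in config.motif_spec
    if not is_pyp and not re.match(r"^decoy\d+$", clade):
        raise ValueError(
            f"unknown clade {clade!r}: not in motif_spec and not a decoy label"
        )
    if is_pyp:
        clade_idx = sorted(config.motif_spec).index(clade)
        rng = _rng(config, 2, clade_idx)
        ancestor = _evolve(pyp_root(config), config.site_mutation_rate * config.clade_divergence, rng)
    else:
        decoy_idx = int(clade[5:])
        rng = _rng(config, 3, decoy_idx)
        ancestor = _draw_ancestor(config.reference_length, rng)
    depth = config.site_mutation_rate * config.family_tree_depth
    leaves = _evolve_tree(ancestor, size, depth, rng)
    records = []
    for i, leaf in enumerate(leaves, start=1):
        seq, planted = _plant_motif_and_substitutions(leaf, clade, config, rng)
        records.append(
            SequenceRecord(
                id=f"{clade}_{i:04d}",
                residues=_decode(seq),
                planted_family="PYP" if is_pyp else clade,
                planted_clade=clade if is_pyp else None,
            )
        )
    return records


# --------------------------------------------------------------------------
# Genomes, gene tables, full dataset
# --------------------------------------------------------------------------


@dataclass
class Dataset:
    sequences: list[SequenceRecord]
    genes: list[GeneRecord]
    genomes: pd.DataFrame  # genome_id, phylum, order, carries_pyp
    reference: SequenceRecord


def _gene_table(
    genome_id: str,
    config: SynthConfig,
    rng: np.random.Generator,
    pyp_sequence_id: str | None,
) -> list[GeneRecord]:
    n = config.genes_per_contig
    w = config.neighbor_window
    categories = ["hypothetical"] * n
    seq_ids: list[str | None] = [None] * n
    if pyp_sequence_id is not None:
        lo, hi = w, n - w - 1
        focal = int(rng.integers(lo, hi + 1)) if hi >= lo else n // 2
        categories[focal] = "PYP"
        seq_ids[focal] = pyp_sequence_id
        offsets = [o for o in range(-w, w + 1) if o != 0]
        for cat in NEIGHBOR_CATEGORIES:
            p = config.neighbor_freqs.get(cat, 0.0)
            if rng.random() >= p:
                continue
            free = [o for o in offsets if 0 <= focal + o < n and categories[focal + o] == "hypothetical"]
            if not free:
                continue
            off = free[int(rng.integers(len(free)))]
            categories[focal + off] = cat
    genes = []
    pos = 1
    for idx in range(n):
        length = int(rng.integers(300, 1501))
        if idx > 0:
            gap = int(rng.integers(-30, 301))
            pos = genes[-1].end + gap + 1
        start = max(pos, 1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                contig="ctg1",
                start=start,
                end=start + length - 1,
                strand=strand,
                index=idx + 1,
                category=categories[idx],
                sequence_id=seq_ids[idx],
            )
        )
    return genes


def simulate(config: SynthConfig) -> Dataset:
    """Generate the full synthetic dataset under the configured conditions.

    Genome counts per phylum are honored exactly; each genome carries a PYP
    gene with its phylum's prevalence probability; the number of PYP family
    members equals the number of carrier genomes (one gene per carrier), and
    their clades follow the per-phylum clade affinities. Decoy family members
    are attached to arbitrary genomes.
    """
    grng = _rng(config, 10)
    genome_rows = []
    carriers: list[tuple[str, str]] = []  # (genome_id, clade)
    gid = 0
    for phylum in config.genomes_per_phylum:  # insertion order: deterministic
        n = config.genomes_per_phylum[phylum]
        prev = config.pyp_prevalence.get(phylum, 0.0)
        affinity = config.clade_affinity.get(
            phylum, {c: 1.0 / len(config.clade_labels) for c in config.clade_labels}
        )
        clades = sorted(affinity)
        probs = np.array([affinity[c] for c in clades], dtype=float)
        probs /= probs.sum()
        for _ in range(n):
            gid += 1
            genome_id = f"G{gid:04d}"
            order = f"{phylum}_o{int(grng.integers(1, config.orders_per_phylum + 1))}"
            carries = bool(grng.random() < prev)
            genome_rows.append(
                {
                    "genome_id": genome_id,
                    "phylum": phylum,
                    "order": order,
                    "carries_pyp": carries,
                }
            )
            if carries:
                clade = clades[int(grng.choice(len(clades), p=probs))]
                carriers.append((genome_id, clade))
    genomes = pd.DataFrame(
        genome_rows, columns=["genome_id", "phylum", "order", "carries_pyp"]
    )
    by_genome = {row["genome_id"]: row for row in genome_rows}

    # PYP families sized by their carriers
    sequences: list[SequenceRecord] = []
    carrier_seq: dict[str, str] = {}
    for clade in config.clade_labels:
        clade_carriers = [g for g, c in carriers if c == clade]
        if not clade_carriers:
            continue
        fam = generate_family(config, clade, len(clade_carriers))
        for rec, genome_id in zip(fam, clade_carriers):
            rec.genome_id = genome_id
            rec.phylum = by_genome[genome_id]["phylum"]
            rec.order = by_genome[genome_id]["order"]
            carrier_seq[genome_id] = rec.id
            sequences.append(rec)

    # decoy families on arbitrary genomes
    arng = _rng(config, 11)
    all_genomes = list(genomes["genome_id"])
    for d in range(1, config.n_decoy_families + 1):
        fam = generate_family(config, f"decoy{d}", config.decoy_family_size)
        for rec in fam:
            genome_id = all_genomes[int(arng.integers(len(all_genomes)))]
            rec.genome_id = genome_id
            rec.phylum = by_genome[genome_id]["phylum"]
            rec.order = by_genome[genome_id]["order"]
            sequences.append(rec)

    # gene tables for every genome
    trng = _rng(config, 12)
    genes: list[GeneRecord] = []
    for row in genome_rows:
        genes.extend(
            _gene_table(
                row["genome_id"], config, trng, carrier_seq.get(row["genome_id"])
            )
        )
    return Dataset(
        sequences=sequences,
        genes=genes,
        genomes=genomes,
        reference=reference_record(config),
    )


def generate_dataset(config: SynthConfig):
    """Spec-shaped convenience: ``(sequences, genes)`` of :func:`simulate`."""
    ds = simulate(config)
    return ds.sequences, ds.genes


# --------------------------------------------------------------------------
# File output (FASTA / TSV / GFF3)
# --------------------------------------------------------------------------


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.residues
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [
        SequenceRecord(id=r.id, residues=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_taxonomy(dataset: Dataset, path) -> None:
    """Sequence taxonomy TSV: id, genome_id, phylum, order."""
    rows = [
        {
            "id": r.id,
            "genome_id": r.genome_id,
            "phylum": r.phylum,
            "order": r.order,
        }
        for r in dataset.sequences
    ]
    pd.DataFrame(rows, columns=["id", "genome_id", "phylum", "order"]).to_csv(
        path, sep="\t", index=False
    )


def write_genomes(dataset: Dataset, path) -> None:
    dataset.genomes.to_csv(path, sep="\t", index=False)


def write_ground_truth(dataset: Dataset, path) -> None:
    rows = [
        {
            "id": r.id,
            "planted_family": r.planted_family or "",
            "planted_clade": r.planted_clade or "",
        }
        for r in dataset.sequences
    ]
    pd.DataFrame(rows, columns=["id", "planted_family", "planted_clade"]).to_csv(
        path, sep="\t", index=False
    )


GENE_COLUMNS = [
    "genome_id", "contig", "start", "end", "strand", "index", "category", "sequence_id",
]


def write_genes_tsv(genes, path) -> None:
    rows = [
        {
            "genome_id": g.genome_id,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "index": g.index,
            "category": g.category,
            "sequence_id": g.sequence_id or "",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        GeneRecord(
            genome_id=row.genome_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            index=int(row.index),
            category=row.category,
            sequence_id=row.sequence_id or None,
        )
        for row in df.itertuples()
    ]


def write_genes_gff3(genes, path) -> None:
    """GFF3 with one CDS row per gene; category and sequence link are carried
    in the attributes column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.genome_id}.{g.contig}.{g.index};category={g.category}"
            if g.sequence_id:
                attrs += f";sequence_id={g.sequence_id}"
            fh.write(
                f"{g.genome_id}.{g.contig}\tpypfam\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


def read_genes_gff3(path) -> list[GeneRecord]:
    genes = []
    counters: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            if ftype != "CDS":
                continue
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            genome_id, contig = seqid.rsplit(".", 1)
            counters[seqid] = counters.get(seqid, 0) + 1
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    index=counters[seqid],
                    category=fields.get("category", "hypothetical"),
                    sequence_id=fields.get("sequence_id"),
                )
            )
    return genes
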