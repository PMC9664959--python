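"""Synthetic-data generator: determinism, planted constraints, calibration."""

import math

import numpy as np
import pytest

from pypfam.align import AA, BACKGROUND, global_align
from pypfam.synthdata import (
    GeneRecord,
    SequenceRecord,
    SynthConfig,
    generate_dataset,
    generate_family,
    read_genes_gff3,
    read_genes_tsv,
    reference_record,
    simulate,
    write_fasta,
    write_genes_gff3,
    write_genes_tsv,
    write_taxonomy,
)


class TestConfigValidation:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            SynthConfig(substitution_rates={"Y42F": 1.5})

    def test_motif_positions_must_fit_reference(self):
        with pytest.raises(ValueError, match="motif position"):
            SynthConfig(reference_length=50, motif_spec={"A": {69: "C"}})

    def test_malformed_substitution_label_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            SynthConfig(substitution_rates={"Y42": 0.1})


class TestGenerateFamily:
    def test_zero_rate_yields_identical_copies(self):
        cfg = SynthConfig(seed=1, site_mutation_rate=0.0, substitution_rates={})
        fam = generate_family(cfg, "A", 3)
        assert fam[0].residues == fam[1].residues == fam[2].residues

    def test_motif_forced_when_no_substitutions(self):
        cfg = SynthConfig(seed=2, substitution_rates={})
        for rec in generate_family(cfg, "A", 40):
            assert rec.residues[68] == "C"  # reference position 69
            assert rec.residues[41] == "Y"
            assert rec.residues[45] == "E"

    def test_unknown_clade_rejected(self, config):
        with pytest.raises(ValueError, match="unknown clade"):
            generate_family(config, "Z", 5)

    def test_ground_truth_labels_recorded(self, config):
        fam = generate_family(config, "B", 4)
        assert all(r.planted_family == "PYP" for r in fam)
        assert all(r.planted_clade == "B" for r in fam)
        dec = generate_family(config, "decoy1", 4)
        assert all(r.planted_family == "decoy1" for r in dec)

    def test_mean_pairwise_identity_matches_independent_simulation(self):
        """Monte-Carlo oracle: an independently coded simulator with the same
        generator equations (Kingman coalescent rescaled to the configured
        depth, per-branch substitution probability 1-exp(-t), uniform target
        residue) should produce the same mean pairwise identity."""
        depth = 0.05
        size = 50
        cfg_ids = []
        for seed in range(10):
            cfg = SynthConfig(
                seed=seed, family_tree_depth=depth, substitution_rates={}
            )
            fam = generate_family(cfg, "A", size)
            rng = np.random.default_rng(seed + 100)
            idx = rng.choice(size, size=(30, 2))
            vals = []
            for i, j in idx:
                if i == j:
                    continue
                a, b = fam[i].residues, fam[j].residues
                vals.append(sum(x == y for x, y in zip(a, b)) / len(a))
            cfg_ids.append(np.mean(vals))

        def oracle_mean_identity(seed):
            rng = np.random.default_rng(seed)
            # coalescent heights
            heights = [0.0] * size
            children = {}
            active = list(range(size))
            h, nxt, k = 0.0, size, size
            while len(active) > 1:
                h += rng.exponential(2.0 / (k * (k - 1)))
                i, j = sorted(rng.choice(len(active), size=2, replace=False))
                children[nxt] = (active[i], active[j])
                heights.append(h)
                active[i] = nxt
                active.pop(j)
                nxt += 1
                k -= 1
            root_h = heights[-1]
            heights = [x / root_h * depth for x in heights]
            root = len(heights) - 1
            L = 125
            seqs = {root: rng.choice(20, size=L, p=BACKGROUND)}
            for node in range(root, size - 1, -1):
                a, b = children[node]
                for child in (a, b):
                    t = heights[node] - heights[child]
                    s = seqs[node].copy()
                    hit = rng.random(L) < 1 - math.exp(-t)
                    nhit = hit.sum()
                    if nhit:
                        s[hit] = (s[hit] + rng.integers(1, 20, size=nhit)) % 20
                    seqs[child] = s
            vals = []
            for _ in range(30):
                i, j = rng.choice(size, size=2, replace=False)
                vals.append(np.mean(seqs[i] == seqs[j]))
            return np.mean(vals)

        oracle = [oracle_mean_identity(s) for s in range(10)]
        se = math.sqrt(np.var(cfg_ids) / 10 + np.var(oracle) / 10)
        assert abs(np.mean(cfg_ids) - np.mean(oracle)) < 3 * max(se, 1e-3)


class TestDataset:
    def test_genome_counts_honored_exactly(self):
        cfg = SynthConfig(seed=3, genomes_per_phylum={"A": 10, "B": 4})
        seqs, genes = generate_dataset(cfg)
        genome_ids = {g.genome_id for g in genes}
        assert len(genome_ids) == 14

    def test_zero_prevalence_phylum_has_no_family_genes(self):
        cfg = SynthConfig(
            seed=4,
            genomes_per_phylum={"PhylumX": 30, "PhylumY": 30},
            pyp_prevalence={"PhylumX": 0.0, "PhylumY": 0.5},
        )
        ds = simulate(cfg)
        x_genomes = set(ds.genomes[ds.genomes.phylum == "PhylumX"].genome_id)
        pyp_genomes = {r.genome_id for r in ds.sequences if r.planted_family == "PYP"}
        assert not (x_genomes & pyp_genomes)

    def test_certain_neighbor_placed_for_every_family_gene(self):
        cfg = SynthConfig(
            seed=5,
            genomes_per_phylum={"P": 40},
            pyp_prevalence={"P": 1.0},
            neighbor_freqs={"TAL": 1.0},
        )
        ds = simulate(cfg)
        tables = {}
        for g in ds.genes:
            tables.setdefault(g.genome_id, []).append(g)
        focal = [g for g in ds.genes if g.category == "PYP"]
        assert focal
        for gene in focal:
            window = [
                g
                for g in tables[gene.genome_id]
                if g.contig == gene.contig and 1 <= abs(g.index - gene.index) <= 5
            ]
            assert any(g.category == "TAL" for g in window)

    def test_neighbor_frequencies_recovered_within_3se(self):
        cfg = SynthConfig(
            seed=6, genomes_per_phylum={"P": 300}, pyp_prevalence={"P": 1.0}
        )
        ds = simulate(cfg)
        tables = {}
        for g in ds.genes:
            tables.setdefault(g.genome_id, []).append(g)
        focal = [g for g in ds.genes if g.category == "PYP"]
        n = len(focal)
        assert n == 300
        for cat, p in (("TAL", 0.30), ("pCL", 0.40)):
            hits = sum(
                any(
                    g.category == cat and 1 <= abs(g.index - f.index) <= 5
                    for g in tables[f.genome_id]
                )
                for f in focal
            )
            se = math.sqrt(p * (1 - p) / n)
            assert abs(hits / n - p) < 3 * se

    def test_gene_tables_well_formed(self, config):
        ds = simulate(config)
        by_contig = {}
        for g in ds.genes:
            assert g.start <= g.end
            by_contig.setdefault((g.genome_id, g.contig), []).append(g)
        for genes in by_contig.values():
            genes.sort(key=lambda g: g.index)
            assert [g.index for g in genes] == list(range(1, len(genes) + 1))
            starts = [g.start for g in genes]
            assert starts == sorted(starts)

    def test_overlapping_genes_occur(self, config):
        ds = simulate(config)
        by_contig = {}
        for g in ds.genes:
            by_contig.setdefault((g.genome_id, g.contig), []).append(g)
        overlaps = 0
        for genes in by_contig.values():
            genes.sort(key=lambda g: g.index)
            for a, b in zip(genes, genes[1:]):
                if b.start - a.end - 1 < 0:
                    overlaps += 1
        assert overlaps > 0  # gaps are drawn from [-30, 300] bp


class TestDeterminism:
    def test_identical_config_gives_identical_files(self, tmp_path):
        for run in ("r1", "r2"):
            cfg = SynthConfig(seed=9, genomes_per_phylum={"P": 20, "Q": 10})
            ds = simulate(cfg)
            d = tmp_path / run
            d.mkdir()
            write_fasta(ds.sequences, d / "seqs.fasta")
            write_taxonomy(ds, d / "tax.tsv")
            write_genes_tsv(ds.genes, d / "genes.tsv")
            write_genes_gff3(ds.genes, d / "genes.gff3")
        for name in ("seqs.fasta", "tax.tsv", "genes.tsv", "genes.gff3"):
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()


class TestGeneTableIO:
    def test_tsv_and_gff3_round_trip_agree(self, tmp_path, config):
        ds = simulate(SynthConfig(seed=11, genomes_per_phylum={"P": 5},
                                  pyp_prevalence={"P": 1.0}))
        write_genes_tsv(ds.genes, tmp_path / "g.tsv")
        write_genes_gff3(ds.genes, tmp_path / "g.gff3")
        t = read_genes_tsv(tmp_path / "g.tsv")
        g = read_genes_gff3(tmp_path / "g.gff3")
        key = lambda r: (r.genome_id, r.contig, r.index)
        assert [key(r) for r in t] == [key(r) for r in g]
        for a, b in zip(t, g):
            assert (a.start, a.end, a.strand, a.category, a.sequence_id) == (
                b.start, b.end, b.strand, b.category, b.sequence_id
            )


class TestReference:
    def test_reference_carries_full_motif(self, reference):
        assert reference.residues[41] == "Y"
        assert reference.residues[45] == "E"
        assert reference.residues[49] == "S"
        assert reference.residues[68] == "C"
        assert reference.residues[91] == "F"
        assert reference.residues[95] == "F"
        assert reference.residues[99] == "M"
        assert reference.residues[118] == "W"
        assert len(reference.residues) == 125
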