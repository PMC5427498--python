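"""Simulator: structure targets, determinism, ledger conservation."""

import numpy as np
import pytest

from annodiff import genemodel_audit as gma
from annodiff import seqio, synthetic
from annodiff.synthetic import SimConfig

from conftest import clean_config


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(n_false_genes=-1)
        with pytest.raises(ValueError):
            SimConfig(omega=0)


class TestAncestor:
    def test_minimal_single_gene(self):
        g = synthetic.make_ancestor(clean_config(n_genes=1, n_scaffolds=1))
        assert len(g.genes) == 1
        prot = seqio.translate(seqio.extract_cds(g, g.genes[0].gene_id))
        assert prot.startswith("M") and prot.endswith("*") and "*" not in prot[:-1]

    def test_structure_means_near_targets(self):
        g = synthetic.make_ancestor(clean_config(n_genes=400))
        n_exons = [len(x.exons) for x in g.genes]
        exon_sizes = [e - s + 1 for x in g.genes for s, e in x.exons]
        intron_sizes = [e - s + 1 for x in g.genes for s, e in x.introns()]
        assert np.mean(n_exons) == pytest.approx(6.9, rel=0.10)
        assert np.mean(exon_sizes) == pytest.approx(237, rel=0.10)
        assert np.median(intron_sizes) == pytest.approx(70, rel=0.15)

    def test_introns_are_canonical_gt_ag(self, small_clean_genome):
        g = small_clean_genome
        for gene in g.genes:
            seq = g.scaffold(gene.scaffold_id).sequence
            for s, e in gene.introns():
                sense = seq[s - 1 : e]
                if gene.strand == "-":
                    sense = seqio.reverse_complement(sense)
                assert sense[:2] == "GT" and sense[-2:] == "AG"

    def test_no_hygiene_lesions_pre_injection(self):
        ds = synthetic.simulate(clean_config(n_genes=60))
        for g in (ds.genome_a, ds.genome_b, ds.outgroup):
            s = gma.audit_summary(g)
            assert (s.missing_start, s.missing_stop, s.premature_stop) == (0, 0, 0)


class TestEvolve:
    def test_zero_branch_is_identity(self, small_clean_genome):
        rng = np.random.default_rng(0)
        out = synthetic.evolve(small_clean_genome, 0.0, 0.25, rng, "copy")
        for sc in small_clean_genome.scaffolds:
            assert out.scaffold(sc.id).sequence == sc.sequence

    def test_divergence_scales_with_branch_length(self, small_clean_genome):
        rng = np.random.default_rng(0)
        short = synthetic.evolve(small_clean_genome, 0.01, 0.25, rng, "s")
        long = synthetic.evolve(small_clean_genome, 0.1, 0.25, rng, "l")

        def ndiff(g):
            return sum(
                x != y
                for a, b in zip(small_clean_genome.scaffolds, g.scaffolds)
                for x, y in zip(a.sequence, b.sequence)
            )

        assert ndiff(long) > 5 * ndiff(short) > 0


class TestInjection:
    def test_zero_rate_config_changes_nothing(self):
        cfg = clean_config(n_genes=10)
        ds = synthetic.simulate(cfg)
        assert len(ds.ledger) == 0
        assert len(ds.genome_b.genes) == len(ds.genome_a.genes)

    def test_ledger_row_count_matches_configured_events(self, default_dataset):
        cfg = default_dataset.config
        expected = (
            cfg.n_false_genes
            + cfg.n_splits_a
            + cfg.n_splits_b
            + cfg.n_inparalog_duplications
            + cfg.n_intron_gains_a
            + cfg.n_intron_gains_b
            + cfg.n_intron_losses_a
            + cfg.n_intron_losses_b
            + cfg.n_contaminant_scaffolds
        )
        assert len(default_dataset.ledger) == expected

    def test_ledger_ids_resolve_in_emitted_genomes(self, default_dataset):
        ds = default_dataset
        gene_events = ds.ledger[
            ds.ledger.event.isin(["false_gene", "duplication", "intron_gain", "intron_loss"])
        ]
        genomes = {"A": ds.genome_a, "B": ds.genome_b}
        for _, row in gene_events.iterrows():
            genomes[row.genome].gene(row.target)  # raises KeyError if missing
        for sid in ds.contaminant_scaffolds:
            ds.genome_a.scaffold(sid)

    def test_structural_edits_preserve_reading_frame(self, default_dataset):
        ds = default_dataset
        edited = ds.ledger[ds.ledger.event.isin(["intron_gain", "intron_loss", "duplication"])]
        genomes = {"A": ds.genome_a, "B": ds.genome_b}
        for _, row in edited.iterrows():
            prot = seqio.translate(seqio.extract_cds(genomes[row.genome], row.target))
            assert "*" not in prot[:-1]

    def test_false_genes_are_short_intronless_and_at_rich(self, default_dataset):
        ds = default_dataset
        lo, hi = ds.config.false_gene_length_range
        for fid in ds.ledger.loc[ds.ledger.event == "false_gene", "target"]:
            g = ds.genome_b.gene(fid)
            assert len(g.exons) == 1
            assert lo - 6 <= g.cds_length() <= hi + 6
            gc = seqio.gc_fraction(seqio.extract_cds(ds.genome_b, fid))
            assert gc < ds.config.coding_gc
            assert ds.expression["B"][fid] is False


class TestEmit:
    def test_fixed_seed_runs_are_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes=12, n_false_genes=3, n_splits_b=1,
                        n_inparalog_duplications=1, n_intron_gains_a=1, n_intron_gains_b=1,
                        n_intron_losses_a=0, n_intron_losses_b=1, n_contaminant_scaffolds=1)
        f1 = synthetic.emit(synthetic.simulate(cfg), tmp_path / "run1")
        f2 = synthetic.emit(synthetic.simulate(cfg), tmp_path / "run2")
        assert f1.keys() == f2.keys()
        for name in f1:
            assert synthetic.file_sha256(f1[name]) == synthetic.file_sha256(f2[name]), name

    def test_emitted_gff3_rereadable_and_lossless(self, tmp_path):
        cfg = SimConfig(seed=2, n_genes=10, n_false_genes=2, n_splits_b=1,
                        n_inparalog_duplications=1, n_intron_gains_b=1,
                        n_intron_gains_a=0, n_intron_losses_a=0, n_intron_losses_b=0,
                        n_contaminant_scaffolds=1)
        ds = synthetic.simulate(cfg)
        files = synthetic.emit(ds, tmp_path)
        back = seqio.read_genome(files["genome_b.fasta"], files["genome_b.gff3"], label="B")
        assert {g.gene_id for g in back.genes} == {g.gene_id for g in ds.genome_b.genes}
        for g in ds.genome_b.genes:
            assert back.gene(g.gene_id).cds == g.cds
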