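"""Intron site mapping and Dollo polarization."""

import itertools

import numpy as np
import pytest

from annodiff import introns as intr
from annodiff import pipeline, synthetic
from annodiff.align import global_align_protein
from annodiff.seqio import AnnotatedGenome, GeneModel, Scaffold


def dollo_call_oracle(a: bool, b: bool, o: bool) -> str:
    """Exhaustive minimal-event enumeration on the rooted tree ((A,B)P,O)R
    under the single-gain (Dollo) constraint."""
    if not (a or b or o):
        return "invalid"
    histories = []
    for root in (0, 1):
        for p in (0, 1):
            events = []
            for frm, to, branch in (
                (root, int(o), "RO"),
                (root, p, "RP"),
                (p, int(a), "PA"),
                (p, int(b), "PB"),
            ):
                if frm != to:
                    events.append(("gain" if to == 1 else "loss", branch))
            gains = sum(1 for e, _ in events if e == "gain") + (1 if root == 1 else 0)
            if gains > 1:
                continue
            histories.append(events)
    m = min(len(e) for e in histories)
    minimal = [tuple(sorted(e)) for e in histories if len(e) == m]
    if m == 0:
        return "conserved"
    terminal = {
        ("gain", "PA"): "gain_a",
        ("gain", "PB"): "gain_b",
        ("loss", "PA"): "loss_a",
        ("loss", "PB"): "loss_b",
    }
    single_terminal = {
        terminal[h[0]] for h in minimal if len(h) == 1 and h[0] in terminal
    }
    if len(minimal) == 1 and single_terminal:
        return single_terminal.pop()
    # ambiguity among histories that never touch the A/B terminal branches
    if not a and not b:
        return "ancestral_absence"
    return "ambiguous_pulex_edge"


class TestPolarize:
    @pytest.mark.parametrize("triple", list(itertools.product([False, True], repeat=3)))
    def test_matches_dollo_enumeration(self, triple):
        assert intr.polarize(triple) == dollo_call_oracle(*triple)

    def test_total_and_deterministic(self):
        calls = {intr.polarize(t) for t in itertools.product([False, True], repeat=3)}
        assert calls == set(intr.CALLS)

    @pytest.mark.parametrize("triple", list(itertools.product([False, True], repeat=3)))
    def test_genome_swap_symmetry(self, triple):
        a, b, o = triple
        swap = {"gain_a": "gain_b", "gain_b": "gain_a", "loss_a": "loss_b", "loss_b": "loss_a"}
        c1 = intr.polarize((a, b, o))
        c2 = intr.polarize((b, a, o))
        assert c2 == swap.get(c1, c1)


def _call(call, la=None, lb=None, gca=None, gcb=None, validated=True):
    return intr.IntronSiteCall(
        "p", 0, 0, (True, True, True), call,
        length_a=la, length_b=lb, gc_a=gca, gc_b=gcb, expression_validated=validated,
    )


class TestSummarize:
    def test_percent_excess_from_observed_counts(self):
        calls = [_call("gain_b", lb=72) for _ in range(57)]
        calls += [_call("gain_a", la=76) for _ in range(32)]
        calls += [_call("loss_b", la=65) for _ in range(10)]
        s = intr.summarize_events(calls, ("PA", "TC"))
        assert (s.gains["TC"], s.gains["PA"]) == (57, 32)
        assert s.percent_excess_gains("TC", "PA") == pytest.approx(78.125)
        assert s.losses["PA"] == 0
        assert s.median_lost_bp["PA"] is None  # zero losses -> N/A
        assert s.median_lost_bp["TC"] == 65

    def test_counts_conserved_across_classes(self):
        calls = (
            [_call("gain_a", la=60)] * 3
            + [_call("conserved")] * 5
            + [_call("ambiguous_pulex_edge")] * 2
            + [_call("ancestral_absence")] * 1
        )
        s = intr.summarize_events(calls, ("A", "B"))
        total = (
            sum(s.gains.values()) + sum(s.losses.values())
            + s.n_conserved + s.n_ambiguous + s.n_ancestral_absence
        )
        assert total == s.n_sites == len(calls)

    def test_expression_filter(self):
        calls = [_call("gain_a", la=60, validated=False), _call("gain_a", la=60)]
        s = intr.summarize_events(calls, ("A", "B"), expression_validated_only=True)
        assert s.gains["A"] == 1


class TestMapping:
    @pytest.fixture(scope="class")
    def gain_in_a(self):
        """Identical genomes except one injected intron gain in A."""
        cfg = synthetic.SimConfig(
            seed=1, n_genes=8, n_scaffolds=1,
            branch_silent_divergence=0.0,
            n_false_genes=0, n_splits_a=0, n_splits_b=0, n_inparalog_duplications=0,
            n_intron_gains_a=1, n_intron_gains_b=0,
            n_intron_losses_a=0, n_intron_losses_b=0, n_contaminant_scaffolds=0,
        )
        return synthetic.simulate(cfg)

    def test_gain_detected_at_exact_projected_position(self, gain_in_a):
        ds = gain_in_a
        row = ds.ledger[ds.ledger.event == "intron_gain"].iloc[0]
        gid, offset = row.target, int(row.position)
        pa, _ = pipeline.coding_sequences(ds.genome_a)
        pb, _ = pipeline.coding_sequences(ds.genome_b)
        po, _ = pipeline.coding_sequences(ds.outgroup)
        aln_ab = global_align_protein(pa[gid], pb[gid])
        aln_ao = global_align_protein(pa[gid], po[gid])
        calls = intr.map_intron_sites(
            ds.genome_a, ds.genome_a.gene(gid),
            ds.genome_b, ds.genome_b.gene(gid),
            ds.outgroup, ds.outgroup.gene(gid),
            aln_ab, aln_ao,
        )
        hits = [c for c in calls if c.call == "gain_a"]
        assert len(hits) == 1
        assert (hits[0].codon_index, hits[0].phase) == (offset // 3, offset % 3)
        assert hits[0].presence == (True, False, False)

    def test_untouched_genes_are_all_conserved(self, gain_in_a):
        ds = gain_in_a
        touched = set(ds.ledger.target)
        pa, _ = pipeline.coding_sequences(ds.genome_a)
        pb, _ = pipeline.coding_sequences(ds.genome_b)
        po, _ = pipeline.coding_sequences(ds.outgroup)
        for gid in pa:
            if gid in touched:
                continue
            calls = intr.map_intron_sites(
                ds.genome_a, ds.genome_a.gene(gid),
                ds.genome_b, ds.genome_b.gene(gid),
                ds.outgroup, ds.outgroup.gene(gid),
                global_align_protein(pa[gid], pb[gid]),
                global_align_protein(pa[gid], po[gid]),
            )
            assert all(c.call == "conserved" for c in calls)

    def test_flank_aa_precondition(self):
        with pytest.raises(ValueError):
            intr.map_intron_sites(None, None, None, None, None, None, None, None, flank_aa=3)

    def test_intron_near_cds_start_dropped_and_counted(self):
        # intron 2 codons into the CDS: left flank is below the 5-aa floor
        rng = np.random.default_rng(3)
        body = synthetic._random_codons(rng, 40, 0.45)
        cds = "ATGAAA" + body + "TAA"
        intron = "GT" + "A" * 40 + "AG"
        seq_a = cds[:6] + intron + cds[6:]
        ga = AnnotatedGenome(
            "A", [Scaffold("s", seq_a)],
            [GeneModel("g", "s", "+", [(1, 6), (7 + len(intron), len(seq_a))],
                       [(1, 6, 0), (7 + len(intron), len(seq_a), 0)])],
        )
        gb = AnnotatedGenome(
            "B", [Scaffold("s", cds)],
            [GeneModel("g", "s", "+", [(1, len(cds))], [(1, len(cds), 0)])],
        )
        go = AnnotatedGenome(
            "outgroup", [Scaffold("s", cds)],
            [GeneModel("g", "s", "+", [(1, len(cds))], [(1, len(cds), 0)])],
        )
        pa, _ = pipeline.coding_sequences(ga)
        pb, _ = pipeline.coding_sequences(gb)
        po, _ = pipeline.coding_sequences(go)
        stats = intr.SiteMapStats()
        calls = intr.map_intron_sites(
            ga, ga.gene("g"), gb, gb.gene("g"), go, go.gene("g"),
            global_align_protein(pa["g"], pb["g"]),
            global_align_protein(pa["g"], po["g"]),
            stats=stats,
        )
        assert calls == []
        assert stats.n_dropped_flank == 1
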