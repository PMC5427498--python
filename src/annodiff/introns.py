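"""Intron gain/loss mapping and Dollo polarization across a genome pair.

Intron positions are expressed in protein coordinates (codon index plus
phase 0/1/2), projected between orthologs through their protein alignment,
and scored for presence in both ingroups and the outgroup. Presence triples
are polarized under Dollo parsimony on the 3-taxon tree ((A,B),outgroup): a
position is gained at most once, so e.g. an intron present only in B is a
B-lineage gain, while one present in both ingroups but absent from the
outgroup cannot be polarized (stem gain vs outgroup loss).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import seqio
from .align import ProteinAlignment, global_align_protein
from .seqio import AnnotatedGenome, GeneModel, gc_fraction

CALLS = (
    "gain_a",
    "gain_b",
    "loss_a",
    "loss_b",
    "conserved",
    "ambiguous_pulex_edge",
    "ancestral_absence",
    "invalid",
)

_POLARITY = {
    (True, False, False): "gain_a",
    (False, True, False): "gain_b",
    (False, True, True): "loss_a",
    (True, False, True): "loss_b",
    (True, True, True): "conserved",
    (True, True, False): "ambiguous_pulex_edge",
    (False, False, True): "ancestral_absence",
    (False, False, False): "invalid",
}


@dataclass
class IntronSiteCall:
    pair_id: str
    codon_index: int
    phase: int
    presence: tuple[bool, bool, bool]  # (ingroup A, ingroup B, outgroup)
    call: str
    length_a: int | None = None
    length_b: int | None = None
    gc_a: float | None = None
    gc_b: float | None = None
    expression_validated: bool = False


def polarize(presence: tuple[bool, bool, bool]) -> str:
    """Dollo call for one presence triple; total and deterministic."""
    return _POLARITY[tuple(bool(x) for x in presence)]


# ---------------------------------------------------------------------------
# position extraction


def intron_positions(genome: AnnotatedGenome, gene: GeneModel) -> dict[tuple[int, int], tuple[int, float]]:
    """Map (codon_index, phase) -> (intron length, intron GC) for one gene.

    The position is the number of coding bases 5' of the intron in
    translation order; phase 0 means the intron falls between codons.
    """
    out: dict[tuple[int, int], tuple[int, float]] = {}
    segs = list(gene.cds)
    introns = gene.introns()
    if not introns:
        return out
    seq = genome.scaffold(gene.scaffold_id).sequence
    seg_lengths = [e - s + 1 for s, e, _ in segs]
    total = sum(seg_lengths)
    phase0 = segs[0][2] if gene.strand == "+" else segs[-1][2]
    cum = 0
    for i, (s, e) in enumerate(introns):
        cum_plus = sum(seg_lengths[: i + 1])
        if gene.strand == "+":
            offset = cum_plus - phase0
        else:
            offset = (total - cum_plus) - phase0
        if offset <= 0:
            continue
        length = e - s + 1
        gc = gc_fraction(seq[s - 1 : e])
        out[(offset // 3, offset % 3)] = (length, gc)
    return out


# ---------------------------------------------------------------------------
# site mapping through protein alignments


def _residue_to_column(aligned: str) -> list[int]:
    """Column index of each residue of the degapped row."""
    return [i for i, c in enumerate(aligned) if c != "-"]


def _column_to_residue(aligned: str) -> dict[int, int]:
    out = {}
    r = 0
    for i, c in enumerate(aligned):
        if c != "-":
            out[i] = r
            r += 1
    return out


def _flank_identity(pa: ProteinAlignment, col: int, flank_aa: int) -> tuple[float, float, int]:
    """Identity of the columns left/right of ``col`` and min flank length."""

    def side(cols: range) -> tuple[float, int]:
        match = total = 0
        for i in cols:
            x, y = pa.aligned_a[i], pa.aligned_b[i]
            if x == "-" or y == "-":
                continue
            total += 1
            if x == y:
                match += 1
        return (match / total if total else 0.0), total

    left = side(range(max(0, col - flank_aa), col))
    right = side(range(col, min(len(pa.aligned_a), col + flank_aa)))
    return left[0], right[0], min(left[1], right[1])


@dataclass
class SiteMapStats:
    n_sites: int = 0
    n_dropped_flank: int = 0
    n_dropped_projection: int = 0


def map_intron_sites(
    genome_a: AnnotatedGenome,
    gene_a: GeneModel,
    genome_b: AnnotatedGenome,
    gene_b: GeneModel,
    outgroup: AnnotatedGenome,
    gene_o: GeneModel,
    aln_ab: ProteinAlignment,
    aln_ao: ProteinAlignment,
    aln_bo: ProteinAlignment | None = None,
    flank_aa: int = 20,
    flank_identity_floor: float = 0.6,
    min_flank_aa: int = 5,
    expression_a: Mapping[str, bool] | None = None,
    expression_b: Mapping[str, bool] | None = None,
    stats: SiteMapStats | None = None,
) -> list[IntronSiteCall]:
    """Candidate intron sites for one ortholog pair with outgroup homolog.

    Sites from all three gene models are projected onto the A-B alignment
    column space (the ingroup-A residue frame); sites whose flanks fail the
    identity floor in either alignment, or whose position cannot be
    projected, are dropped and counted, never guessed. Identical projected
    codon+phase positions are merged into one site.
    """
    if flank_aa < 5:
        raise ValueError("flank_aa must be >= 5")
    if stats is None:
        stats = SiteMapStats()
    pos_a = intron_positions(genome_a, gene_a)
    pos_b = intron_positions(genome_b, gene_b)
    pos_o = intron_positions(outgroup, gene_o)

    cols_a = _residue_to_column(aln_ab.aligned_a)
    col2res_b = _column_to_residue(aln_ab.aligned_b)
    res_b_to_col = _residue_to_column(aln_ab.aligned_b)
    cols_a_o = _residue_to_column(aln_ao.aligned_a)
    col2res_o = _column_to_residue(aln_ao.aligned_b)
    res_o_to_col_ao = _residue_to_column(aln_ao.aligned_b)
    col2res_a_ab = _column_to_residue(aln_ab.aligned_a)
    col2res_a_ao = _column_to_residue(aln_ao.aligned_a)

    # express every site in A-residue coordinates
    sites: dict[tuple[int, int], dict] = {}

    def add(codon_a: int, phase: int, source: str) -> None:
        sites.setdefault((codon_a, phase), {"sources": set()})["sources"].add(source)

    for (codon, phase) in pos_a:
        add(codon, phase, "a")
    for (codon, phase) in pos_b:
        if codon >= len(res_b_to_col):
            stats.n_dropped_projection += 1
            continue
        col = res_b_to_col[codon]
        ra = col2res_a_ab.get(col)
        if ra is None:
            stats.n_dropped_projection += 1
            continue
        add(ra, phase, "b")
    for (codon, phase) in pos_o:
        if codon >= len(res_o_to_col_ao):
            stats.n_dropped_projection += 1
            continue
        col = res_o_to_col_ao[codon]
        ra = col2res_a_ao.get(col)
        if ra is None:
            stats.n_dropped_projection += 1
            continue
        add(ra, phase, "o")

    out = []
    validated = True
    if expression_a is not None:
        validated = validated and bool(expression_a.get(gene_a.gene_id, False))
    if expression_b is not None:
        validated = validated and bool(expression_b.get(gene_b.gene_id, False))
    for (codon_a, phase) in sorted(sites):
        if codon_a >= len(cols_a) or codon_a >= len(cols_a_o):
            stats.n_dropped_projection += 1
            continue
        col_ab = cols_a[codon_a]
        col_ao = cols_a_o[codon_a]
        ok = True
        for pa, col in ((aln_ab, col_ab), (aln_ao, col_ao)):
            li, ri, minlen = _flank_identity(pa, col, flank_aa)
            if minlen < min_flank_aa or li < flank_identity_floor or ri < flank_identity_floor:
                ok = False
                break
        if not ok:
            stats.n_dropped_flank += 1
            continue
        res_b = col2res_b.get(col_ab)
        res_o = col2res_o.get(col_ao)
        in_a = (codon_a, phase) in pos_a
        in_b = res_b is not None and (res_b, phase) in pos_b
        in_o = res_o is not None and (res_o, phase) in pos_o
        la_gc = pos_a.get((codon_a, phase))
        lb_gc = pos_b.get((res_b, phase)) if res_b is not None else None
        presence = (in_a, in_b, in_o)
        out.append(
            IntronSiteCall(
                pair_id=f"{gene_a.gene_id}|{gene_b.gene_id}",
                codon_index=codon_a,
                phase=phase,
                presence=presence,
                call=polarize(presence),
                length_a=la_gc[0] if la_gc else None,
                length_b=lb_gc[0] if lb_gc else None,
                gc_a=la_gc[1] if la_gc else None,
                gc_b=lb_gc[1] if lb_gc else None,
                expression_validated=validated,
            )
        )
        stats.n_sites += 1
    return out


# ---------------------------------------------------------------------------
# summaries


@dataclass
class IntronEventSummary:
    n_sites: int
    gains: dict[str, int]  # per genome label
    losses: dict[str, int]
    median_gained_bp: dict[str, float | None]
    median_lost_bp: dict[str, float | None]
    gc_gained: dict[str, float | None]
    gc_lost: dict[str, float | None]
    n_conserved: int
    n_ambiguous: int
    n_ancestral_absence: int

    def percent_excess_gains(self, label_num: str, label_den: str) -> float | None:
        """Percent excess of gains in one genome over the other,
        ``100 * (gains_num / gains_den - 1)``."""
        den = self.gains.get(label_den, 0)
        if den == 0:
            return None
        return 100.0 * (self.gains[label_num] / den - 1.0)


def _median_or_none(vals: Sequence[float]) -> float | None:
    return float(np.median(vals)) if vals else None


def summarize_events(
    calls: Iterable[IntronSiteCall],
    genome_labels: tuple[str, str],
    expression_validated_only: bool = False,
) -> IntronEventSummary:
    """Tally polarized calls into per-genome gain/loss counts with
    median lengths and GC of the gained/lost introns (N/A when empty)."""
    la, lb = genome_labels
    calls = [c for c in calls if not expression_validated_only or c.expression_validated]
    gains = {la: 0, lb: 0}
    losses = {la: 0, lb: 0}
    gained_len: dict[str, list[float]] = {la: [], lb: []}
    lost_len: dict[str, list[float]] = {la: [], lb: []}
    gained_gc: dict[str, list[float]] = {la: [], lb: []}
    lost_gc: dict[str, list[float]] = {la: [], lb: []}
    n_cons = n_amb = n_anc = 0
    for c in calls:
        if c.call == "gain_a":
            gains[la] += 1
            if c.length_a is not None:
                gained_len[la].append(c.length_a)
            if c.gc_a is not None:
                gained_gc[la].append(c.gc_a)
        elif c.call == "gain_b":
            gains[lb] += 1
            if c.length_b is not None:
                gained_len[lb].append(c.length_b)
            if c.gc_b is not None:
                gained_gc[lb].append(c.gc_b)
        elif c.call == "loss_a":
            # the lost intron's length/GC are read from the genome retaining it
            losses[la] += 1
            if c.length_b is not None:
                lost_len[la].append(c.length_b)
            if c.gc_b is not None:
                lost_gc[la].append(c.gc_b)
        elif c.call == "loss_b":
            losses[lb] += 1
            if c.length_a is not None:
                lost_len[lb].append(c.length_a)
            if c.gc_a is not None:
                lost_gc[lb].append(c.gc_a)
        elif c.call == "conserved":
            n_cons += 1
        elif c.call == "ambiguous_pulex_edge":
            n_amb += 1
        elif c.call == "ancestral_absence":
            n_anc += 1
    return IntronEventSummary(
        n_sites=len(calls),
        gains=gains,
        losses=losses,
        median_gained_bp={k: _median_or_none(v) for k, v in gained_len.items()},
        median_lost_bp={k: _median_or_none(v) for k, v in lost_len.items()},
        gc_gained={k: _median_or_none(v) for k, v in gained_gc.items()},
        gc_lost={k: _median_or_none(v) for k, v in lost_gc.items()},
        n_conserved=n_cons,
        n_ambiguous=n_amb,
        n_ancestral_absence=n_anc,
    )


def sites_tsv(calls: Iterable[IntronSiteCall]) -> str:
    hdr = "pair\tcodon_index\tphase\tin_a\tin_b\tin_outgroup\tcall\tlen_a\tlen_b\tgc_a\tgc_b\tvalidated"
    rows = [hdr]
    na = lambda v, f="{}": "NA" if v is None else f.format(v)
    for c in calls:
        rows.append(
            f"{c.pair_id}\t{c.codon_index}\t{c.phase}\t{int(c.presence[0])}\t"
            f"{int(c.presence[1])}\t{int(c.presence[2])}\t{c.call}\t"
            f"{na(c.length_a)}\t{na(c.length_b)}\t{na(c.gc_a, '{:.3f}')}\t"
            f"{na(c.gc_b, '{:.3f}')}\t{int(c.expression_validated)}"
        )
    return "\n".join(rows) + "\n"


def summary_tsv(s: IntronEventSummary, genome_labels: tuple[str, str]) -> str:
    la, lb = genome_labels
    na = lambda v: "N/A" if v is None else (f"{v:.0f}" if isinstance(v, float) else str(v))
    rows = [
        f"metric\t{la}\t{lb}",
        f"intron_gains\t{s.gains[la]}\t{s.gains[lb]}",
        f"intron_losses\t{s.losses[la]}\t{s.losses[lb]}",
        f"median_gained_intron_bp\t{na(s.median_gained_bp[la])}\t{na(s.median_gained_bp[lb])}",
        f"median_lost_intron_bp\t{na(s.median_lost_bp[la])}\t{na(s.median_lost_bp[lb])}",
        f"gc_gained_intron\t{'N/A' if s.gc_gained[la] is None else f'{s.gc_gained[la]:.2f}'}\t"
        f"{'N/A' if s.gc_gained[lb] is None else f'{s.gc_gained[lb]:.2f}'}",
        f"gc_lost_intron\t{'N/A' if s.gc_lost[la] is None else f'{s.gc_lost[la]:.2f}'}\t"
        f"{'N/A' if s.gc_lost[lb] is None else f'{s.gc_lost[lb]:.2f}'}",
    ]
    return "\n".join(rows) + "\n"
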