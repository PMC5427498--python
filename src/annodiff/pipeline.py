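"""End-to-end audit orchestration.

``run_audit`` ties the stages together for a pair of annotated genomes and
an optional outgroup: proteome extraction, reciprocal-best-hit orthology
and clustering, orphan classification, split/merge detection, masked-codon
Ka/Ks per ortholog pair, identity summaries, the outgroup relative-rate
contrast, intron site mapping with Dollo polarization, and paralog ageing.
The command-line interface wraps these functions.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import align as al
from . import divergence as dv
from . import genemodel_audit as gma
from . import introns as intr
from . import orthology as orth
from . import seqio
from .seqio import AnnotatedGenome


@dataclass
class AuditConfig:
    """Thresholds for the audit stages (study defaults)."""

    homology_threshold: float = orth.DEFAULT_HOMOLOGY_THRESHOLD
    kmer_k: int = 5
    kmer_min_shared: int = 2
    mask_window_bp: int = 15
    mask_min_identity: float = 0.4
    footprint_overlap_max: float = 0.2
    flank_aa: int = 20
    flank_identity_floor: float = 0.6
    identity_min_alignment_bp: int = 300
    paralog_bin_width: float = 0.1


@dataclass
class PairEstimate:
    gene_a: str
    gene_b: str
    alignment: al.ProteinAlignment
    estimate: dv.KaKsEstimate

    @property
    def identity(self) -> float:
        return self.alignment.identity


@dataclass
class AuditResult:
    labels: tuple[str, str]
    graph: orth.OrthologyGraph
    category: dict[str, str]
    ortholog_pairs: list[PairEstimate]
    identity_summary: dv.IdentitySummary | None
    splits_in_a: list[orth.SplitMergeEvent]
    splits_in_b: list[orth.SplitMergeEvent]
    relative_rate: dv.RelativeRateResult | None
    intron_calls: list[intr.IntronSiteCall]
    intron_summary: intr.IntronEventSummary | None
    paralog_ages: dict[str, orth.ParalogAgeDistribution]
    audit_a: gma.AuditSummary
    audit_b: gma.AuditSummary
    skipped_stages: list[str] = field(default_factory=list)

    def mean_ortholog_ks(self) -> float | None:
        vals = [p.estimate.Ks for p in self.ortholog_pairs if p.estimate.Ks is not None]
        return float(np.mean(vals)) if vals else None

    def mean_ortholog_ka(self) -> float | None:
        vals = [p.estimate.Ka for p in self.ortholog_pairs if p.estimate.Ka is not None]
        return float(np.mean(vals)) if vals else None

    def median_omega(self) -> float | None:
        vals = [p.estimate.omega for p in self.ortholog_pairs if p.estimate.omega is not None]
        return float(np.median(vals)) if vals else None


def coding_sequences(genome: AnnotatedGenome) -> tuple[dict[str, str], dict[str, str]]:
    """(proteome, stop-trimmed CDS) for every translatable gene.

    Internal stops are retained in the proteins (the audit needs them); the
    terminal stop codon is stripped so CDS length is 3x protein length.
    """
    prots: dict[str, str] = {}
    cdss: dict[str, str] = {}
    for g in genome.genes:
        cds = seqio.extract_cds(genome, g.gene_id)
        usable = cds[: len(cds) - len(cds) % 3]
        if len(usable) < 6:
            continue
        prot = seqio.translate(usable)
        if prot.endswith("*"):
            prot = prot[:-1]
        if not prot:
            continue
        prots[g.gene_id] = prot
        cdss[g.gene_id] = usable[: 3 * len(prot)]
    return prots, cdss


def masked_kaks(
    prot_a: str, prot_b: str, cds_a: str, cds_b: str,
    cfg: AuditConfig, id_a: str = "", id_b: str = "",
) -> PairEstimate:
    pa = al.global_align_protein(prot_a, prot_b, id_a=id_a, id_b=id_b)
    ca = al.codon_backtranslate(pa, cds_a, cds_b)
    ca = al.mask_low_quality_windows(ca, cfg.mask_window_bp, cfg.mask_min_identity)
    return PairEstimate(id_a, id_b, pa, dv.kaks(ca))


def run_audit(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    outgroup: AnnotatedGenome | None = None,
    expression_a: Mapping[str, bool] | None = None,
    expression_b: Mapping[str, bool] | None = None,
    config: AuditConfig | None = None,
) -> AuditResult:
    """Run the comparative audit; outgroup-dependent stages are skipped
    (explicitly, in ``skipped_stages``) when no outgroup is supplied."""
    cfg = config or AuditConfig()
    la, lb = genome_a.label, genome_b.label
    if la == lb:
        la, lb = f"{la}#1", f"{lb}#2"
    prot_a, cds_a = coding_sequences(genome_a)
    prot_b, cds_b = coding_sequences(genome_b)
    skipped: list[str] = []

    rbh, best_ab, best_ba = orth.reciprocal_best_hits_full(
        prot_a, prot_b, cfg.homology_threshold, cfg.kmer_k, cfg.kmer_min_shared
    )
    within = {
        la: orth.score_hits(prot_a, prot_a, cfg.kmer_k, cfg.kmer_min_shared, cfg.homology_threshold),
        lb: orth.score_hits(prot_b, prot_b, cfg.kmer_k, cfg.kmer_min_shared, cfg.homology_threshold),
    }
    best_between = {
        **{orth.qualify(la, q): orth.qualify(lb, h.subject_id) for q, h in best_ab.items()},
        **{orth.qualify(lb, q): orth.qualify(la, h.subject_id) for q, h in best_ba.items()},
    }
    graph = orth.build_clusters(rbh, within, (la, lb), best_between)

    prot_o: dict[str, str] = {}
    cds_o: dict[str, str] = {}
    references: dict[str, Mapping[str, str]] = {}
    if outgroup is not None:
        prot_o, cds_o = coding_sequences(outgroup)
        references["outgroup"] = prot_o
    category = orth.classify_orphans(
        graph, {la: prot_a, lb: prot_b}, references, cfg.homology_threshold
    )

    pair_aln: dict[tuple[str, str], PairEstimate] = {}
    ortholog_pairs = []
    for a, b, _score in rbh:
        pe = masked_kaks(prot_a[a], prot_b[b], cds_a[a], cds_b[b], cfg, a, b)
        pair_aln[(a, b)] = pe
        ortholog_pairs.append(pe)

    try:
        identity_summary = dv.summarize_identity(
            [p.alignment for p in ortholog_pairs], cfg.identity_min_alignment_bp
        )
    except ValueError:
        identity_summary = None

    splits_in_b = orth.detect_split_merge(
        prot_a, prot_b, la, lb, cfg.footprint_overlap_max, cfg.homology_threshold
    )
    splits_in_a = orth.detect_split_merge(
        prot_b, prot_a, lb, la, cfg.footprint_overlap_max, cfg.homology_threshold
    )

    relrate = None
    intron_calls: list[intr.IntronSiteCall] = []
    intron_summary = None
    if outgroup is None:
        skipped += ["relative_rate (no outgroup)", "introns (no outgroup)"]
    else:
        rbh_ao = dict(
            (a, o) for a, o, _ in orth.reciprocal_best_hits(
                prot_a, prot_o, cfg.homology_threshold, cfg.kmer_k, cfg.kmer_min_shared
            )
        )
        rbh_bo = dict(
            (b, o) for b, o, _ in orth.reciprocal_best_hits(
                prot_b, prot_o, cfg.homology_threshold, cfg.kmer_k, cfg.kmer_min_shared
            )
        )
        triplets = []  # (a, b, o)
        for a, b, _score in rbh:
            o = rbh_ao.get(a)
            if o is not None and rbh_bo.get(b) == o:
                triplets.append((a, b, o))
        per_gene = []
        ao_estimates: dict[str, PairEstimate] = {}
        for a, b, o in triplets:
            est_ao = masked_kaks(prot_a[a], prot_o[o], cds_a[a], cds_o[o], cfg, a, o)
            est_bo = masked_kaks(prot_b[b], prot_o[o], cds_b[b], cds_o[o], cfg, b, o)
            ao_estimates[a] = est_ao
            per_gene.append((f"{a}|{b}", est_ao.estimate, est_bo.estimate))
        if per_gene:
            try:
                relrate = dv.relative_rate(per_gene)
            except ValueError:
                relrate = None
                skipped.append("relative_rate (no defined estimates)")
        else:
            skipped.append("relative_rate (no triplets)")

        stats = intr.SiteMapStats()
        for a, b, o in triplets:
            calls = intr.map_intron_sites(
                genome_a, genome_a.gene(a),
                genome_b, genome_b.gene(b),
                outgroup, outgroup.gene(o),
                pair_aln[(a, b)].alignment,
                ao_estimates[a].alignment,
                flank_aa=cfg.flank_aa,
                flank_identity_floor=cfg.flank_identity_floor,
                expression_a=expression_a,
                expression_b=expression_b,
                stats=stats,
            )
            intron_calls.extend(calls)
        intron_summary = intr.summarize_events(intron_calls, (la, lb))

    # paralog ageing from within-genome cluster mates
    paralog_ages: dict[str, orth.ParalogAgeDistribution] = {}
    benchmark = None
    ks_vals = [p.estimate.Ks for p in ortholog_pairs if p.estimate.Ks is not None]
    if ks_vals:
        benchmark = float(np.mean(ks_vals))
    for label, prots, cdss in ((la, prot_a, cds_a), (lb, prot_b, cds_b)):
        pairwise_ks: dict[frozenset[str], float] = {}
        for cluster in graph.clusters:
            members = sorted(
                g.split(":", 1)[1] for g in cluster if g.startswith(f"{label}:")
            )
            for i, x in enumerate(members):
                for y in members[i + 1 :]:
                    if x not in prots or y not in prots:
                        continue
                    pe = masked_kaks(prots[x], prots[y], cdss[x], cdss[y], cfg, x, y)
                    if pe.estimate.Ks is not None:
                        pairwise_ks[
                            frozenset((orth.qualify(label, x), orth.qualify(label, y)))
                        ] = pe.estimate.Ks
        paralog_ages[label] = orth.paralog_age_distribution(
            graph, pairwise_ks, label, benchmark, cfg.paralog_bin_width
        )

    return AuditResult(
        labels=(la, lb),
        graph=graph,
        category=category,
        ortholog_pairs=ortholog_pairs,
        identity_summary=identity_summary,
        splits_in_a=splits_in_a,
        splits_in_b=splits_in_b,
        relative_rate=relrate,
        intron_calls=intron_calls,
        intron_summary=intron_summary,
        paralog_ages=paralog_ages,
        audit_a=gma.audit_summary(genome_a),
        audit_b=gma.audit_summary(genome_b),
        skipped_stages=skipped,
    )


# ---------------------------------------------------------------------------
# report rendering


def render_report(result: AuditResult) -> str:
    """Human-readable summary of the key scalars of an audit run."""
    la, lb = result.labels
    lines = [f"# Comparative annotation audit: {la} vs {lb}", ""]
    lines.append(f"genes: {result.audit_a.n_genes} ({la}) vs {result.audit_b.n_genes} ({lb})")
    counts_a = orth.category_counts(result.category, la)
    counts_b = orth.category_counts(result.category, lb)
    lines.append(f"1:1 ortholog pairs: {len(result.graph.rbh_pairs)}")
    for lab, c in ((la, counts_a), (lb, counts_b)):
        lines.append(
            f"{lab}: one_to_one={c['one_to_one']} inparalog={c['inparalog']} "
            f"pulex_specific={c['pulex_specific']} orphan={c['lineage_specific']} "
            f"unassigned={c['unassigned']}"
        )
    if result.identity_summary:
        s = result.identity_summary
        lines.append(
            f"protein identity: mean={s.mean_identity:.4f} "
            f"fraction_identical={s.fraction_identical:.3f} (n={s.n_pairs})"
        )
    ks, ka, om = result.mean_ortholog_ks(), result.mean_ortholog_ka(), result.median_omega()
    if ks is not None:
        om_txt = "N/A" if om is None else f"{om:.3f}"
        lines.append(f"ortholog divergence: mean Ks={ks:.4f} mean Ka={ka:.4f} median omega={om_txt}")
    lines.append(
        f"split events: {len(result.splits_in_a)} in {la}, {len(result.splits_in_b)} in {lb}"
    )
    for lab in (la, lb):
        h = result.audit_a if lab == la else result.audit_b
        lines.append(
            f"hygiene {lab}: missing_start={h.missing_start} missing_stop={h.missing_stop} "
            f"missing_both={h.missing_both} union={h.missing_start_or_stop} "
            f"premature_stop={h.premature_stop}"
        )
    if result.relative_rate is not None:
        r = result.relative_rate
        lines.append(
            f"relative rate ({lb} minus {la} vs outgroup): "
            f"dKs={r.mean_delta_ks:.4f}+/-{r.se_delta_ks:.4f} "
            f"dKa={r.mean_delta_ka:.4f}+/-{r.se_delta_ka:.4f} (n={len(r.genes)})"
        )
    if result.intron_summary is not None:
        s = result.intron_summary
        excess = s.percent_excess_gains(lb, la)
        lines.append(
            f"intron events: gains {s.gains[la]} ({la}) / {s.gains[lb]} ({lb}), "
            f"losses {s.losses[la]} / {s.losses[lb]}, "
            f"excess gains in {lb}: "
            + ("N/A" if excess is None else f"{excess:.0f}%")
        )
    for lab, dist in result.paralog_ages.items():
        if dist.records:
            frac = dist.fraction_younger_than_benchmark()
            lines.append(
                f"paralogs {lab}: n={len(dist.records)} mode_bin={dist.mode_bin} "
                f"younger_than_benchmark={'N/A' if frac is None else f'{frac:.2f}'}"
            )
    for s in result.skipped_stages:
        lines.append(f"SKIPPED: {s}")
    return "\n".join(lines) + "\n"


def manifest(files: Mapping[str, Path], seed: int | None, config: AuditConfig | None = None) -> str:
    """Structured run manifest with per-file SHA256 hashes."""
    entries = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in sorted(files.items())
    }
    doc = {
        "tool": "annodiff 0.1.0",
        "seed": seed,
        "config": None if config is None else vars(config),
        "files": entries,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"
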