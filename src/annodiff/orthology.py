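"""Orthology inference and annotation-artifact detection.

Reciprocal-best-hit (RBH) ortholog pairing over proteomes, single-linkage
cluster building with an in-paralog rule, orphan classification against
reference proteomes, split/merge event detection from alignment footprints,
and paralog Ks age distributions.

In place of database-search e-values, homology calls use a normalized
alignment score ``score / min(self_score_a, self_score_b)``; at the default
threshold shuffled unrelated proteins essentially never qualify, standing in
for the e-value cutoff of 0.01 used with BLAST searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import (
    HitCandidate,
    ProteinAlignment,
    global_align_protein,
    kmer_candidates,
    local_align_score,
    local_footprint,
)

DEFAULT_HOMOLOGY_THRESHOLD = 0.2  # normalized-score surrogate for e-value 0.01
CATEGORIES = ("one_to_one", "inparalog", "pulex_specific", "lineage_specific", "unassigned")


@dataclass
class Hit:
    query_id: str
    subject_id: str
    score: float
    normalized_score: float


@dataclass
class OrthologyGraph:
    rbh_pairs: list[tuple[str, str, float]]
    clusters: list[set[str]]  # gene ids prefixed "label:gene"
    category: dict[str, str]  # per prefixed gene id
    genome_labels: tuple[str, str]

    def cluster_of(self, gene: str) -> set[str] | None:
        for c in self.clusters:
            if gene in c:
                return c
        return None


def qualify(label: str, gene_id: str) -> str:
    return f"{label}:{gene_id}"


# ---------------------------------------------------------------------------
# scoring


class _ScoreCache:
    """Self-score cache for normalized-score computation."""

    def __init__(self) -> None:
        self._self: dict[int, float] = {}

    def self_score(self, seq: str) -> float:
        key = id(seq)
        if key not in self._self:
            self._self[key] = local_align_score(seq, seq)
        return self._self[key]


def score_hits(
    query_set: Mapping[str, str],
    subject_set: Mapping[str, str],
    k: int = 5,
    min_shared: int = 2,
    min_normalized: float = DEFAULT_HOMOLOGY_THRESHOLD,
) -> list[Hit]:
    """Significant local-alignment hits after the k-mer prefilter.

    A hit qualifies when its Smith-Waterman score is at least
    ``min_normalized`` of the smaller self-alignment score of the pair;
    local scoring keeps gene fragments detectable against full-length
    homologs, mirroring database-search behaviour.
    """
    cache = _ScoreCache()
    hits = []
    for cand in kmer_candidates(query_set, subject_set, k=k, min_shared=min_shared):
        q, s = query_set[cand.query_id], subject_set[cand.subject_id]
        raw = local_align_score(q, s)
        denom = min(cache.self_score(q), cache.self_score(s))
        norm = raw / denom if denom > 0 else 0.0
        if norm >= min_normalized:
            hits.append(Hit(cand.query_id, cand.subject_id, raw, norm))
    return hits


def _better(h: Hit, cur: Hit) -> bool:
    if h.score != cur.score:
        return h.score > cur.score
    if h.normalized_score != cur.normalized_score:
        return h.normalized_score > cur.normalized_score
    return h.subject_id < cur.subject_id


def best_hits(hits: Iterable[Hit]) -> dict[str, Hit]:
    """Best hit per query; ties broken by score, then normalized score,
    then lexicographically smallest subject id (deterministic)."""
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _better(h, cur):
            best[h.query_id] = h
    return best


def reciprocal_best_hits_full(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_normalized: float = DEFAULT_HOMOLOGY_THRESHOLD,
    k: int = 5,
    min_shared: int = 2,
) -> tuple[list[tuple[str, str, float]], dict[str, Hit], dict[str, Hit]]:
    """RBH pairs plus the directional best-hit maps they derive from."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ab = best_hits(score_hits(proteome_a, proteome_b, k, min_shared, min_normalized))
    ba = best_hits(score_hits(proteome_b, proteome_a, k, min_shared, min_normalized))
    pairs = []
    for a, hit in sorted(ab.items()):
        back = ba.get(hit.subject_id)
        if back is not None and back.subject_id == a:
            pairs.append((a, hit.subject_id, hit.score))
    return pairs, ab, ba


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_normalized: float = DEFAULT_HOMOLOGY_THRESHOLD,
    k: int = 5,
    min_shared: int = 2,
) -> list[tuple[str, str, float]]:
    """RBH pairs (a, b, score): b is a's best hit and a is b's."""
    return reciprocal_best_hits_full(proteome_a, proteome_b, min_normalized, k, min_shared)[0]


# ---------------------------------------------------------------------------
# clusters and categories


def build_clusters(
    rbh_pairs: Sequence[tuple[str, str, float]],
    within_hits: Mapping[str, Sequence[Hit]],
    genome_labels: tuple[str, str],
    best_between: Mapping[str, str] | None = None,
) -> OrthologyGraph:
    """Single-linkage closure over RBH edges plus in-paralog edges.

    A within-genome hit (x, y) joins the cluster when its score is at least
    an anchored gene's weakest between-genome RBH score (the in-paralog
    notion: duplicates closer to each other than either is to anything in
    the other genome), or — when ``best_between`` maps qualified gene ids to
    their best cross-genome hit — when both genes converge on the same
    cross-genome gene (co-ortholog convergence, which also captures older
    duplicates that still share one ortholog).
    """
    la, lb = genome_labels
    rbh_score: dict[str, float] = {}
    edges: list[tuple[str, str]] = []
    for a, b, score in rbh_pairs:
        qa, qb = qualify(la, a), qualify(lb, b)
        edges.append((qa, qb))
        rbh_score[qa] = min(rbh_score.get(qa, math.inf), score)
        rbh_score[qb] = min(rbh_score.get(qb, math.inf), score)
    for label, hits in within_hits.items():
        for h in hits:
            if h.query_id == h.subject_id:
                continue
            qx, qy = qualify(label, h.query_id), qualify(label, h.subject_id)
            anchor = [g for g in (qx, qy) if g in rbh_score]
            joined = bool(anchor) and h.score >= min(rbh_score[g] for g in anchor)
            if not joined and best_between is not None:
                bx, by = best_between.get(qx), best_between.get(qy)
                joined = bx is not None and bx == by
            if joined:
                edges.append((qx, qy))

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for x, y in edges:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry
    groups: dict[str, set[str]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    clusters = sorted(groups.values(), key=lambda c: sorted(c)[0])

    category: dict[str, str] = {}
    in_rbh = {qualify(la, a) for a, _, _ in rbh_pairs} | {
        qualify(lb, b) for _, b, _ in rbh_pairs
    }
    for c in clusters:
        for g in c:
            category[g] = "one_to_one" if g in in_rbh else "inparalog"
    return OrthologyGraph(list(rbh_pairs), clusters, category, genome_labels)


def classify_orphans(
    graph: OrthologyGraph,
    proteomes: Mapping[str, Mapping[str, str]],
    reference_proteomes: Mapping[str, Mapping[str, str]],
    min_normalized: float = DEFAULT_HOMOLOGY_THRESHOLD,
) -> dict[str, str]:
    """Category per gene with precedence reference > cross-genome > orphan.

    Genes already paired or clustered keep their structural label
    (one_to_one / inparalog). Remaining genes with a reference-proteome hit
    are ``unassigned`` (homologous outside the pair but unclustered), genes
    whose only homology is to the companion genome are ``pulex_specific``,
    and genes with no hit anywhere are ``lineage_specific`` orphans.
    """
    la, lb = graph.genome_labels
    category = dict(graph.category)

    ref_hit: set[str] = set()
    for label, prot in proteomes.items():
        leftovers = {
            gid: seq
            for gid, seq in prot.items()
            if qualify(label, gid) not in category
        }
        if not leftovers:
            continue
        for ref in reference_proteomes.values():
            hits = score_hits(leftovers, ref, min_normalized=min_normalized)
            ref_hit |= {qualify(label, h.query_id) for h in hits}
        other = proteomes[lb if label == la else la]
        cross = score_hits(
            {g: s for g, s in leftovers.items() if qualify(label, g) not in ref_hit},
            other,
            min_normalized=min_normalized,
        )
        cross_hit = {qualify(label, h.query_id) for h in cross}
        for gid in leftovers:
            q = qualify(label, gid)
            if q in ref_hit:
                category[q] = "unassigned"
            elif q in cross_hit:
                category[q] = "pulex_specific"
            else:
                category[q] = "lineage_specific"
    return category


def category_counts(category: Mapping[str, str], label: str) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    prefix = f"{label}:"
    for g, c in category.items():
        if g.startswith(prefix):
            counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# orphan feature report


@dataclass
class GeneFeatures:
    gene_id: str
    category: str
    n_introns: int
    cds_length: int
    gc_fraction: float
    premature_stop: bool
    expression_support: bool | None
    depth: float | None


@dataclass
class FeatureContrast:
    """Group means with standard errors for orphans vs 1:1 orthologs."""

    group_stats: dict[str, dict[str, tuple[float, float]]]  # group -> feature -> (mean, se)
    records: list[GeneFeatures]


def _mean_se(vals: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(vals, dtype=float)
    if len(arr) == 0:
        return float("nan"), float("nan")
    se = float(np.std(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return float(arr.mean()), se


def orphan_feature_report(
    genome,
    category: Mapping[str, str],
    label: str,
    expression: Mapping[str, bool] | None = None,
    depth: Mapping[str, float] | None = None,
) -> FeatureContrast:
    """Structural features of orphans contrasted with 1:1 orthologs."""
    from . import genemodel_audit, seqio

    records = []
    for g in genome.genes:
        q = qualify(label, g.gene_id)
        cat = category.get(q, "unassigned")
        audit = genemodel_audit.audit_gene(genome, g.gene_id)
        records.append(
            GeneFeatures(
                gene_id=g.gene_id,
                category=cat,
                n_introns=audit.n_introns,
                cds_length=audit.cds_length,
                gc_fraction=audit.gc_fraction,
                premature_stop=audit.has_premature_stop,
                expression_support=None if expression is None else expression.get(g.gene_id),
                depth=None if depth is None else depth.get(g.gene_id),
            )
        )
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for group, pick in (
        ("one_to_one", lambda r: r.category == "one_to_one"),
        ("orphan", lambda r: r.category == "lineage_specific"),
    ):
        rows = [r for r in records if pick(r)]
        stats[group] = {
            "n_introns": _mean_se([r.n_introns for r in rows]),
            "cds_length": _mean_se([r.cds_length for r in rows]),
            "gc_fraction": _mean_se([r.gc_fraction for r in rows]),
            "premature_stop": _mean_se([float(r.premature_stop) for r in rows]),
        }
        if rows and rows[0].expression_support is not None:
            stats[group]["expression_support"] = _mean_se(
                [float(bool(r.expression_support)) for r in rows]
            )
    return FeatureContrast(stats, records)


# ---------------------------------------------------------------------------
# split / merge detection


@dataclass
class SplitMergeEvent:
    merged_gene: str  # qualified id in genome X
    fragment_genes: list[str]  # >= 2 qualified ids in genome Y
    footprints: list[tuple[int, int]]  # residue intervals on merged protein


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return ov / min(a[1] - a[0] + 1, b[1] - b[0] + 1)


def detect_split_merge(
    proteome_x: Mapping[str, str],
    proteome_y: Mapping[str, str],
    label_x: str,
    label_y: str,
    footprint_overlap_max: float = 0.2,
    min_normalized: float = DEFAULT_HOMOLOGY_THRESHOLD,
) -> list[SplitMergeEvent]:
    """Genes of Y whose best hits converge on one X gene with disjoint
    footprints: a split in Y's annotation (equivalently a merge in X).

    An event requires >= 2 Y genes sharing a best hit and pairwise footprint
    overlap at most ``footprint_overlap_max`` of the shorter footprint.
    """
    bh = best_hits(score_hits(proteome_y, proteome_x, min_normalized=min_normalized))
    by_target: dict[str, list[str]] = {}
    for yid, hit in bh.items():
        by_target.setdefault(hit.subject_id, []).append(yid)
    events = []
    for xid, yids in sorted(by_target.items()):
        if len(yids) < 2:
            continue
        fps = {}
        for yid in yids:
            fp = local_footprint(proteome_x[xid], proteome_y[yid])
            if fp is not None:
                fps[yid] = fp
        frag_ids = sorted(fps)
        if len(frag_ids) < 2:
            continue
        ok = all(
            _interval_overlap(fps[u], fps[v]) <= footprint_overlap_max
            for i, u in enumerate(frag_ids)
            for v in frag_ids[i + 1 :]
        )
        if ok:
            events.append(
                SplitMergeEvent(
                    merged_gene=qualify(label_x, xid),
                    fragment_genes=[qualify(label_y, y) for y in frag_ids],
                    footprints=[fps[y] for y in frag_ids],
                )
            )
    return events


# ---------------------------------------------------------------------------
# paralog ageing


@dataclass
class ParalogAgeRecord:
    gene: str
    cluster_index: int
    mean_ks: float
    age_bin: int


@dataclass
class ParalogAgeDistribution:
    records: list[ParalogAgeRecord]
    bin_width: float
    histogram: dict[int, int]
    benchmark_ks: float | None

    @property
    def mode_bin(self) -> tuple[float, float] | None:
        if not self.histogram:
            return None
        b = max(sorted(self.histogram), key=lambda k: self.histogram[k])
        return b * self.bin_width, (b + 1) * self.bin_width

    def fraction_younger_than_benchmark(self) -> float | None:
        if self.benchmark_ks is None or not self.records:
            return None
        return float(
            np.mean([r.mean_ks < self.benchmark_ks for r in self.records])
        )


def paralog_age_distribution(
    graph: OrthologyGraph,
    pairwise_ks: Mapping[frozenset[str], float],
    label: str,
    ortholog_benchmark: float | None = None,
    bin_width: float = 0.1,
) -> ParalogAgeDistribution:
    """Per-paralog mean Ks against same-genome cluster mates, binned.

    ``pairwise_ks`` maps within-genome qualified gene-id pairs to Ks values
    computed from masked codon alignments. Genes whose every comparison is
    undefined are skipped. The benchmark is the mean 1:1 ortholog Ks from
    the same run, plotted as the young/old boundary.
    """
    records = []
    prefix = f"{label}:"
    for ci, cluster in enumerate(graph.clusters):
        members = sorted(g for g in cluster if g.startswith(prefix))
        if len(members) < 2:
            continue
        for g in members:
            vals = [
                pairwise_ks[frozenset((g, h))]
                for h in members
                if h != g and frozenset((g, h)) in pairwise_ks
                and pairwise_ks[frozenset((g, h))] is not None
            ]
            if not vals:
                continue
            mean_ks = float(np.mean(vals))
            records.append(
                ParalogAgeRecord(g, ci, mean_ks, int(mean_ks // bin_width))
            )
    hist: dict[int, int] = {}
    for r in records:
        hist[r.age_bin] = hist.get(r.age_bin, 0) + 1
    return ParalogAgeDistribution(records, bin_width, hist, ortholog_benchmark)
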