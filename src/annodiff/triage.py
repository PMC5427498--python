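"""Scaffold contamination triage.

Combines a precomputed taxonomy-hit table with breadth of coverage from two
independent read sets (a paired-end library and single-sperm reads). A
scaffold with a qualifying bacterial hit is dropped outright; otherwise it
is kept when PE breadth exceeds 0.80 and sperm breadth exceeds 0.30, with a
review annotation for the 0.30-0.80 sperm band (kept after manual-check in
the source protocol), and dropped for low support below that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import AnnotatedGenome

logger = logging.getLogger(__name__)

DECISIONS = ("keep", "keep_review", "drop_bacterial", "drop_low_support")


@dataclass(frozen=True)
class TriageThresholds:
    pe_breadth_min: float = 0.80
    sperm_breadth_min: float = 0.30
    sperm_review_max: float = 0.80
    taxonomy_evalue_max: float = 1e-5
    taxonomy_identity_min: float = 0.95


@dataclass
class TriageDecision:
    scaffold_id: str
    pe_breadth: float
    sperm_breadth: float
    taxonomy_flag: str  # none | bacterial_hit
    decision: str

    @property
    def kept(self) -> bool:
        return self.decision in ("keep", "keep_review")


def breadth(track, scaffold_length: int, min_depth: int = 1) -> float:
    """Fraction of scaffold positions covered at >= ``min_depth``.

    ``track`` is either a per-base depth array of length
    ``scaffold_length`` or a sparse mapping position (1-based) -> depth;
    positions beyond the scaffold length are an error.
    """
    if scaffold_length < 1:
        raise ValueError("scaffold_length must be >= 1")
    if track is None:
        return 0.0
    if isinstance(track, Mapping):
        covered = 0
        for pos, depth in track.items():
            if pos < 1 or pos > scaffold_length:
                raise ValueError(f"depth position {pos} beyond scaffold length {scaffold_length}")
            if depth >= min_depth:
                covered += 1
        return covered / scaffold_length
    arr = np.asarray(track)
    if arr.size == 0:
        return 0.0
    if arr.size > scaffold_length:
        raise ValueError("depth track longer than scaffold")
    return float(np.count_nonzero(arr >= min_depth)) / scaffold_length


def bacterial_flag(
    taxonomy_row: Mapping | None, thresholds: TriageThresholds = TriageThresholds()
) -> str:
    """Taxonomy verdict for one scaffold from a best-hit table row with
    ``taxon``, ``evalue`` and ``identity`` fields."""
    if taxonomy_row is None:
        return "none"
    taxon = str(taxonomy_row.get("taxon", "")).lower()
    if (
        "bacter" in taxon
        and float(taxonomy_row.get("evalue", 1.0)) < thresholds.taxonomy_evalue_max
        and float(taxonomy_row.get("identity", 0.0)) > thresholds.taxonomy_identity_min
    ):
        return "bacterial_hit"
    return "none"


def triage_scaffold(
    scaffold_id: str,
    pe_breadth: float,
    sperm_breadth: float,
    taxonomy_flag: str = "none",
    thresholds: TriageThresholds = TriageThresholds(),
) -> TriageDecision:
    """Pure decision rule over the two breadths and the taxonomy flag."""
    for v in (pe_breadth, sperm_breadth):
        if not 0.0 <= v <= 1.0:
            raise ValueError("breadths must lie in [0, 1]")
    if taxonomy_flag == "bacterial_hit":
        decision = "drop_bacterial"
    elif pe_breadth > thresholds.pe_breadth_min and sperm_breadth > thresholds.sperm_breadth_min:
        decision = (
            "keep"
            if sperm_breadth > thresholds.sperm_review_max
            else "keep_review"
        )
    else:
        decision = "drop_low_support"
    return TriageDecision(scaffold_id, pe_breadth, sperm_breadth, taxonomy_flag, decision)


def triage_genome(
    genome: AnnotatedGenome,
    pe_tracks: Mapping[str, object],
    sperm_tracks: Mapping[str, object],
    taxonomy: pd.DataFrame | None = None,
    thresholds: TriageThresholds = TriageThresholds(),
    min_depth: int = 1,
) -> tuple[list[TriageDecision], AnnotatedGenome]:
    """Apply the decision rule per scaffold and return the retained genome.

    Scaffolds with no depth track are treated as breadth 0. The retained
    genome keeps exactly the keep/keep_review scaffolds (and the genes on
    them); idempotent on its own output.
    """
    tax_by_scaffold = {}
    if taxonomy is not None and len(taxonomy):
        tax_by_scaffold = {
            str(r["scaffold"]): r for _, r in taxonomy.iterrows()
        }
    decisions = []
    for sc in genome.scaffolds:
        pe = breadth(pe_tracks.get(sc.id), len(sc), min_depth)
        sperm = breadth(sperm_tracks.get(sc.id), len(sc), min_depth)
        flag = bacterial_flag(tax_by_scaffold.get(sc.id), thresholds)
        decisions.append(triage_scaffold(sc.id, pe, sperm, flag, thresholds))
    kept_ids = {d.scaffold_id for d in decisions if d.kept}
    if not kept_ids:
        logger.warning("triage removed every scaffold of %s", genome.label)
    retained = AnnotatedGenome(
        genome.label,
        [sc for sc in genome.scaffolds if sc.id in kept_ids],
        [g for g in genome.genes if g.scaffold_id in kept_ids],
    ) if kept_ids else AnnotatedGenome(genome.label, [], [])
    return decisions, retained


def read_depth_tsv(path: str | Path) -> dict[str, dict[int, int]]:
    """samtools-depth-style 3-column TSV (scaffold, 1-based position, depth)
    into sparse per-scaffold tracks."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "pos", "depth"])
    out: dict[str, dict[int, int]] = {}
    for sc, sub in df.groupby("scaffold"):
        out[str(sc)] = dict(zip(sub["pos"].astype(int), sub["depth"].astype(int)))
    return out


def decisions_tsv(decisions: Iterable[TriageDecision]) -> str:
    rows = ["scaffold\tpe_breadth\tsperm_breadth\ttaxonomy\tdecision"]
    for d in decisions:
        rows.append(
            f"{d.scaffold_id}\t{d.pe_breadth:.3f}\t{d.sperm_breadth:.3f}\t"
            f"{d.taxonomy_flag}\t{d.decision}"
        )
    return "\n".join(rows) + "\n"
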