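"""Genome I/O and gene-model materialization.

Reads scaffold FASTA plus GFF3 gene models into an :class:`AnnotatedGenome`,
extracts spliced CDS with strand and phase handling, translates with the
standard genetic code, and computes assembly summary statistics (scaffold
counts, N50, gap totals).

Coordinates are GFF3 1-based inclusive throughout; any half-open conversion
is confined to I/O adapters. For multi-transcript genes the transcript with
the longest summed CDS is canonical for all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class GenomeValidationError(ValueError):
    """A gene model violates its structural invariants."""


class GFF3ParseError(ValueError):
    """Malformed GFF3 input."""


@dataclass
class Scaffold:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise GenomeValidationError(f"scaffold {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One gene with its canonical (longest-CDS) transcript.

    ``exons`` and ``cds`` are lists of 1-based inclusive ``(start, end)``
    intervals sorted ascending; ``cds`` intervals additionally carry a phase
    (bases to trim from the 5' end of the first codon of that segment).
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]
    n_transcripts: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.cds:
            raise GenomeValidationError(f"{self.gene_id}: no CDS intervals")
        if not self.exons:
            self.exons = [(s, e) for s, e, _ in self.cds]
        last = 0
        for s, e in self.exons:
            if s > e or s <= last:
                raise GenomeValidationError(
                    f"{self.gene_id}: exons not sorted/disjoint at ({s},{e})"
                )
            last = e
        for s, e, ph in self.cds:
            if s > e:
                raise GenomeValidationError(f"{self.gene_id}: inverted CDS ({s},{e})")
            if ph not in (0, 1, 2):
                raise GenomeValidationError(f"{self.gene_id}: bad phase {ph}")
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise GenomeValidationError(
                    f"{self.gene_id}: CDS ({s},{e}) not contained in any exon"
                )
        if self.cds_length() == 0:
            raise GenomeValidationError(f"{self.gene_id}: zero-length CDS")

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Introns between consecutive CDS segments (1-based inclusive)."""
        out = []
        for (s1, e1, _), (s2, e2, _) in zip(self.cds, self.cds[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class AnnotatedGenome:
    label: str
    scaffolds: list[Scaffold]
    genes: list[GeneModel]
    _scaffold_index: dict[str, Scaffold] = field(default_factory=dict, repr=False)
    _gene_index: dict[str, GeneModel] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._scaffold_index = {s.id: s for s in self.scaffolds}
        if len(self._scaffold_index) != len(self.scaffolds):
            raise GenomeValidationError("duplicate scaffold ids")
        self._gene_index = {g.gene_id: g for g in self.genes}
        if len(self._gene_index) != len(self.genes):
            raise GenomeValidationError("duplicate gene ids")
        for g in self.genes:
            sc = self._scaffold_index.get(g.scaffold_id)
            if sc is None:
                raise GenomeValidationError(
                    f"{g.gene_id}: unknown scaffold {g.scaffold_id!r}"
                )
            if g.span()[1] > len(sc):
                raise GenomeValidationError(
                    f"{g.gene_id}: feature end {g.span()[1]} beyond scaffold "
                    f"{g.scaffold_id} length {len(sc)}"
                )

    def scaffold(self, scaffold_id: str) -> Scaffold:
        return self._scaffold_index[scaffold_id]

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def reindex(self) -> None:
        """Rebuild internal indexes after in-place mutation."""
        self.__post_init__()


@dataclass
class AssemblyStats:
    total_length_bp: int
    n_scaffolds: int
    largest_scaffold_bp: int
    mean_scaffold_bp: float
    n50_length_bp: int
    n50_count: int
    total_gap_bp: int


def normalize_sequence(seq: str, context: str = "") -> str:
    """Uppercase and collapse non-ACGTN ambiguity codes to N."""
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        n_bad = sum(seq.count(b) for b in bad)
        logger.info("normalized %d ambiguous bases to N in %s", n_bad, context or "sequence")
        seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
    return seq


# ---------------------------------------------------------------------------
# reading


def read_genome(fasta_path: str | Path, gff3_path: str | Path, label: str | None = None) -> AnnotatedGenome:
    """Read scaffolds and gene models into an :class:`AnnotatedGenome`.

    For genes with several mRNAs the transcript with the longest summed CDS
    is kept (ties broken by transcript id).
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    scaffolds = [
        Scaffold(rec.id, normalize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted classes on bad lines
        raise GFF3ParseError(f"{gff3_path}: {exc}") from exc

    genes = []
    for f in db.features_of_type("gene"):
        best: tuple[int, str, list, list] | None = None
        for m in db.children(f, featuretype="mRNA"):
            cds = [
                (c.start, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(m, featuretype="CDS", order_by="start")
            ]
            if not cds:
                continue
            exons = [
                (x.start, x.end)
                for x in db.children(m, featuretype="exon", order_by="start")
            ]
            length = sum(e - s + 1 for s, e, _ in cds)
            key = (-length, m.id)
            if best is None or key < best[:2]:
                best = (key[0], key[1], exons, cds)
        n_mrna = len(list(db.children(f, featuretype="mRNA")))
        if best is None:
            continue  # gene without CDS: not a protein-coding model
        genes.append(
            GeneModel(
                gene_id=f.id,
                scaffold_id=f.seqid,
                strand=f.strand,
                exons=best[2],
                cds=best[3],
                n_transcripts=max(n_mrna, 1),
            )
        )
    return AnnotatedGenome(label or fasta_path.stem, scaffolds, genes)


# ---------------------------------------------------------------------------
# writing


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path, gff3_path: str | Path) -> None:
    """Write FASTA (wrapped at 60 columns) and gene/mRNA/exon/CDS GFF3."""
    with open(fasta_path, "w") as fh:
        for sc in genome.scaffolds:
            fh.write(f">{sc.id}\n")
            for i in range(0, len(sc.sequence), 60):
                fh.write(sc.sequence[i : i + 60] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            s, e = g.span()
            base = f"{g.scaffold_id}\tannodiff\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{s}\t{e}{tail}.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{s}\t{e}{tail}.\tID={tid};Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(f"{base}exon\t{xs}\t{xe}{tail}.\tID={tid}.e{i};Parent={tid}\n")
            for i, (cs, ce, ph) in enumerate(g.cds, 1):
                fh.write(f"{base}CDS\t{cs}\t{ce}{tail}{ph}\tID={tid}.c{i};Parent={tid}\n")


# ---------------------------------------------------------------------------
# sequence extraction


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(genome: AnnotatedGenome, gene_id: str) -> str:
    """Spliced CDS in translation order (minus strand reverse-complemented).

    The phase of the first segment in translation order trims incomplete
    leading bases, so the returned string starts on a codon boundary.
    """
    g = genome.gene(gene_id)
    seq = genome.scaffold(g.scaffold_id).sequence
    parts = [seq[s - 1 : e] for s, e, _ in g.cds]
    if g.strand == "+":
        cds = "".join(parts)
        phase = g.cds[0][2]
    else:
        cds = "".join(reverse_complement(p) for p in reversed(parts))
        phase = g.cds[-1][2]
    cds = cds[phase:]
    if len(cds) % 3 != 0:
        logger.debug("%s: CDS length %d not a codon multiple", gene_id, len(cds))
    return cds


class PartialCodonError(ValueError):
    """CDS length is not a multiple of three."""


def translate(cds: str, strip_terminal_stop: bool = False, allow_partial: bool = False) -> str:
    """Translate a CDS; internal stops are retained as ``*``.

    Ambiguous codons translate to ``X``. A trailing partial codon raises
    :class:`PartialCodonError` unless ``allow_partial`` (then it is dropped).
    """
    if len(cds) < 3:
        raise PartialCodonError(f"CDS too short to translate ({len(cds)} nt)")
    rem = len(cds) % 3
    if rem:
        if not allow_partial:
            raise PartialCodonError(f"CDS length {len(cds)} leaves a {rem}-base remainder")
        cds = cds[: len(cds) - rem]
    prot = str(Seq(cds).translate())
    if strip_terminal_stop and prot.endswith("*"):
        prot = prot[:-1]
    return prot


# ---------------------------------------------------------------------------
# assembly statistics


def _gap_total(seq: str) -> int:
    return seq.count("N")


def assembly_stats(genome: AnnotatedGenome) -> AssemblyStats:
    """Scaffold-level summary metrics.

    N50 is the length of the scaffold at which the cumulative length, taken
    in descending length order, first reaches half the total assembly
    length; ``n50_count`` counts scaffolds up to and including it.
    """
    lengths = sorted((len(s) for s in genome.scaffolds), reverse=True)
    if not lengths:
        raise ValueError("genome has no scaffolds")
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50_length = lengths[-1]
    n50_count = len(lengths)
    for i, L in enumerate(lengths, 1):
        acc += L
        if acc >= half:
            n50_length, n50_count = L, i
            break
    return AssemblyStats(
        total_length_bp=total,
        n_scaffolds=len(lengths),
        largest_scaffold_bp=lengths[0],
        mean_scaffold_bp=total / len(lengths),
        n50_length_bp=n50_length,
        n50_count=n50_count,
        total_gap_bp=sum(_gap_total(s.sequence) for s in genome.scaffolds),
    )


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases (0.0 for all-N or empty input)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def stats_tsv(stats: AssemblyStats) -> str:
    rows = [
        ("total_length_bp", stats.total_length_bp),
        ("n_scaffolds", stats.n_scaffolds),
        ("largest_scaffold_bp", stats.largest_scaffold_bp),
        ("mean_scaffold_bp", f"{stats.mean_scaffold_bp:.1f}"),
        ("n50_length_bp", stats.n50_length_bp),
        ("n50_count", stats.n50_count),
        ("total_gap_bp", stats.total_gap_bp),
    ]
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
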