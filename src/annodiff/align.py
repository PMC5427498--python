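"""Pairwise alignment primitives.

Global (Needleman-Wunsch) protein alignment with affine gaps and BLOSUM62,
a k-mer candidate prefilter for all-vs-all proteome comparison, codon-level
back-translation of protein alignments, and sliding-window masking of
low-quality alignment regions (15 bp windows, 0.4 identity floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
GAP_CODON = "---"


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass
class ProteinAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    id_a: str = ""
    id_b: str = ""

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def identity(self) -> float:
        """Fraction identical over columns where neither row is gapped."""
        match = cols = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" or y == "-":
                continue
            cols += 1
            if x == y:
                match += 1
        return match / cols if cols else 0.0

    def transpose(self) -> "ProteinAlignment":
        return ProteinAlignment(self.aligned_b, self.aligned_a, self.score, self.id_b, self.id_a)


@dataclass
class HitCandidate:
    query_id: str
    subject_id: str
    shared_kmer_count: int


@dataclass
class CodonAlignment:
    """Gap-aware in-frame codon pairing; substrate for Ka/Ks.

    Each entry of ``codons_a``/``codons_b`` is a 3-letter codon or ``---``;
    ``mask`` flags columns excluded from downstream site counting.
    """

    codons_a: list[str]
    codons_b: list[str]
    id_a: str = ""
    id_b: str = ""
    mask: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")
        if not self.mask:
            self.mask = [False] * len(self.codons_a)

    def __len__(self) -> int:
        return len(self.codons_a)

    def usable_columns(self) -> list[int]:
        """Columns that are ungapped in both rows and not masked."""
        return [
            i
            for i, (ca, cb, m) in enumerate(zip(self.codons_a, self.codons_b, self.mask))
            if not m and ca != GAP_CODON and cb != GAP_CODON
        ]


def _aligner(matrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    # Biopython convention: open_gap_score is the score of the first gapped
    # position, extend of each additional; a length-L gap scores
    # -(gap_open + (L-1) * gap_extend).
    return PairwiseAligner(
        substitution_matrix=matrix,
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
        mode="global",
    )


def global_align_protein(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    id_a: str = "",
    id_b: str = "",
) -> ProteinAlignment:
    """Optimal global alignment with affine gap penalties.

    Ties between co-optimal alignments are broken deterministically by the
    aligner's fixed traceback order.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(load_matrix(matrix_name), gap_open, gap_extend)
    alns = aligner.align(a, b)
    best = alns[0]
    return ProteinAlignment(str(best[0]), str(best[1]), best.score, id_a, id_b)


def global_align_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Alignment score only (no traceback); faster for all-vs-all scans."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _aligner(load_matrix(matrix_name), gap_open, gap_extend).score(a, b)


def _local_aligner(matrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    return PairwiseAligner(
        substitution_matrix=matrix,
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
        mode="local",
    )


def local_align_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Smith-Waterman local score; the database-search surrogate, robust to
    length mismatch (e.g. gene fragments against full-length proteins)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _local_aligner(load_matrix(matrix_name), gap_open, gap_extend).score(a, b)


def local_footprint(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[int, int] | None:
    """0-based inclusive residue interval of ``a`` covered by the optimal
    local alignment with ``b`` (None if the best local score is <= 0)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _local_aligner(load_matrix(matrix_name), gap_open, gap_extend)
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns[0].score <= 0:
        return None
    segs = alns[0].aligned[0]
    if len(segs) == 0:
        return None
    return int(segs[0][0]), int(segs[-1][1]) - 1


# ---------------------------------------------------------------------------
# k-mer candidate search


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_candidates(
    query_set: Mapping[str, str],
    subject_set: Mapping[str, str],
    k: int = 5,
    min_shared: int = 2,
) -> list[HitCandidate]:
    """Pairs of proteins sharing at least ``min_shared`` k-mers.

    Serves as the sensitive prefilter before full alignment; at the defaults
    every pair with >=80% ungapped identity over >=50 residues shares far
    more than ``min_shared`` 5-mers, so true homolog pairs are retained.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    index: dict[str, list[str]] = {}
    for sid, seq in subject_set.items():
        for km in _kmers(seq, k):
            index.setdefault(km, []).append(sid)
    out = []
    for qid, qseq in query_set.items():
        counts: dict[str, int] = {}
        for km in _kmers(qseq, k):
            for sid in index.get(km, ()):
                counts[sid] = counts.get(sid, 0) + 1
        for sid in sorted(counts):
            if counts[sid] >= min_shared:
                out.append(HitCandidate(qid, sid, counts[sid]))
    return out


# ---------------------------------------------------------------------------
# codon back-translation


class BacktranslateError(ValueError):
    pass


def codon_backtranslate(pa: ProteinAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Lift a protein alignment to codons; protein gaps become codon gaps.

    CDS inputs must exclude the terminal stop codon, so that
    ``len(cds) == 3 * len(degapped protein)``.
    """
    prot_a = pa.aligned_a.replace("-", "")
    prot_b = pa.aligned_b.replace("-", "")
    for prot, cds, gid in ((prot_a, cds_a, pa.id_a), (prot_b, cds_b, pa.id_b)):
        if len(cds) != 3 * len(prot):
            raise BacktranslateError(
                f"gene {gid or '?'}: CDS length {len(cds)} != 3 x protein length {len(prot)}"
            )
    codons_a, codons_b = [], []
    ia = ib = 0
    for x, y in zip(pa.aligned_a, pa.aligned_b):
        if x == "-":
            codons_a.append(GAP_CODON)
        else:
            codons_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if y == "-":
            codons_b.append(GAP_CODON)
        else:
            codons_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment(codons_a, codons_b, pa.id_a, pa.id_b)


# ---------------------------------------------------------------------------
# sliding-window masking


def mask_low_quality_windows(
    ca: CodonAlignment, window_bp: int = 15, min_identity: float = 0.4
) -> CodonAlignment:
    """Mask low-identity alignment regions by nucleotide sliding window.

    The window is ``window_bp`` nucleotides and advances one codon (3 nt) at
    a time; identity is computed over window positions where both rows are
    ungapped. When a window falls below ``min_identity``, the mismatching
    (or gapped) codon columns inside it are flagged masked — identical
    columns at the window edges are left alone, so an isolated mismatch
    block is masked exactly. Masking is idempotent: flags only accumulate
    and identity is computed from the sequences, never the mask.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    win_codons = max(1, (window_bp + 2) // 3)
    n = len(ca)
    mask = list(ca.mask)

    def col_identical(i: int) -> bool:
        return ca.codons_a[i] == ca.codons_b[i] and ca.codons_a[i] != GAP_CODON

    starts = range(0, max(1, n - win_codons + 1))
    for w0 in starts:
        cols = range(w0, min(n, w0 + win_codons))
        match = total = 0
        for i in cols:
            x, y = ca.codons_a[i], ca.codons_b[i]
            if x == GAP_CODON or y == GAP_CODON:
                continue
            for p in range(3):
                total += 1
                if x[p] == y[p]:
                    match += 1
        if total == 0:
            continue
        if match / total < min_identity:
            for i in cols:
                if not col_identical(i):
                    mask[i] = True
    return CodonAlignment(list(ca.codons_a), list(ca.codons_b), ca.id_a, ca.id_b, mask)


def alignment_to_fasta(pa: ProteinAlignment) -> str:
    return f">{pa.id_a or 'a'}\n{pa.aligned_a}\n>{pa.id_b or 'b'}\n{pa.aligned_b}\n"
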