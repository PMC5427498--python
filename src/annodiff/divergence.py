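"""Molecular-evolution statistics for coding-sequence pairs.

Implements the Nei-Gojobori (1986) counting estimator of synonymous and
nonsynonymous divergence with Jukes-Cantor multiple-hit correction:

* per-codon synonymous site counts ``s = sum over positions of the fraction
  of viable (non-stop) one-step neighbours that are synonymous``;
* pairwise differences decomposed over all minimal substitution paths with
  equal weights, paths routed through stop codons discarded;
* ``pS = Ns/S``, ``pN = Na/N`` and ``d = -(3/4) ln(1 - (4/3) p)``, undefined
  at saturation (``p >= 3/4``).

Also provides amino-acid identity summaries, the heterozygosity-corrected
silent-site divergence ``Ks - pi/2``, neutral divergence-time and Ne-ratio
formulas, and the outgroup relative-rate contrast.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .align import GAP_CODON, CodonAlignment, ProteinAlignment

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = frozenset(_TABLE.stop_codons)


@lru_cache(maxsize=1)
def _codon_to_aa() -> dict[str, str]:
    aa = dict(_TABLE.forward_table)
    for c in STOP_CODONS:
        aa[c] = "*"
    return aa


class ExcludedCodon(ValueError):
    """Codon cannot enter NG86 counting (stop or ambiguous)."""


def is_countable(codon: str) -> bool:
    return len(codon) == 3 and set(codon) <= set(_BASES) and codon not in STOP_CODONS


@lru_cache(maxsize=64)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts ``(s, n)`` with s + n = 3.

    At each position, s contributes the fraction of viable one-step
    neighbours (mutations not creating a stop codon) that preserve the amino
    acid. Stop and ambiguous codons are excluded from counting.
    """
    if not is_countable(codon):
        raise ExcludedCodon(f"codon {codon!r} is stop or ambiguous")
    aa = _codon_to_aa()
    s = 0.0
    for pos in range(3):
        syn = viable = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            viable += 1
            if aa[mut] == aa[codon]:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


@lru_cache(maxsize=4096)
def path_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) step counts over minimal paths.

    All orderings of the differing positions are enumerated; any path whose
    intermediate or final step passes through a stop codon is discarded.
    Returns None when every path is stop-routed (codon pair excluded).
    """
    aa = _codon_to_aa()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if aa[cur] == aa[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, nsyn_tot / n_paths


def jukes_cantor(p: float) -> float | None:
    """JC69 distance ``-(3/4) ln(1 - 4p/3)``; None at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsEstimate:
    """NG86 estimate for one aligned coding pair.

    ``Ka``/``Ks`` are substitutions per site or None when undefined
    (saturation or no usable columns); ``omega`` is defined only when
    ``Ks > 0``.
    """

    Ka: float | None
    Ks: float | None
    Na: float
    Ns: float
    N: float
    S: float
    n_codons_used: int
    n_codons_excluded: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def omega(self) -> float | None:
        if self.Ka is None or self.Ks is None or self.Ks <= 0:
            return None
        return self.Ka / self.Ks


def kaks(ca: CodonAlignment) -> KaKsEstimate:
    """NG86 Ka/Ks over the unmasked, ungapped columns of a codon alignment.

    Columns containing a stop or ambiguous codon in either row are excluded
    and counted; S and N site totals are averaged over the two sequences.
    """
    S1 = S2 = N1 = N2 = 0.0
    Ns = Na = 0.0
    used = excluded = 0
    flags: list[str] = []
    for i in ca.usable_columns():
        a, b = ca.codons_a[i], ca.codons_b[i]
        if not (is_countable(a) and is_countable(b)):
            excluded += 1
            continue
        steps = path_differences(a, b)
        if steps is None:
            excluded += 1
            continue
        sa, na = ng86_sites(a)
        sb, nb = ng86_sites(b)
        S1 += sa
        N1 += na
        S2 += sb
        N2 += nb
        Ns += steps[0]
        Na += steps[1]
        used += 1
    if used == 0:
        return KaKsEstimate(None, None, 0.0, 0.0, 0.0, 0.0, 0, excluded, ["no_usable_columns"])
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    pS = Ns / S if S > 0 else 0.0
    pN = Na / N if N > 0 else 0.0
    Ks = jukes_cantor(pS) if S > 0 else None
    Ka = jukes_cantor(pN) if N > 0 else None
    if Ks is None:
        flags.append("ks_saturated" if S > 0 else "no_synonymous_sites")
    if Ka is None and N > 0:
        flags.append("ka_saturated")
    return KaKsEstimate(Ka, Ks, Na, Ns, N, S, used, excluded, flags)


# ---------------------------------------------------------------------------
# population-genetic summaries


@dataclass
class PopGenParams:
    """Neutral parameters for time and Ne inference.

    ``u`` is the base-substitution mutation rate per site per generation,
    ``pi_s`` the within-population silent-site nucleotide diversity
    (estimating 4*Ne*u at neutrality), and ``generations_per_year`` converts
    generations to calendar time.
    """

    u: float
    pi_s: float
    generations_per_year: float

    def __post_init__(self) -> None:
        if self.u <= 0 or self.pi_s <= 0 or self.generations_per_year <= 0:
            raise ValueError("all PopGenParams fields must be positive")

    @property
    def ne(self) -> float:
        return self.pi_s / (4.0 * self.u)


def corrected_divergence(ks_obs: float, pi_ancestral: float) -> float:
    """Net silent-site divergence ``Ks - pi/2``, floored at zero.

    Subtracting half the ancestral diversity removes the expected
    contribution of polymorphism segregating at the split.
    """
    if ks_obs < 0 or pi_ancestral < 0:
        raise ValueError("inputs must be non-negative")
    d = ks_obs - pi_ancestral / 2.0
    if d < 0:
        import warnings

        warnings.warn("ancestral polymorphism exceeds observed divergence; floored at 0")
        return 0.0
    return d


def divergence_time(ks: float, params: PopGenParams) -> tuple[float, float]:
    """Neutral divergence time ``(generations, years)`` = ``Ks/(2u)``."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    generations = ks / (2.0 * params.u)
    return generations, generations / params.generations_per_year


def ne_ratio(pi_a: float, pi_b: float) -> float:
    """Ratio of effective population sizes from silent-site diversities.

    Assumes equal mutation rate in the two populations, so
    ``Ne_a/Ne_b = pi_a/pi_b``.
    """
    if pi_b <= 0:
        raise ValueError("pi_b must be positive")
    if pi_a < 0:
        raise ValueError("pi_a must be >= 0")
    return pi_a / pi_b


# ---------------------------------------------------------------------------
# relative-rate contrast


@dataclass
class RelativeRateResult:
    """Per-gene branch-length contrasts against a shared outgroup.

    ``delta_ks[i] = Ks(B, outgroup) - Ks(A, outgroup)`` so positive values
    mean excess accumulation on the B lineage; antisymmetric under swapping
    the two ingroups.
    """

    genes: list[str]
    delta_ks: np.ndarray
    delta_ka: np.ndarray
    n_excluded: int

    @property
    def mean_delta_ks(self) -> float:
        return float(np.mean(self.delta_ks))

    @property
    def mean_delta_ka(self) -> float:
        return float(np.mean(self.delta_ka))

    @property
    def se_delta_ks(self) -> float:
        return _se(self.delta_ks)

    @property
    def se_delta_ka(self) -> float:
        return _se(self.delta_ka)


def _se(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def relative_rate(
    per_gene: Iterable[tuple[str, KaKsEstimate, KaKsEstimate]],
) -> RelativeRateResult:
    """Relative-rate test from per-gene (A vs outgroup, B vs outgroup) pairs.

    Genes with an undefined Ks or Ka on either branch are excluded and
    counted rather than imputed.
    """
    genes, dks, dka = [], [], []
    excluded = 0
    for gene, est_a, est_b in per_gene:
        if None in (est_a.Ks, est_b.Ks, est_a.Ka, est_b.Ka):
            excluded += 1
            continue
        genes.append(gene)
        dks.append(est_b.Ks - est_a.Ks)
        dka.append(est_b.Ka - est_a.Ka)
    if not genes:
        raise ValueError("no genes with defined estimates on both branches")
    return RelativeRateResult(genes, np.asarray(dks), np.asarray(dka), excluded)


# ---------------------------------------------------------------------------
# identity summaries


@dataclass
class IdentitySummary:
    n_pairs: int
    mean_identity: float
    fraction_identical: float
    histogram: list[tuple[float, float, int]]  # (bin_lo, bin_hi, count)


def summarize_identity(
    pairs: Sequence[ProteinAlignment],
    min_alignment_bp: int = 300,
    bin_width: float = 0.005,
) -> IdentitySummary:
    """Identity distribution over ortholog pairs above an alignment-length
    floor (in coding nucleotides, i.e. 3x alignment columns)."""
    idents = [
        p.identity for p in pairs if 3 * len(p.aligned_a) >= min_alignment_bp
    ]
    if not idents:
        raise ValueError("no pairs above the alignment-length floor")
    arr = np.asarray(idents)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    hist = [
        (float(lo), float(hi), int(c))
        for lo, hi, c in zip(edges[:-1], edges[1:], counts)
        if c
    ]
    return IdentitySummary(
        n_pairs=len(arr),
        mean_identity=float(arr.mean()),
        fraction_identical=float(np.mean(arr == 1.0)),
        histogram=hist,
    )


def kaks_table(rows: Iterable[tuple[str, str, float, KaKsEstimate]]) -> str:
    """Per-gene TSV: gene_a, gene_b, identity, Ka, Ks, omega, codons, flags."""
    out = ["gene_a\tgene_b\tidentity\tKa\tKs\tomega\tn_codons_used\tflags"]
    fmt = lambda v: "NA" if v is None else f"{v:.6f}"
    for ga, gb, ident, est in rows:
        out.append(
            f"{ga}\t{gb}\t{ident:.4f}\t{fmt(est.Ka)}\t{fmt(est.Ks)}\t"
            f"{fmt(est.omega)}\t{est.n_codons_used}\t{','.join(est.flags) or '.'}"
        )
    return "\n".join(out) + "\n"
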