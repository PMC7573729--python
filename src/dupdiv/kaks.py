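"""Nei-Gojobori (1986) Dn/Ds estimation for codon alignments.

The unweighted NG86 counting method:

* Synonymous site count of a codon: at each position, the fraction of
  single-nucleotide changes that are synonymous, with changes creating stop
  codons excluded from the denominator; a codon therefore always contributes
  3 sites split between synonymous (S) and nonsynonymous (N).  Pair counts
  average the two sequences.
* Differences between a codon pair: all minimal substitution pathways
  (orderings of the differing positions) are enumerated, pathways passing
  through a stop codon are excluded, and synonymous/nonsynonymous step counts
  are averaged over the remaining pathways with equal weight.
* pS = Sd/S, pN = Nd/N, each Jukes-Cantor corrected:
  D = -(3/4) ln(1 - (4/3) p).  omega = Dn/Ds.

A pair is *valid* when Ds and Dn are defined and 0 < omega < 9; other pairs
carry a reason code (identical, omega-not-positive, omega-too-large,
zero-synonymous, saturation) and are masked in the pairwise omega matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .alignment import GAP, CodonAlignment
from .distmatrix import DistanceMatrix
from .errors import InsufficientDataError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_NUC = "ACGT"


def _is_codon(c: str) -> bool:
    return len(c) == 3 and all(ch in _NUC for ch in c)


@lru_cache(maxsize=None)
def syn_fraction(codon: str) -> tuple[float, ...]:
    """Per-position fraction of non-stop single-nucleotide changes that are
    synonymous."""
    aa = _AA[codon]
    out = []
    for pos in range(3):
        syn = tot = 0
        for nuc in _NUC:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            tot += 1
            if _AA[alt] == aa:
                syn += 1
        out.append(syn / tot if tot else 0.0)
    return tuple(out)


def syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (nonsynonymous = 3 - this)."""
    return float(sum(syn_fraction(codon)))


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    Enumerates every ordering of the differing positions; orderings whose
    intermediate codons are stops are discarded.  If every ordering is
    blocked by stops (does not occur between sense codons under the standard
    code, but kept for safety) all orderings are used.
    """
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff:
        return (0.0, 0.0)
    paths = []
    for order in permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append(1.0 if _AA[nxt] == _AA[cur] else 0.0)
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:
        for order in permutations(diff):
            cur = codon_a
            steps = []
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                same = nxt not in STOP_CODONS and cur not in STOP_CODONS and _AA.get(
                    nxt
                ) == _AA.get(cur)
                steps.append(1.0 if same else 0.0)
                cur = nxt
            paths.append(steps)
    sd = float(np.mean([sum(s) for s in paths]))
    return (sd, len(diff) - sd)


@dataclass(frozen=True)
class KaksResult:
    gene_a: str
    gene_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ds: float | None
    Dn: float | None
    omega: float | None
    valid: bool
    reason: str


def codon_filter(aln: CodonAlignment, pair: tuple[str, str]):
    """Codon pairs compared for a pair of sequences.

    Codons containing a gap, an ambiguity, or coding a stop in either
    sequence are excluded.  Returns (retained list of (codon_index, codon_a,
    codon_b), n_dropped).
    """
    a, b = (aln.row(pair[0]), aln.row(pair[1]))
    kept, dropped = [], 0
    for k in range(aln.n_codons):
        ca, cb = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
        if (
            not _is_codon(ca)
            or not _is_codon(cb)
            or ca in STOP_CODONS
            or cb in STOP_CODONS
        ):
            dropped += 1
            continue
        kept.append((k, ca, cb))
    if not kept:
        raise InsufficientDataError(
            f"no comparable codons between {pair[0]!r} and {pair[1]!r}"
        )
    return kept, dropped


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86(codon_pairs, gene_a: str = "a", gene_b: str = "b") -> KaksResult:
    """NG86 estimate from a list of (index, codon_a, codon_b) tuples."""
    if not codon_pairs:
        raise InsufficientDataError("NG86 requires at least one codon pair")
    s_a = sum(syn_sites(ca) for _, ca, _ in codon_pairs)
    s_b = sum(syn_sites(cb) for _, _, cb in codon_pairs)
    n_codons = len(codon_pairs)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    Sd = Nd = 0.0
    for _, ca, cb in codon_pairs:
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ds = _jc_correct(pS)
    Dn = _jc_correct(pN)

    omega = None
    if Ds is None or Dn is None:
        valid, reason = False, "saturation"
    elif Sd == 0.0 and Nd == 0.0:
        valid, reason = False, "identical"
    elif Ds == 0.0:
        valid, reason = False, "zero-synonymous"
    else:
        omega = Dn / Ds
        if omega <= 0.0:
            valid, reason = False, "omega-not-positive"
        elif omega >= 9.0:
            valid, reason = False, "omega-too-large"
        else:
            valid, reason = True, "ok"
    return KaksResult(
        gene_a, gene_b, n_codons, S, N, Sd, Nd, pS, pN, Ds, Dn, omega, valid, reason
    )


def ng86_pair(aln: CodonAlignment, gene_a: str, gene_b: str) -> KaksResult:
    kept, _ = codon_filter(aln, (gene_a, gene_b))
    return ng86(kept, gene_a, gene_b)


def pairwise_kaks_table(aln: CodonAlignment):
    """All unordered pairs: a tidy result table plus the masked omega matrix.

    Invalid pairs stay in the table with their reason code but are masked in
    the matrix.
    """
    if aln.n_seqs < 2:
        raise InsufficientDataError("need >= 2 sequences")
    rows = []
    n = aln.n_seqs
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            res = ng86_pair(aln, aln.ids[i], aln.ids[j])
            rows.append(res)
            if res.valid:
                values[i, j] = values[j, i] = res.omega
            else:
                mask[i, j] = mask[j, i] = True
    table = pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "n_codons": r.n_codons,
                "S": r.S,
                "N": r.N,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "pS": r.pS,
                "pN": r.pN,
                "Ds": r.Ds,
                "Dn": r.Dn,
                "omega": r.omega,
                "valid": r.valid,
                "reason": r.reason,
            }
            for r in rows
        ]
    )
    return table, DistanceMatrix(aln.ids, values, mask)
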