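"""Codon-level substitution machinery shared by the simulator and the inference code.

The model is MG94xHKY85 on the 61 sense codons of the standard nuclear code:
instantaneous change is allowed only between codons differing at a single
nucleotide position, with rate

    q_ij = (kappa if transition else 1) * pi_p(target_nt) * m_ij

where ``pi_p`` is the position-specific target-nucleotide frequency (F3x4
convention, uniform by default) and ``m_ij`` is a synonymous rate multiplier
``alpha`` or a non-synonymous multiplier ``beta``.  Rates into stop codons are
zero by construction of the state space.  The chain is reversible with
stationary distribution proportional to the product of positional nucleotide
frequencies restricted to sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(_table.forward_table))
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON = {c: _table.forward_table[c] for c in SENSE_CODONS}
AA_BY_INDEX = np.array([AA_OF_CODON[c] for c in SENSE_CODONS])

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True for A<->G and C<->T changes."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    return AA_OF_CODON[codon_a] == AA_OF_CODON[codon_b]


@lru_cache(maxsize=4)
def _neighbor_arrays() -> tuple[np.ndarray, ...]:
    """Sparse description of all single-nucleotide sense->sense changes.

    Returns parallel arrays (i, j, position, target_nt_index, transition_flag,
    synonymous_flag) over every ordered pair of sense codons one step apart.
    """
    src, dst, pos, tgt, ts, syn = [], [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for p in range(3):
            for nt in NUCLEOTIDES:
                if nt == ci[p]:
                    continue
                cj = ci[:p] + nt + ci[p + 1:]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                src.append(i)
                dst.append(j)
                pos.append(p)
                tgt.append(NT_INDEX[nt])
                ts.append(is_transition(ci[p], nt))
                syn.append(is_synonymous(ci, cj))
    return tuple(np.asarray(a) for a in (src, dst, pos, tgt, ts, syn))


def uniform_position_frequencies() -> np.ndarray:
    return np.full((3, 4), 0.25)


def f3x4_frequencies(rows: list[str]) -> np.ndarray:
    """Position-specific nucleotide frequencies (3x4) from aligned coding rows.

    Gap characters are ignored.  Zero counts are floored at a pseudo-count of
    one to keep the stationary distribution strictly positive.
    """
    counts = np.ones((3, 4))
    for row in rows:
        for k in range(0, len(row) - len(row) % 3, 3):
            for p in range(3):
                nt = row[k + p]
                if nt in NT_INDEX:
                    counts[p, NT_INDEX[nt]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def codon_frequencies(pos_freqs: np.ndarray) -> np.ndarray:
    """Stationary frequencies of the 61 sense codons under F3x4."""
    pi = np.array(
        [
            pos_freqs[0, NT_INDEX[c[0]]]
            * pos_freqs[1, NT_INDEX[c[1]]]
            * pos_freqs[2, NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


@dataclass
class CodonModel:
    """MG94xHKY85 rate components for fixed kappa and positional frequencies.

    ``q_syn`` and ``q_nonsyn`` hold the off-diagonal synonymous and
    non-synonymous parts; a full generator for rate multipliers (alpha, beta)
    is ``alpha * q_syn + beta * q_nonsyn`` with diagonals set to minus the row
    sums.  ``norm`` rescales time so that one unit of branch length equals one
    expected substitution per codon site for a neutral (alpha = beta = 1) site.
    """

    kappa: float
    pos_freqs: np.ndarray = field(default_factory=uniform_position_frequencies)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.pos_freqs = np.asarray(self.pos_freqs, dtype=float)
        src, dst, pos, tgt, ts, syn = _neighbor_arrays()
        rate = np.where(ts, self.kappa, 1.0) * self.pos_freqs[pos, tgt]
        qs = np.zeros((N_SENSE, N_SENSE))
        qn = np.zeros((N_SENSE, N_SENSE))
        qs[src[syn], dst[syn]] = rate[syn]
        qn[src[~syn], dst[~syn]] = rate[~syn]
        self.q_syn = qs
        self.q_nonsyn = qn
        self.pi = codon_frequencies(self.pos_freqs)
        # neutral-site mean rate used as the time unit
        self.norm = float(self.pi @ (qs + qn).sum(axis=1))

    def generator(self, alpha: float, beta: float, normalized: bool = True) -> np.ndarray:
        q = alpha * self.q_syn + beta * self.q_nonsyn
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        if normalized:
            q = q / self.norm
        return q


class EigenDecomposition:
    """Spectral form of a reversible generator, for cheap matrix exponentials.

    For a pi-reversible Q, B = D^{1/2} Q D^{-1/2} is symmetric (D = diag(pi)),
    so P(t) = A exp(w t) A_inv with A = D^{-1/2} V from the eigensystem of B.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        b = (q * d[:, None]) / d[None, :]
        b = 0.5 * (b + b.T)  # symmetrize against round-off
        w, v = np.linalg.eigh(b)
        self.w = w
        self.a = v / d[:, None]
        self.a_inv = v.T * d[None, :]

    def prob_matrix(self, t: float) -> np.ndarray:
        p = (self.a * np.exp(self.w * t)) @ self.a_inv
        np.clip(p, 0.0, None, out=p)
        return p

    def prob_matrices(self, ts: np.ndarray) -> np.ndarray:
        ew = np.exp(np.multiply.outer(np.asarray(ts, dtype=float), self.w))
        p = np.einsum("ij,tj,jk->tik", self.a, ew, self.a_inv)
        np.clip(p, 0.0, None, out=p)
        return p


def mutation_opportunities(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """Rate-weighted synonymous and non-synonymous mutational opportunity.

    Enumerates the nine single-nucleotide changes of ``codon`` (changes into
    stop codons excluded), weighting each by kappa when it is a transition.
    Under uniform positional frequencies these weights are proportional to the
    MG94 rates out of the codon, so they serve as exact opportunity counts for
    pooled rate checks.
    """
    syn = nonsyn = 0.0
    for p in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[p]:
                continue
            other = codon[:p] + nt + codon[p + 1:]
            if other in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[p], nt) else 1.0
            if is_synonymous(codon, other):
                syn += w
            else:
                nonsyn += w
    return syn, nonsyn


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '-' for any codon touching a gap, 'X' otherwise unknown."""
    if "-" in codon:
        return "-"
    if codon in STOP_CODONS:
        return "*"
    return AA_OF_CODON.get(codon, "X")
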