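"""McDonald-Kreitman counting, the fixation index, and composite-region tests.

The MK test contrasts, for synonymous and non-synonymous changes separately,
fixed differences between two species (dN, dS) with polymorphisms segregating
within them (pN, pS).  The fixation index FI = (dN/dS)/(pN/pS) is about 1
under neutrality, below 1 under purifying selection (non-synonymous variants
segregate but do not fix) and above 1 under adaptive fixation.

Counting conventions (full panels, not consensus pairs):
  * a nucleotide position of a codon column is a fixed difference when each
    species is internally monomorphic there and the two species differ, and a
    polymorphism when either species segregates there; a segregating position
    is never also counted as fixed;
  * each single-nucleotide change is classified synonymous or non-synonymous
    in its codon context; codons carrying several changed positions are scored
    by enumerating all orderings of the single-nucleotide steps and averaging
    the per-path synonymous/non-synonymous tallies with equal weights,
    excluding orderings that pass through a stop codon (if every ordering
    does, all are used);
  * divergence paths run between the two species' majority codons and are
    averaged over both species' codon contexts, which makes the counts
    invariant under relabelling of the species;
  * counts may therefore be fractional; they are kept fractional for FI and
    rounded half-up only for Fisher's exact test.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from .alignment import CodonAlignment
from .codons import STOP_CODONS, translate_codon


@dataclass
class MKCounts:
    scope_id: str
    dN: float = 0.0
    dS: float = 0.0
    pN: float = 0.0
    pS: float = 0.0
    n_codons: int = 0

    def __add__(self, other: "MKCounts") -> "MKCounts":
        return MKCounts(
            self.scope_id,
            self.dN + other.dN,
            self.dS + other.dS,
            self.pN + other.pN,
            self.pS + other.pS,
            self.n_codons + other.n_codons,
        )


@dataclass
class FIResult:
    scope_id: str
    fi: float  # nan when undefined
    fisher_p: float  # nan when undefined
    call: str  # positive | negative | none
    counts: MKCounts | None = None
    note: str = ""


def _is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def _step_is_synonymous(before: str, after: str) -> bool:
    return translate_codon(before) == translate_codon(after)


def _path_average(base: str, steps: list[tuple[int, str]]) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) step counts over step orderings.

    Each step sets one codon position to a target nucleotide.  Orderings whose
    intermediate codons are stops are excluded; if none survive, all are used.
    """
    if not steps:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(steps):
        syn = nonsyn = 0
        cur = base
        valid = True
        for idx, (p, nt) in enumerate(order):
            nxt = cur[:p] + nt + cur[p + 1:]
            if _step_is_synonymous(cur, nxt):
                syn += 1
            else:
                nonsyn += 1
            if idx < len(order) - 1 and _is_stop(nxt):
                valid = False
            cur = nxt
        paths.append((valid, syn, nonsyn))
    used = [(s, n) for valid, s, n in paths if valid] or [(s, n) for _, s, n in paths]
    return (
        sum(s for s, _ in used) / len(used),
        sum(n for _, n in used) / len(used),
    )


def _majority(values: list[str], first: str) -> str:
    counts = Counter(values)
    top = max(counts.values())
    tied = {v for v, c in counts.items() if c == top}
    if first in tied:
        return first
    return next(v for v in values if v in tied)


def mk_counts(
    aln: CodonAlignment,
    codon_indices: set[int] | None = None,
    ignore_positions: set[int] | None = None,
    scope_id: str | None = None,
) -> MKCounts:
    """MK counts for a gene, optionally restricted to a codon-index set.

    ``ignore_positions`` (0-based nucleotide columns) supports the variant of
    low-frequency SNP handling that drops the site from the counts instead of
    rewriting alleles: an ignored position is treated as monomorphic at each
    species' majority allele.
    """
    ignore = ignore_positions or set()
    sp_a, sp_b = aln.species
    rows_a = [r.seq for r in aln.rows_of(sp_a)]
    rows_b = [r.seq for r in aln.rows_of(sp_b)]
    indices = range(aln.n_codons) if codon_indices is None else sorted(codon_indices)
    out = MKCounts(scope_id or aln.gene_id)
    for k in indices:
        cods_a = [s[3 * k : 3 * k + 3] for s in rows_a]
        cods_b = [s[3 * k : 3 * k + 3] for s in rows_b]
        if any("-" in c for c in cods_a + cods_b):
            continue
        if any(_is_stop(c) for c in cods_a + cods_b):
            continue
        out.n_codons += 1
        maj_a = "".join(_majority([c[p] for c in cods_a], cods_a[0][p]) for p in range(3))
        maj_b = "".join(_majority([c[p] for c in cods_b], cods_b[0][p]) for p in range(3))
        seg_a, seg_b, fixed = [], [], []
        for p in range(3):
            if 3 * k + p in ignore:
                continue
            alleles_a = {c[p] for c in cods_a}
            alleles_b = {c[p] for c in cods_b}
            if len(alleles_a) > 1:
                seg_a.append(p)
            if len(alleles_b) > 1:
                seg_b.append(p)
            if len(alleles_a) == 1 and len(alleles_b) == 1 and alleles_a != alleles_b:
                fixed.append(p)

        if fixed:
            steps = [(p, maj_b[p]) for p in fixed]
            base1 = maj_a
            base2 = "".join(maj_a[p] if p in fixed else maj_b[p] for p in range(3))
            bases = [base1] if base1 == base2 else [base1, base2]
            syn = nonsyn = 0.0
            for base in bases:
                s, n = _path_average(base, steps)
                syn += s / len(bases)
                nonsyn += n / len(bases)
            out.dS += syn
            out.dN += nonsyn

        for cods, maj, seg in ((cods_a, maj_a, seg_a), (cods_b, maj_b, seg_b)):
            if not seg:
                continue
            allele_sets = {p: {c[p] for c in cods} for p in seg}
            if any(len(allele_sets[p]) > 2 for p in seg):
                # multi-allelic codon: classify each minority change in the
                # majority-codon context, without cross-position path averaging
                for p in seg:
                    for nt in sorted(allele_sets[p] - {maj[p]}):
                        nxt = maj[:p] + nt + maj[p + 1:]
                        if _step_is_synonymous(maj, nxt):
                            out.pS += 1.0
                        else:
                            out.pN += 1.0
            else:
                steps = [(p, next(iter(allele_sets[p] - {maj[p]}))) for p in seg]
                s, n = _path_average(maj, steps)
                out.pS += s
                out.pN += n
    if out.n_codons == 0:
        raise ValueError(f"{out.scope_id}: no comparable codons")
    return out


def fixation_index(counts: MKCounts) -> FIResult:
    """FI = (dN/dS)/(pN/pS); undefined (nan) unless dS, pN and pS are positive."""
    if counts.dS > 0 and counts.pN > 0 and counts.pS > 0:
        fi = (counts.dN / counts.dS) / (counts.pN / counts.pS)
        return FIResult(counts.scope_id, float(fi), math.nan, "none", counts)
    return FIResult(counts.scope_id, math.nan, math.nan, "none", counts, note="fi_undefined")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_exact_2x2(counts: MKCounts) -> float:
    """Two-tailed Fisher's exact p for the table [[dN, dS], [pN, pS]].

    Fractional counts are rounded half-up.  A zero row or column margin makes
    the table uninformative; p = 1 by convention.
    """
    table = np.array(
        [
            [_round_half_up(counts.dN), _round_half_up(counts.dS)],
            [_round_half_up(counts.pN), _round_half_up(counts.pS)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(_scipy_fisher(table, alternative="two-sided")[1])


def mk_test(
    aln_or_counts,
    codon_indices: set[int] | None = None,
    alpha: float = 0.05,
    ignore_positions: set[int] | None = None,
    scope_id: str | None = None,
) -> FIResult:
    """Full per-scope MK test: counts, FI, Fisher's exact and selection call."""
    if isinstance(aln_or_counts, MKCounts):
        counts = aln_or_counts
    else:
        counts = mk_counts(aln_or_counts, codon_indices, ignore_positions, scope_id)
    res = fixation_index(counts)
    p = fisher_exact_2x2(counts)
    call = "none"
    if not math.isnan(res.fi) and p <= alpha:
        if res.fi > 1:
            call = "positive"
        elif res.fi < 1:
            call = "negative"
    return FIResult(counts.scope_id, res.fi, p, call, counts, res.note)


def composite_mk(
    genes: list[CodonAlignment],
    masks: dict[str, np.ndarray],
    cls: str,
    alpha: float = 0.05,
) -> FIResult:
    """Pooled MK test over all codons of one conformational class.

    ``masks`` maps gene_id to a per-residue class array (codon i encodes
    residue i); codons of class ``cls`` from every gene are merged into one
    composite scope, mirroring a concatenated-region alignment.
    """
    total = MKCounts(f"composite_{cls}")
    contributed = False
    for aln in genes:
        classes = np.asarray(masks[aln.gene_id], dtype=object)
        idx = {int(i) for i in np.flatnonzero(classes[: aln.n_codons] == cls)}
        if not idx:
            continue
        try:
            c = mk_counts(aln, codon_indices=idx)
        except ValueError:
            continue
        total = total + c
        contributed = True
    if not contributed:
        raise ValueError(f"no codons of class {cls!r} contribute to the composite")
    return mk_test(total, alpha=alpha)


def remove_fi_outliers(fi_values: list[float], n_sd: float = 3.0) -> list[float]:
    """Drop FI values more than n_sd standard deviations from the mean.

    Mean and SD come from the full defined set in a single pass.
    """
    defined = [v for v in fi_values if not math.isnan(v)]
    if len(defined) < 2:
        return list(defined)
    arr = np.asarray(defined)
    mean, sd = float(arr.mean()), float(arr.std())
    if sd == 0:
        return list(defined)
    return [v for v in defined if abs(v - mean) <= n_sd * sd]
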