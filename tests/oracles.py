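"""Independent reference implementations used only to cross-check results.

Everything here is written as directly as possible from first principles
(exhaustive enumeration, naive loops, published formulas) and deliberately
avoids the package's own computational paths.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    if codon in STOPS:
        return "*"
    return str(Seq(codon).translate())


# -- McDonald-Kreitman counting ------------------------------------------------
def _avg_over_orderings(base: str, steps: list[tuple[int, str]]) -> tuple[float, float]:
    """Average syn/nonsyn step tallies over all ordering permutations,
    dropping orderings whose strict intermediates are stop codons."""
    records = []
    for perm in itertools.permutations(range(len(steps))):
        cur = base
        syn = non = 0
        ok = True
        for rank, step_i in enumerate(perm):
            p, nt = steps[step_i]
            new = cur[:p] + nt + cur[p + 1 :]
            if aa(cur) == aa(new):
                syn += 1
            else:
                non += 1
            if new in STOPS and rank != len(perm) - 1:
                ok = False
            cur = new
        records.append((ok, syn, non))
    valid = [(s, n) for ok, s, n in records if ok]
    if not valid:
        valid = [(s, n) for _, s, n in records]
    return (
        sum(v[0] for v in valid) / len(valid),
        sum(v[1] for v in valid) / len(valid),
    )


def _majority_nt(column: list[str], first_row_value: str) -> str:
    counts = Counter(column)
    best = max(counts.values())
    winners = {k for k, v in counts.items() if v == best}
    if first_row_value in winners:
        return first_row_value
    for value in column:
        if value in winners:
            return value
    raise AssertionError


def mk_counts_oracle(species_a_seqs: list[str], species_b_seqs: list[str]):
    """Exhaustive-path MK counting for two species panels of codon sequences.

    Returns (dN, dS, pN, pS).  Implements the documented convention: per
    nucleotide position of each codon, fixed difference iff both species are
    monomorphic and differ, polymorphic iff a species segregates; divergence
    paths run between majority codons averaged over both species' contexts;
    per-species polymorphism paths start from the species majority codon,
    with a no-path fallback for codons holding a >2-allele position.
    """
    n_codons = len(species_a_seqs[0]) // 3
    dN = dS = pN = pS = 0.0
    for k in range(n_codons):
        codons_a = [s[3 * k : 3 * k + 3] for s in species_a_seqs]
        codons_b = [s[3 * k : 3 * k + 3] for s in species_b_seqs]
        if any("-" in c for c in codons_a + codons_b):
            continue
        if any(c in STOPS for c in codons_a + codons_b):
            continue
        maj_a = "".join(_majority_nt([c[p] for c in codons_a], codons_a[0][p]) for p in range(3))
        maj_b = "".join(_majority_nt([c[p] for c in codons_b], codons_b[0][p]) for p in range(3))
        fixed_positions = []
        for p in range(3):
            set_a = {c[p] for c in codons_a}
            set_b = {c[p] for c in codons_b}
            if len(set_a) == 1 and len(set_b) == 1 and set_a != set_b:
                fixed_positions.append(p)
        if fixed_positions:
            steps = [(p, maj_b[p]) for p in fixed_positions]
            ctx2 = "".join(maj_a[p] if p in fixed_positions else maj_b[p] for p in range(3))
            contexts = [maj_a] if ctx2 == maj_a else [maj_a, ctx2]
            s_sum = n_sum = 0.0
            for ctx in contexts:
                s, n = _avg_over_orderings(ctx, steps)
                s_sum += s
                n_sum += n
            dS += s_sum / len(contexts)
            dN += n_sum / len(contexts)
        for codons, maj in ((codons_a, maj_a), (codons_b, maj_b)):
            seg = [p for p in range(3) if len({c[p] for c in codons}) > 1]
            if not seg:
                continue
            if any(len({c[p] for c in codons}) > 2 for p in seg):
                for p in seg:
                    for nt in sorted({c[p] for c in codons} - {maj[p]}):
                        new = maj[:p] + nt + maj[p + 1 :]
                        if aa(maj) == aa(new):
                            pS += 1
                        else:
                            pN += 1
            else:
                steps = [(p, ({c[p] for c in codons} - {maj[p]}).pop()) for p in seg]
                s, n = _avg_over_orderings(maj, steps)
                pS += s
                pN += n
    return dN, dS, pN, pS


# -- Fisher's exact test -------------------------------------------------------
def fisher_two_tailed_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by full enumeration of tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_comb(nn, kk):
        return math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_denom = log_comb(n, c1)
    probs = {x: math.exp(log_comb(r1, x) + log_comb(r2, c1 - x) - log_denom) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


# -- likelihood by exhaustive state summation ----------------------------------
def star_tree_column_loglik(q: np.ndarray, pi: np.ndarray, lengths: list[float],
                            leaf_states: list[int]) -> float:
    """Log-likelihood of one column on a star tree by summing over the root state.

    Transition matrices come from scipy's matrix exponential, not the
    package's eigendecomposition.
    """
    from scipy.linalg import expm

    mats = [expm(q * t) for t in lengths]
    total = 0.0
    for x in range(len(pi)):
        term = pi[x]
        for mat, s in zip(mats, leaf_states):
            if s >= 0:
                term *= mat[x, s]
        total += term
    return math.log(total)


def two_level_tree_column_loglik(q: np.ndarray, pi: np.ndarray, tree, lengths,
                                 leaf_states: list[int]) -> float:
    """Brute-force likelihood for a rooted tree by enumerating every internal
    state assignment (exponential in the number of internal nodes)."""
    from scipy.linalg import expm

    mats = {v: expm(q * float(lengths[v])) for v in range(tree.n_nodes) if v != tree.root}
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    n_states = len(pi)
    total = 0.0
    for assignment in itertools.product(range(n_states), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        for leaf in range(tree.n_leaves):
            state[leaf] = leaf_states[leaf]
        term = pi[state[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            if tree.is_leaf(v) and state[v] < 0:
                continue  # missing leaf integrates out
            term *= mats[v][state[tree.parent[v]], state[v]]
        total += term
    return math.log(total)


# -- distances -----------------------------------------------------------------
def tajima_nei_oracle(seq_a: str, seq_b: str) -> float:
    """Tajima-Nei (1984) distance coded naively from the published formula."""
    pairs = [(x, y) for x, y in zip(seq_a, seq_b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    diffs = [(x, y) for x, y in pairs if x != y]
    p = len(diffs) / n
    if p == 0:
        return 0.0
    freq: Counter = Counter()
    for x, y in pairs:
        freq[x] += 1
        freq[y] += 1
    g = {nt: freq[nt] / (2 * n) for nt in "ACGT"}
    pair_freq: Counter = Counter()
    for x, y in diffs:
        pair_freq[frozenset((x, y))] += 1
    h = 0.0
    for key, count in pair_freq.items():
        i, j = sorted(key)
        x_ij = count / n
        h += x_ij**2 / (2 * g[i] * g[j])
    b = 0.5 * (1 - sum(v**2 for v in g.values()) + p**2 / h)
    return -b * math.log(1 - p / b)


# -- Spearman ------------------------------------------------------------------
def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson with explicit midrank tie averaging."""
    def midranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
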