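"""Per-codon fixed-effects-likelihood (FEL) selection tests.

For each gene the full strain panel (both species) enters a single analysis:
a neighbor-joining tree is built from Tajima-Nei nucleotide distances, an
MG94xHKY85 codon model with one gene-wide omega is fitted by maximum
likelihood (kappa, omega and a global branch-length scale; F3x4 codon
frequencies), and every codon column is then tested by a likelihood-ratio
test comparing free per-site synonymous and non-synonymous rates (alpha,
beta) against the constraint alpha = beta, with branch lengths and kappa held
at their gene-level estimates.  alpha > beta signals negative selection at
the site, beta > alpha positive selection; the LRT statistic is referred to a
chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from .alignment import CodonAlignment
from .codons import CODON_INDEX, CodonModel, EigenDecomposition, f3x4_frequencies
from .trees import PhyloTree

_NT = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturationError(ValueError):
    """Pairwise divergence too large for the distance formula's logarithm."""


def tajima_nei_distance(seq_a: str, seq_b: str, label: str = "") -> float:
    """Tajima-Nei (1984) evolutionary distance between two aligned rows.

    Only positions where both rows carry an unambiguous nucleotide are
    compared.  Identical sequences give 0; saturated pairs (log argument
    non-positive) raise SaturationError.
    """
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    codes_a = np.full(len(a), -1)
    codes_b = np.full(len(b), -1)
    for nt, i in _NT.items():
        codes_a[a == nt.encode()] = i
        codes_b[b == nt.encode()] = i
    ok = (codes_a >= 0) & (codes_b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"{label}: no comparable sites")
    xa, xb = codes_a[ok], codes_b[ok]
    diff = xa != xb
    p = float(diff.mean())
    if p == 0.0:
        return 0.0
    counts = np.bincount(xa, minlength=4) + np.bincount(xb, minlength=4)
    g = counts / (2 * n)
    pair_counts = np.zeros((4, 4))
    np.add.at(pair_counts, (np.minimum(xa[diff], xb[diff]), np.maximum(xa[diff], xb[diff])), 1)
    h = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            if pair_counts[i, j] > 0:
                x_ij = pair_counts[i, j] / n
                h += x_ij**2 / (2 * g[i] * g[j])
    b_coef = 0.5 * (1 - float(np.sum(g**2)) + p**2 / h)
    arg = 1 - p / b_coef
    if arg <= 0:
        raise SaturationError(f"{label}: saturated pair (p={p:.3f}, b={b_coef:.3f})")
    return float(-b_coef * np.log(arg))


def build_nj_tree(aln: CodonAlignment) -> PhyloTree:
    """Neighbor-joining tree from pairwise Tajima-Nei distances.

    Negative NJ branch lengths are clamped to zero.
    """
    if len(aln.rows) < 3:
        raise ValueError(f"{aln.gene_id}: NJ needs at least 3 rows")
    names = [r.strain for r in aln.rows]
    n = len(names)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = tajima_nei_distance(aln.rows[i].seq, aln.rows[j].seq, f"{aln.gene_id}:{names[i]}-{names[j]}")
        dm[i, j] = dm[j, i] = d
    tree = skbio_nj(DistanceMatrix(dm, ids=names))
    phylo = PhyloTree.from_skbio(tree)
    # restore the alignment's leaf order
    order = {n_: i for i, n_ in enumerate(phylo.leaf_names)}
    if [order[n_] for n_ in names] != list(range(n)):
        perm = [phylo.leaf_names.index(n_) for n_ in names]
        remap = np.arange(phylo.n_nodes)
        remap[perm] = np.arange(n)
        parent = np.empty_like(phylo.parent)
        lengths = np.empty_like(phylo.lengths)
        for v in range(phylo.n_nodes):
            parent[remap[v]] = remap[phylo.parent[v]] if phylo.parent[v] >= 0 else -1
            lengths[remap[v]] = phylo.lengths[v]
        phylo = PhyloTree(names, parent, lengths)
    return phylo


# -- likelihood machinery ------------------------------------------------------
def encode_alignment(aln: CodonAlignment, tree: PhyloTree | None = None) -> np.ndarray:
    """Leaf-by-codon matrix of sense-codon indices; -1 for gapped/ambiguous codons.

    When a tree is given, rows are arranged in its leaf order (matched by
    strain name), so the matrix indexes directly into the pruning recursion.
    """
    rows = aln.rows
    if tree is not None:
        by_strain = {r.strain: r for r in aln.rows}
        rows = [by_strain[name] for name in tree.leaf_names]
    codes = np.full((len(rows), aln.n_codons), -1, dtype=np.int64)
    for i, r in enumerate(rows):
        for k in range(aln.n_codons):
            codes[i, k] = CODON_INDEX.get(r.seq[3 * k : 3 * k + 3], -1)
    return codes


def column_logliks(
    tree: PhyloTree, probs: np.ndarray, leaf_codes: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Felsenstein pruning log-likelihood of every codon column.

    ``probs[v]`` is the transition matrix on the edge above node ``v``;
    gapped leaves contribute a uniform partial likelihood (missing data).
    """
    n_states = len(pi)
    n_cols = leaf_codes.shape[1]
    logscale = np.zeros(n_cols)
    partial: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if tree.is_leaf(v):
            continue
        m = np.ones((n_states, n_cols))
        for c in tree.children[v]:
            if tree.is_leaf(c):
                codes = leaf_codes[c]
                f = probs[c][:, np.where(codes < 0, 0, codes)]
                if (codes < 0).any():
                    f = f.copy()
                    f[:, codes < 0] = 1.0
            else:
                f = probs[c] @ partial.pop(c)
            m *= f
        top = m.max(axis=0)
        top[top == 0] = 1.0
        m /= top
        logscale += np.log(top)
        partial[v] = m
    root = partial[tree.root]
    lik = pi @ root
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def _edge_probs(decomp: EigenDecomposition, lengths: np.ndarray, rate: float = 1.0) -> np.ndarray:
    ew = np.exp(np.multiply.outer(lengths * rate, decomp.w))
    p = np.matmul(decomp.a[None, :, :] * ew[:, None, :], decomp.a_inv)
    np.clip(p, 0.0, None, out=p)
    return p


@dataclass
class GlobalFit:
    """Gene-level MG94xHKY85 fit shared by all site tests of the gene."""

    gene_id: str
    tree: PhyloTree
    kappa: float
    omega: float
    scale: float
    log_likelihood: float
    converged: bool
    degenerate: bool = False
    model: CodonModel | None = None
    lengths: np.ndarray | None = None  # per-node branch lengths, codon units
    _decomp_cache: dict = field(default_factory=dict, repr=False)

    @property
    def codon_frequencies(self) -> np.ndarray:
        return self.model.pi

    def decomp(self, omega: float) -> EigenDecomposition:
        key = round(float(omega), 10)
        if key in self._decomp_cache:
            return self._decomp_cache[key]
        q = (self.model.q_syn + omega * self.model.q_nonsyn) / self.model.norm
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        d = EigenDecomposition(q, self.model.pi)
        if key in (0.0, 1.0):  # null and synonymous-only generators are reused
            self._decomp_cache[key] = d
        return d

    def decomp_nonsyn(self) -> EigenDecomposition:
        """Generator for the pure non-synonymous boundary (alpha = 0)."""
        if "nonsyn" not in self._decomp_cache:
            q = self.model.q_nonsyn / self.model.norm
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            self._decomp_cache["nonsyn"] = EigenDecomposition(q, self.model.pi)
        return self._decomp_cache["nonsyn"]


def fit_global_model(
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    max_iter: int = 400,
) -> GlobalFit:
    """Maximum-likelihood gene-wide fit of kappa, omega and a branch scale.

    Codon frequencies follow the F3x4 convention from the observed alignment.
    Branch lengths are the NJ estimates multiplied by one free scale factor
    (nucleotide distances are converted to codon units by the fitted scale).
    """
    if tree is None:
        tree = build_nj_tree(aln)
    codes = encode_alignment(aln, tree)
    pos_freqs = f3x4_frequencies([r.seq for r in aln.rows])
    variant = any(len({c for c in col if c >= 0}) > 1 for col in codes.T)
    if not variant:
        model = CodonModel(2.0, pos_freqs)
        lengths = tree.lengths * 0.0
        fit = GlobalFit(aln.gene_id, tree, 2.0, 1.0, 0.0, 0.0, True, degenerate=True,
                        model=model, lengths=lengths)
        return fit

    nj_lengths = tree.lengths.copy()

    def neg_loglik(theta: np.ndarray) -> float:
        log_kappa, log_omega, log_scale = theta
        kappa = float(np.exp(log_kappa))
        omega = float(np.exp(log_omega))
        scale = float(np.exp(log_scale))
        if not (1e-3 < kappa < 1e3 and 1e-5 < omega < 1e3 and 1e-6 < scale < 1e4):
            return 1e12
        model = CodonModel(kappa, pos_freqs)
        q = model.generator(1.0, omega)
        decomp = EigenDecomposition(q, model.pi)
        probs = _edge_probs(decomp, nj_lengths * scale)
        ll = float(column_logliks(tree, probs, codes, model.pi).sum())
        return -ll if np.isfinite(ll) else 1e12

    res = minimize(
        neg_loglik,
        x0=np.log([2.0, 0.5, 3.0]),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-7},
    )
    kappa, omega, scale = np.exp(res.x)
    model = CodonModel(float(kappa), pos_freqs)
    fit = GlobalFit(
        aln.gene_id,
        tree,
        float(kappa),
        float(omega),
        float(scale),
        float(-res.fun),
        bool(res.success or res.fun < 1e11),
        model=model,
        lengths=nj_lengths * float(scale),
    )
    return fit


@dataclass
class SiteSelectionResult:
    gene_id: str
    codon_index: int  # 0-based
    alpha: float
    beta: float
    lrt: float
    p_value: float
    call: str  # positive | negative | neutral
    note: str = ""


def _column_ll_at_rate(
    tree: PhyloTree,
    decomp: EigenDecomposition,
    lengths: np.ndarray,
    rate: float,
    col: np.ndarray,
    pi: np.ndarray,
) -> float:
    """Single-column pruning log-likelihood at one overall rate.

    Works in the generator's eigenbasis so each edge costs two matrix-vector
    products instead of a full transition-matrix build.
    """
    if rate <= 0.0:
        observed = {int(c) for c in col if c >= 0}
        if len(observed) == 1:
            return float(np.log(pi[observed.pop()]))
        return -np.inf
    a, a_inv, w = decomp.a, decomp.a_inv, decomp.w
    logscale = 0.0
    partial: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if tree.is_leaf(v):
            continue
        m = np.ones(len(pi))
        for c in tree.children[v]:
            ew = np.exp(w * (lengths[c] * rate))
            if tree.is_leaf(c):
                code = col[c]
                if code < 0:
                    continue  # missing data: uniform factor
                f = a @ (ew * a_inv[:, code])
            else:
                f = a @ (ew * (a_inv @ partial.pop(c)))
            np.clip(f, 0.0, None, out=f)
            m *= f
        top = m.max()
        if top == 0.0:
            return -np.inf
        m /= top
        logscale += np.log(top)
        partial[v] = m
    lik = float(pi @ partial[tree.root])
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logscale


def _site_loglik(fit: GlobalFit, codes_col: np.ndarray, alpha: float, beta: float) -> float:
    """Single-column log-likelihood at site rates (alpha, beta)."""
    if alpha <= 0 and beta <= 0:
        rate, omega = 0.0, 1.0
    elif alpha <= 0:
        omega = 1e8  # pure non-synonymous; large finite surrogate
        rate = beta / omega
    else:
        rate, omega = alpha, beta / alpha
    decomp = fit.decomp(max(omega, 1e-8))
    return _column_ll_at_rate(fit.tree, decomp, fit.lengths, rate, codes_col, fit.model.pi)


def _optimize_rate(
    fit: GlobalFit,
    codes_col: np.ndarray,
    omega: float,
    decomp: EigenDecomposition | None = None,
) -> tuple[float, float]:
    """Maximize the column likelihood over the overall rate at fixed omega."""
    if decomp is None:
        decomp = fit.decomp(max(omega, 1e-8))
    tree, lengths, pi = fit.tree, fit.lengths, fit.model.pi

    def neg(log_rate: float) -> float:
        return -_column_ll_at_rate(tree, decomp, lengths, np.exp(log_rate), codes_col, pi)

    res = minimize_scalar(neg, bounds=(-12.0, 4.5), method="bounded",
                          options={"xatol": 2e-3})
    r_hat, ll = float(np.exp(res.x)), -float(res.fun)
    ll0 = _column_ll_at_rate(tree, decomp, lengths, 0.0, codes_col, pi)
    if ll0 >= ll:  # boundary optimum: invariant-like column
        return 0.0, ll0
    return r_hat, ll


def fel_site_test(
    aln_or_codes,
    fit: GlobalFit,
    codon_index: int,
    p_threshold: float = 0.1,
) -> SiteSelectionResult:
    """FEL likelihood-ratio test at one codon column.

    The alternative maximizes the column likelihood over (alpha, beta) via a
    profile over omega = beta/alpha with a nested overall-rate optimization;
    the null constrains alpha = beta.  P-values come from chi2(1).
    """
    codes = aln_or_codes if isinstance(aln_or_codes, np.ndarray) else encode_alignment(aln_or_codes)
    col = codes[:, codon_index]
    gene = fit.gene_id
    if (col < 0).all():
        return SiteSelectionResult(gene, codon_index, np.nan, np.nan, 0.0, 1.0,
                                   "neutral", note="fully_gapped")
    if fit.degenerate:
        return SiteSelectionResult(gene, codon_index, 0.0, 0.0, 0.0, 1.0,
                                   "neutral", note="degenerate_fit")
    observed = {c for c in col if c >= 0}
    if len(observed) <= 1:
        return SiteSelectionResult(gene, codon_index, 0.0, 0.0, 0.0, 1.0,
                                   "neutral", note="invariant")

    # null: alpha = beta = r
    r0, ll_null = _optimize_rate(fit, col, 1.0)

    # alternative: profile likelihood over omega
    def neg_profile(log10_omega: float) -> float:
        return -_optimize_rate(fit, col, 10.0**log10_omega)[1]

    res = minimize_scalar(neg_profile, bounds=(-4.0, 4.0), method="bounded",
                          options={"xatol": 2e-3})
    omega_hat = 10.0 ** float(res.x)
    r_alt, ll_alt = _optimize_rate(fit, col, omega_hat)
    alpha = r_alt
    beta = r_alt * omega_hat
    # boundary candidates the omega profile cannot reach exactly; only worth
    # evaluating when the profile optimum presses against a bound
    if res.x < -2.5:
        r_syn, ll_syn = _optimize_rate(fit, col, 0.0, decomp=fit.decomp(0.0))
        if ll_syn > ll_alt:
            ll_alt, alpha, beta = ll_syn, r_syn, 0.0
    if res.x > 2.5:
        r_non, ll_non = _optimize_rate(fit, col, 1.0, decomp=fit.decomp_nonsyn())
        if ll_non > ll_alt:
            ll_alt, alpha, beta = ll_non, 0.0, r_non
    if ll_null > ll_alt:  # optimizer slack: null is nested in the alternative
        ll_alt, alpha, beta = ll_null, r0, r0
    lrt = max(2.0 * (ll_alt - ll_null), 0.0)
    p = float(chi2.sf(lrt, df=1))
    call = "neutral"
    if p <= p_threshold and not np.isclose(alpha, beta, rtol=1e-6, atol=1e-12):
        call = "positive" if beta > alpha else "negative"
    if not np.isfinite(lrt) or not np.isfinite(p):
        raise FloatingPointError(f"{gene}: non-finite likelihood at codon {codon_index + 1}")
    return SiteSelectionResult(gene, codon_index, float(alpha), float(beta), float(lrt), p, call)


def fel_scan(
    aln: CodonAlignment,
    p_threshold: float = 0.1,
    tree: PhyloTree | None = None,
    fit: GlobalFit | None = None,
) -> list[SiteSelectionResult]:
    """Run the FEL site test at every codon of a gene.

    Identical column patterns share one optimization.
    """
    if fit is None:
        fit = fit_global_model(aln, tree=tree)
    codes = encode_alignment(aln, fit.tree)
    cache: dict[bytes, SiteSelectionResult] = {}
    out = []
    for k in range(codes.shape[1]):
        key = codes[:, k].tobytes()
        if key in cache:
            r = cache[key]
            r = SiteSelectionResult(r.gene_id, k, r.alpha, r.beta, r.lrt, r.p_value, r.call, r.note)
        else:
            r = fel_site_test(codes, fit, k, p_threshold)
            cache[key] = r
        out.append(r)
    return out


def classify_gene_sites(results: list[SiteSelectionResult]) -> tuple[int, int, int]:
    """(positive, negative, neutral) tallies; skipped columns count as neutral."""
    pos = sum(1 for r in results if r.call == "positive")
    neg = sum(1 for r in results if r.call == "negative")
    return pos, neg, len(results) - pos - neg
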