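"""Contingency, ratio, and randomization-enrichment statistics for selected sites.

The central device is an empirical null: the observed number n of selected
sites of one type inside a scope of N codons (a conformational class, or all
codons of a functional category) is compared to the distribution of the same
count in repeated random draws of N codons from the pooled codon universe.
Drawing N exchangeable codons without replacement and counting the type-C
hits is distributionally identical to a hypergeometric draw, which is how the
resamples are generated; with-replacement resampling maps to a binomial draw
the same way.  Two significance measures are reported: a z/t-style comparison
of n against the null sample's mean and SD (the conventional normal-theory
reading of an empirical randomization test) and the exact empirical two-tailed
p-value, which is the statistically preferred quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


def contingency_chi2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 table, no continuity correction.

    Returns (chi2, p); (nan, nan) when a margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or t.sum() == 0:
        raise ValueError("need a non-negative 2x2 table with positive total")
    rows, cols, total = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        return float("nan"), float("nan")
    expected = np.outer(rows, cols) / total
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2_stat = float((diff**2 / expected).sum())
    from scipy.stats import chi2 as chi2_dist

    return chi2_stat, float(chi2_dist.sf(chi2_stat, df=1))


def pos_neg_ratio(n_positive: float, n_negative: float) -> float:
    """Ratio of positively to negatively selected sites within a class."""
    if n_negative <= 0:
        raise ZeroDivisionError("undefined ratio: no negatively selected sites")
    return n_positive / n_negative


@dataclass
class EnrichmentResult:
    label: str
    N: int  # codon sites in scope
    n_observed: int  # selected sites of the tested type in scope
    null_median: float
    null_mean: float
    null_sd: float
    ratio_obs_over_median: float
    p_t: float  # z/t-style two-tailed p against the null sample moments
    p_empirical: float  # exact two-tailed empirical p
    reps: int
    significant: bool = False


def _null_counts(
    n_type_total: int,
    universe_size: int,
    scope_size: int,
    reps: int,
    rng: np.random.Generator,
    replace: bool,
) -> np.ndarray:
    if replace:
        return rng.binomial(scope_size, n_type_total / universe_size, size=reps)
    return rng.hypergeometric(n_type_total, universe_size - n_type_total, scope_size, size=reps)


def randomization_enrichment(
    calls: np.ndarray,
    scope_mask: np.ndarray,
    site_type: str,
    reps: int = 10_000,
    seed: int = 0,
    replace: bool = False,
    alpha: float = 0.001,
) -> EnrichmentResult:
    """Randomization test for enrichment of a call type inside a codon scope.

    ``calls`` is the pooled per-codon call vector over all genes; ``scope_mask``
    is boolean over the same universe (e.g. codons in disordered regions).
    ``reps`` re-samples of N = scope size codons from the whole universe give
    the empirical null for the number of ``site_type`` sites.
    """
    calls = np.asarray(calls)
    scope_mask = np.asarray(scope_mask, dtype=bool)
    if calls.shape != scope_mask.shape:
        raise ValueError("calls and scope mask must align")
    n_scope = int(scope_mask.sum())
    if n_scope == 0:
        raise ValueError("empty scope")
    if reps < 100:
        import warnings

        warnings.warn(f"reps={reps} is very low for an empirical null", stacklevel=2)
    is_type = calls == site_type
    k_total = int(is_type.sum())
    n_obs = int((is_type & scope_mask).sum())
    rng = np.random.default_rng(seed)
    null = _null_counts(k_total, len(calls), n_scope, reps, rng, replace)
    med = float(np.median(null))
    mean, sd = float(null.mean()), float(null.std())
    ratio = n_obs / med if med > 0 else float("nan")
    if sd > 0:
        z = (n_obs - mean) / sd
        p_t = float(2 * norm.sf(abs(z)))
    else:
        p_t = 1.0 if n_obs == mean else 0.0
    p_emp = float((np.sum(np.abs(null - med) >= abs(n_obs - med)) + 1) / (reps + 1))
    return EnrichmentResult(
        site_type, n_scope, n_obs, med, mean, sd, ratio, p_t, p_emp, reps,
        significant=p_emp <= alpha,
    )


def category_enrichment(
    category_table: pd.DataFrame,
    gene_calls: dict[str, np.ndarray],
    site_type: str,
    reps: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    replace: bool = False,
) -> list[EnrichmentResult]:
    """Per-category randomization enrichment of selected sites.

    ``category_table`` has columns gene_id, catalogue, category_id,
    category_name; the codon universe pools every annotated gene once.
    Categories with no codons are skipped.
    """
    annotated = [g for g in dict.fromkeys(category_table["gene_id"]) if g in gene_calls]
    if not annotated:
        raise ValueError("no annotated genes with call data")
    universe = np.concatenate([np.asarray(gene_calls[g]) for g in annotated])
    offsets = {}
    pos = 0
    for g in annotated:
        offsets[g] = (pos, pos + len(gene_calls[g]))
        pos += len(gene_calls[g])
    rng = np.random.default_rng(seed)
    results = []
    grouped = category_table.groupby(["catalogue", "category_id"], sort=True)
    for (catalogue, cat_id), sub in grouped:
        genes = [g for g in dict.fromkeys(sub["gene_id"]) if g in offsets]
        scope = np.zeros(len(universe), dtype=bool)
        for g in genes:
            a, b = offsets[g]
            scope[a:b] = True
        if not scope.any():
            continue
        res = randomization_enrichment(
            universe, scope, site_type, reps=reps,
            seed=int(rng.integers(2**31)), replace=replace, alpha=alpha,
        )
        name = str(sub["category_name"].iloc[0])
        res.label = f"{catalogue}:{cat_id}:{name}"
        results.append(res)
    return results


def category_idr_rank(
    category_table: pd.DataFrame,
    masks: dict[str, np.ndarray],
    cls: str = "idr",
) -> pd.DataFrame:
    """Categories ranked by the mean per-protein fraction of a class.

    Returns a DataFrame (catalogue, category_id, category_name, mean_fraction,
    n_proteins) in descending mean-fraction order, ties broken lexicographically
    by category id.  Categories with no mask-bearing members are skipped.
    """
    rows = []
    for (catalogue, cat_id), sub in category_table.groupby(["catalogue", "category_id"], sort=True):
        fracs = []
        for g in dict.fromkeys(sub["gene_id"]):
            if g in masks:
                classes = np.asarray(masks[g], dtype=object)
                fracs.append(float(np.mean(classes == cls)))
        if not fracs:
            continue
        rows.append(
            {
                "catalogue": catalogue,
                "category_id": cat_id,
                "category_name": str(sub["category_name"].iloc[0]),
                "mean_fraction": float(np.mean(fracs)),
                "n_proteins": len(fracs),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        ["mean_fraction", "category_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
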