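"""End-to-end orchestration: fixture generation, staged analysis, table output.

``make_fixture`` writes a complete synthetic input set (per-gene FASTA codon
alignments, structure-confidence tracks, truth tracks, functional-site sets,
a gene-category table and an empty recombination blacklist).  ``run_all``
drives the analysis stages in order - QC funnel, conformational masks, FEL
site tests, class-frequency and ratio tables, randomization panels, per-gene
and composite MK/FI, sliding-window correlation censuses, the functional-
sites index sweep, and category enrichment/ranking - writing one TSV per
stage plus a JSON manifest of every parameter and derived seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import (
    CodonAlignment,
    filter_gene_set,
    gc_content,
    mask_low_frequency_polymorphisms,
    read_codon_alignment,
)
from .enrich import (
    category_enrichment,
    category_idr_rank,
    contingency_chi2,
    randomization_enrichment,
)
from .fel import classify_gene_sites, fel_scan
from .limacs import FunctionalSiteSet, index_threshold_sweep, read_site_sets, write_site_sets
from .mk import composite_mk, mk_test, remove_fi_outliers
from .simulate import ProteomeConfig, SyntheticGene, generate_proteome, write_truth_track
from .structure import call_classes, read_disorder_track, read_ss_track
from .windows import (
    genewise_correlation_census,
    sliding_window_fi_series,
    sliding_window_selection_series,
    spearman_significance,
)

CLASS_LABELS = ("helix", "strand", "idr")


@dataclass
class RunConfig:
    """All thresholds and paths of one analysis run."""

    fixture_dir: str = "fixture"
    out_dir: str = "results"
    seed: int = 0
    identity_threshold: float = 0.7
    ss_cutoff: int = 8
    idr_cutoff: float = 0.8
    idr_cutoff_liberal: float = 0.5
    fel_p: float = 0.1
    mk_alpha: float = 0.05
    category_alpha: float = 0.01
    enrichment_alpha: float = 0.001
    min_region: int = 30
    window: int = 25
    minor_freq: float = 0.15
    reps: int = 10_000
    limacs_cutoffs: tuple = (0.3, 0.5, 0.8, 0.9)

    def validate(self) -> None:
        assert 0 <= self.identity_threshold <= 1
        assert 0 <= self.ss_cutoff <= 9
        assert 0 < self.idr_cutoff <= 1 and 0 < self.idr_cutoff_liberal <= 1
        assert 0 < self.fel_p < 1 and 0 < self.mk_alpha < 1 and 0 < self.category_alpha < 1
        assert self.window >= 1 and self.min_region >= 1
        assert 0 <= self.minor_freq < 0.5
        assert self.reps >= 100


# -- fixture writing -----------------------------------------------------------
_CATEGORY_POOL = [
    ("funcat", "01", "metabolism", "low"),
    ("funcat", "02", "energy_fermentation", "low"),
    ("funcat", "10", "dna_replication_repair", "high"),
    ("funcat", "11", "transcription", "high"),
    ("funcat", "14", "protein_folding", "low"),
    ("funcat", "30", "cell_signalling", "high"),
    ("funcat", "32", "detoxification", "low"),
    ("funcat", "34", "morphogenesis_mating", "high"),
    ("proteincat", "E1", "hydrolase", "low"),
    ("proteincat", "E2", "transferase", "low"),
    ("proteincat", "T1", "zinc_finger_tf", "high"),
    ("proteincat", "T2", "helix_turn_helix_tf", "high"),
]


def assign_categories(genes: list[SyntheticGene], seed: int) -> pd.DataFrame:
    """Gene-category table whose high-IDR categories attract high-IDR genes."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        idr_frac = float(np.mean(g.truth.classes == "idr"))
        for catalogue in ("funcat", "proteincat"):
            pool = [c for c in _CATEGORY_POOL if c[0] == catalogue]
            weights = np.array(
                [idr_frac + 0.05 if tier == "high" else (1 - idr_frac) + 0.05 for _, _, _, tier in pool]
            )
            weights = weights / weights.sum()
            pick = pool[rng.choice(len(pool), p=weights)]
            rows.append({"gene_id": g.gene_id, "catalogue": pick[0],
                         "category_id": pick[1], "category_name": pick[2]})
    return pd.DataFrame(rows)


def build_site_sets(genes: list[SyntheticGene], seed: int) -> list[FunctionalSiteSet]:
    """Domain regions (some shared across proteins) with their functional sites."""
    rng = np.random.default_rng(seed)
    out = []
    domain_serial = 0
    shared: list[tuple[str, int]] = []  # (domain_id, length) reusable across proteins
    for g in genes:
        n = g.truth.n_codons
        for _ in range(int(rng.integers(1, 3))):
            if shared and rng.random() < 0.3:  # duplicate an existing domain family
                dom_id, length = shared[int(rng.integers(len(shared)))]
            else:
                domain_serial += 1
                dom_id = f"DOM{domain_serial:04d}"
                length = int(rng.integers(40, 120))
                shared.append((dom_id, length))
            length = min(length, n)
            start = int(rng.integers(0, n - length + 1))
            sites = {p for p in g.functional_sites if start <= p < start + length}
            out.append(FunctionalSiteSet(g.gene_id, dom_id, start, start + length, sites))
    return out


def make_fixture(outdir: str | Path, seed: int, cfg: ProteomeConfig | None = None):
    """Generate and write the complete synthetic input set for a run."""
    cfg = cfg or ProteomeConfig()
    outdir = Path(outdir)
    for sub in ("alignments", "tracks", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    tree, genes = generate_proteome(cfg, seed)
    species_lines = [f"{n}\t{tree.species_of[n]}" for n in tree.tree.leaf_names]
    (outdir / "species_map.tsv").write_text("\n".join(species_lines) + "\n")
    (outdir / "tree.nwk").write_text(tree.tree.to_newick() + "\n")
    (outdir / "blacklist.txt").write_text("")
    for g in genes:
        g.alignment.write_fasta(outdir / "alignments" / f"{g.gene_id}.fasta")
        g.ss_track.to_csv(outdir / "tracks" / f"{g.gene_id}.ss.tsv", sep="\t", index=False)
        g.disorder_track.to_csv(outdir / "tracks" / f"{g.gene_id}.dis.tsv", sep="\t", index=False)
        g.truth.functional_sites = g.functional_sites
        write_truth_track(g.truth, outdir / "truth" / f"{g.gene_id}.truth.tsv")
    ss_seed = np.random.SeedSequence(seed).spawn(4)
    sites = build_site_sets(genes, int(ss_seed[2].generate_state(1)[0] % 2**31))
    write_site_sets(sites, outdir / "site_sets.tsv")
    cats = assign_categories(genes, int(ss_seed[3].generate_state(1)[0] % 2**31))
    cats.to_csv(outdir / "categories.tsv", sep="\t", index=False)
    manifest = {"seed": seed, "config": asdict(cfg) | {"omega_by_class": {k: list(v) for k, v in cfg.omega_by_class.items()}},
                "n_genes": len(genes), "strains": list(tree.tree.leaf_names)}
    (outdir / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return tree, genes, sites, cats


# -- analysis ------------------------------------------------------------------
@dataclass
class GeneInput:
    gene_id: str
    alignment: CodonAlignment
    ss_track: pd.DataFrame
    disorder_track: pd.DataFrame


@dataclass
class ProteomeResults:
    qc: pd.DataFrame
    masks: dict[str, np.ndarray]
    masks_liberal: dict[str, np.ndarray]
    sites: pd.DataFrame
    class_stats: pd.DataFrame
    randomization: pd.DataFrame
    fi_genes: pd.DataFrame
    composite_fi: pd.DataFrame
    correlations: pd.DataFrame
    census: pd.DataFrame
    limacs_sweep: pd.DataFrame | None
    category_enrichment: pd.DataFrame | None
    category_rank: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def load_fixture_inputs(fixture_dir: str | Path) -> tuple[list[GeneInput], list, pd.DataFrame, set]:
    fixture_dir = Path(fixture_dir)
    inputs = []
    for fasta in sorted((fixture_dir / "alignments").glob("*.fasta")):
        gid = fasta.stem
        aln = read_codon_alignment(fasta, gene_id=gid)
        ss = read_ss_track(fixture_dir / "tracks" / f"{gid}.ss.tsv")
        dis = read_disorder_track(fixture_dir / "tracks" / f"{gid}.dis.tsv")
        inputs.append(GeneInput(gid, aln, ss, dis))
    sites = read_site_sets(fixture_dir / "site_sets.tsv") if (fixture_dir / "site_sets.tsv").exists() else []
    cats_path = fixture_dir / "categories.tsv"
    cats = pd.read_csv(cats_path, sep="\t", dtype=str) if cats_path.exists() else pd.DataFrame()
    bl_path = fixture_dir / "blacklist.txt"
    blacklist = {ln.strip() for ln in bl_path.read_text().splitlines() if ln.strip()} if bl_path.exists() else set()
    return inputs, sites, cats, blacklist


def analyze(
    inputs: list[GeneInput],
    config: RunConfig,
    site_sets: list | None = None,
    categories: pd.DataFrame | None = None,
    blacklist: set | None = None,
) -> ProteomeResults:
    """Run every analysis stage on in-memory gene inputs."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # stage 1: QC funnel
    alignments = [g.alignment for g in inputs]
    kept, reports = filter_gene_set(alignments, config.identity_threshold, blacklist or set())
    kept_ids = {a.gene_id for a in kept}
    qc = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in reports],
            "identity": [r.mean_pairwise_protein_identity for r in reports],
            "passed": [r.passed_threshold for r in reports],
            "reason": [r.excluded_reason for r in reports],
            "gc_content": [gc_content(a.rows[0].seq) for a in alignments],
        }
    )
    by_id = {g.gene_id: g for g in inputs}

    # stage 2: conformational masks at strict and liberal disorder cutoffs
    masks, masks_lib = {}, {}
    for gid in sorted(kept_ids):
        g = by_id[gid]
        masks[gid] = call_classes(g.ss_track, g.disorder_track, config.ss_cutoff,
                                  config.idr_cutoff, gid).classes
        masks_lib[gid] = call_classes(g.ss_track, g.disorder_track, config.ss_cutoff,
                                      config.idr_cutoff_liberal, gid).classes

    # stage 3: FEL site tests on the raw alignments
    site_rows = []
    calls_by_gene: dict[str, np.ndarray] = {}
    for aln in kept:
        results = fel_scan(aln, p_threshold=config.fel_p)
        calls_by_gene[aln.gene_id] = np.array([r.call for r in results], dtype=object)
        for r in results:
            site_rows.append(
                {"gene_id": r.gene_id, "codon": r.codon_index + 1, "alpha": r.alpha,
                 "beta": r.beta, "lrt": r.lrt, "p": r.p_value, "call": r.call}
            )
    sites_df = pd.DataFrame(site_rows)

    # stage 4: class frequencies, positive/negative ratios, chi-square contrasts
    pooled_calls, pooled_classes = [], []
    for gid in sorted(kept_ids):
        n = min(len(calls_by_gene[gid]), len(masks[gid]))
        pooled_calls.append(calls_by_gene[gid][:n])
        pooled_classes.append(np.asarray(masks[gid][:n], dtype=object))
    calls_vec = np.concatenate(pooled_calls)
    classes_vec = np.concatenate(pooled_classes)
    class_rows = []
    counts = {}
    for cls in CLASS_LABELS:
        in_cls = classes_vec == cls
        n_pos = int(np.sum((calls_vec == "positive") & in_cls))
        n_neg = int(np.sum((calls_vec == "negative") & in_cls))
        n_tot = int(in_cls.sum())
        counts[cls] = (n_pos, n_neg, n_tot)
        class_rows.append(
            {"class": cls, "n_codons": n_tot, "n_positive": n_pos, "n_negative": n_neg,
             "freq_positive": n_pos / n_tot if n_tot else math.nan,
             "freq_negative": n_neg / n_tot if n_tot else math.nan,
             "pos_neg_ratio": n_pos / n_neg if n_neg else math.nan}
        )
    # IDR vs pooled regular structure contrast on positive-site frequency
    pos_idr, neg_idr, tot_idr = counts["idr"]
    pos_struct = counts["helix"][0] + counts["strand"][0]
    neg_struct = counts["helix"][1] + counts["strand"][1]
    tot_struct = counts["helix"][2] + counts["strand"][2]
    for site_label, a, b in (
        ("positive", (pos_idr, tot_idr - pos_idr), (pos_struct, tot_struct - pos_struct)),
        ("negative", (neg_idr, tot_idr - neg_idr), (neg_struct, tot_struct - neg_struct)),
    ):
        try:
            chi2_stat, p = contingency_chi2([list(a), list(b)])
        except ValueError:
            chi2_stat, p = math.nan, math.nan
        class_rows.append(
            {"class": f"idr_vs_structured_{site_label}", "n_codons": tot_idr + tot_struct,
             "n_positive": a[0], "n_negative": b[0], "freq_positive": math.nan,
             "freq_negative": math.nan, "pos_neg_ratio": math.nan,
             "chi2": chi2_stat, "chi2_p": p}
        )
    class_stats = pd.DataFrame(class_rows)

    # stage 5: randomization enrichment panels per class x site type
    rand_rows = []
    for cls in CLASS_LABELS:
        scope = classes_vec == cls
        if not scope.any():
            continue
        for site_type in ("positive", "negative"):
            res = randomization_enrichment(
                calls_vec, scope, site_type, reps=config.reps,
                seed=int(rng.integers(2**31)), alpha=config.enrichment_alpha,
            )
            rand_rows.append(
                {"class": cls, "site_type": site_type, "N": res.N, "n_observed": res.n_observed,
                 "null_median": res.null_median, "ratio": res.ratio_obs_over_median,
                 "p_t": res.p_t, "p_empirical": res.p_empirical, "significant": res.significant}
            )
    randomization = pd.DataFrame(rand_rows)

    # stage 6: per-gene MK on low-frequency-masked alignments; composite MK
    masked = {aln.gene_id: mask_low_frequency_polymorphisms(aln, config.minor_freq) for aln in kept}
    fi_rows = []
    for gid in sorted(kept_ids):
        res = mk_test(masked[gid], alpha=config.mk_alpha)
        c = res.counts
        fi_rows.append(
            {"gene_id": gid, "dN": c.dN, "dS": c.dS, "pN": c.pN, "pS": c.pS,
             "fi": res.fi, "fisher_p": res.fisher_p, "call": res.call,
             "idr_fraction": float(np.mean(np.asarray(masks[gid], dtype=object) == "idr")),
             "structured_fraction": float(np.mean(np.isin(np.asarray(masks[gid], dtype=object), ("helix", "strand")))),
             "gc_content": float(qc.loc[qc.gene_id == gid, "gc_content"].iloc[0])}
        )
    fi_genes = pd.DataFrame(fi_rows)
    defined_fi = fi_genes["fi"].dropna()
    kept_fi = remove_fi_outliers(list(defined_fi))
    outlier_genes = set(fi_genes.loc[~fi_genes["fi"].isin(kept_fi) & fi_genes["fi"].notna(), "gene_id"])
    composite_rows = []
    for label, mask_set in (("strict", masks), ("liberal", masks_lib)):
        for cls in CLASS_LABELS:
            for filtered in (False, True):
                gene_list = [masked[g] for g in sorted(kept_ids) if not (filtered and g in outlier_genes)]
                try:
                    res = composite_mk(gene_list, mask_set, cls, alpha=config.mk_alpha)
                except ValueError:
                    continue
                c = res.counts
                composite_rows.append(
                    {"idr_cutoff": label, "class": cls, "outliers_removed": filtered,
                     "dN": c.dN, "dS": c.dS, "pN": c.pN, "pS": c.pS,
                     "fi": res.fi, "fisher_p": res.fisher_p, "call": res.call}
                )
    composite_fi = pd.DataFrame(composite_rows)

    # stage 7: gene-level correlations among FI, disorder content, and G+C
    sig = fi_genes[(fi_genes["call"] != "none") & fi_genes["fi"].notna()]
    corr_rows = []
    for label, frame, xcol, ycol in (
        ("fi_vs_idr_fraction", sig, "idr_fraction", "fi"),
        ("fi_vs_structured_fraction", sig, "structured_fraction", "fi"),
        ("fi_vs_gc", sig, "gc_content", "fi"),
        ("idr_fraction_vs_gc", fi_genes, "gc_content", "idr_fraction"),
    ):
        if len(frame) >= 3:
            v = spearman_significance(frame[xcol].to_numpy(), frame[ycol].to_numpy())
            corr_rows.append({"pair": label, "rs": v.rs, "n": v.n, "method": v.method,
                              "p": v.p, "significant": v.significant})
        else:
            corr_rows.append({"pair": label, "rs": math.nan, "n": len(frame),
                              "method": "not_assessed", "p": math.nan, "significant": False})
    correlations = pd.DataFrame(corr_rows)

    # stage 8: sliding-window censuses (selection counts and window FI)
    sel_series, fi_series = [], []
    for gid in sorted(kept_ids):
        sel_series.append(
            sliding_window_selection_series(calls_by_gene[gid], masks[gid], gid, config.window)
        )
        fi_series.append(sliding_window_fi_series(masked[gid], masks[gid], config.window))
    census = pd.DataFrame(
        [
            {"series": "selection_vs_idr", **dict(zip(("n_positive_significant", "n_negative_significant"),
                                                      genewise_correlation_census(sel_series)))},
            {"series": "fi_vs_idr", **dict(zip(("n_positive_significant", "n_negative_significant"),
                                               genewise_correlation_census(fi_series)))},
        ]
    )

    # stage 9: functional-sites index sweep
    limacs_sweep = None
    if site_sets:
        ss_tracks = {g.gene_id: g.ss_track for g in inputs if g.gene_id in kept_ids}
        dis_tracks = {g.gene_id: g.disorder_track for g in inputs if g.gene_id in kept_ids}
        usable = [s for s in site_sets if s.protein_id in kept_ids]
        sweeps = []
        for dedupe in (False, True):
            df = index_threshold_sweep(usable, ss_tracks, dis_tracks,
                                       list(config.limacs_cutoffs), dedupe_domains=dedupe,
                                       ss_cutoff=config.ss_cutoff)
            df["dedupe"] = dedupe
            sweeps.append(df)
        limacs_sweep = pd.concat(sweeps, ignore_index=True)

    # stage 10: category enrichment and IDR rank
    cat_enrich_df = cat_rank = None
    if categories is not None and len(categories):
        cats_kept = categories[categories["gene_id"].isin(kept_ids)]
        rows = []
        for site_type in ("positive", "negative"):
            for res in category_enrichment(cats_kept, calls_by_gene, site_type,
                                           reps=config.reps, alpha=config.category_alpha,
                                           seed=int(rng.integers(2**31))):
                rows.append({"category": res.label, "site_type": site_type, "N": res.N,
                             "n_observed": res.n_observed, "null_median": res.null_median,
                             "ratio": res.ratio_obs_over_median, "p_t": res.p_t,
                             "p_empirical": res.p_empirical, "significant": res.significant})
        cat_enrich_df = pd.DataFrame(rows)
        cat_rank = category_idr_rank(cats_kept, masks)

    manifest = {
        "config": asdict(config),
        "n_genes_in": len(inputs),
        "n_genes_kept": len(kept_ids),
        "n_positive_sites": int(np.sum(calls_vec == "positive")),
        "n_negative_sites": int(np.sum(calls_vec == "negative")),
    }
    return ProteomeResults(qc, masks, masks_lib, sites_df, class_stats, randomization,
                           fi_genes, composite_fi, correlations, census, limacs_sweep,
                           cat_enrich_df, cat_rank, manifest)


def write_results(results: ProteomeResults, outdir: str | Path, config: RunConfig) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "qc.tsv": results.qc,
        "sites.tsv": results.sites,
        "class_stats.tsv": results.class_stats,
        "randomization.tsv": results.randomization,
        "fi_genes.tsv": results.fi_genes,
        "composite_fi.tsv": results.composite_fi,
        "correlations.tsv": results.correlations,
        "census.tsv": results.census,
    }
    if results.limacs_sweep is not None:
        tables["limacs_sweep.tsv"] = results.limacs_sweep
    if results.category_enrichment is not None:
        tables["category_enrichment.tsv"] = results.category_enrichment
        tables["category_idr_rank.tsv"] = results.category_rank
    header = f"# seed={config.seed}\n"
    for name, df in tables.items():
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        written.append(name)
    (outdir / "manifest.json").write_text(json.dumps(results.manifest, indent=2, default=str))
    written.append("manifest.json")
    return written


def run_all(config: RunConfig) -> ProteomeResults:
    """File-driven pipeline: read a fixture directory, analyze, write tables."""
    inputs, site_sets, categories, blacklist = load_fixture_inputs(config.fixture_dir)
    results = analyze(inputs, config, site_sets, categories, blacklist)
    write_results(results, config.out_dir, config)
    return results
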