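"""Synthetic two-species strain panels with known selective and structural truth.

The generator emulates the inputs of a yeast-style strain resequencing study:
a panel of strains from each of two diverged species, per-gene in-frame codon
alignments carrying both within-species polymorphism and between-species
fixed differences, per-residue structure-confidence tracks, functional-site
placements, and gene category tables.  Sequences evolve under MG94xHKY85 on a
two-clade strain tree; each codon site carries its own dN/dS ratio omega, and
a separate omega may be assigned to the two inter-species stem branches so
that fixation (divergence) and polymorphism can be given different selective
regimes - the contrast the McDonald-Kreitman test is designed to detect.

The simulator encodes the inference model's own assumptions (no indels, no
recombination, uniform codon frequencies by default), not yeast biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentRow, CodonAlignment
from .codons import (
    CodonModel,
    EigenDecomposition,
    SENSE_CODONS,
    translate_codon,
    uniform_position_frequencies,
)
from .trees import PhyloTree, StrainTree

CLASSES = ("helix", "strand", "idr", "none")


@dataclass
class TruthTrack:
    """Ground truth for one simulated gene.

    ``omega`` applies on within-species branches (polymorphism), and
    ``omega_divergence`` (defaulting to ``omega``) on the two stem branches
    separating the species clades (fixed differences).
    """

    omega: np.ndarray
    classes: np.ndarray  # per-residue: helix | strand | idr | none
    functional_sites: set[int] = field(default_factory=set)
    kappa: float = 2.0
    omega_divergence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if len(self.omega) != len(self.classes):
            raise ValueError("omega and class tracks must have equal length")
        if len(self.omega) == 0:
            raise ValueError("empty truth track")
        if not np.all(np.isfinite(self.omega)) or np.any(self.omega <= 0):
            raise ValueError("omega must be finite and positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega_divergence is None:
            self.omega_divergence = self.omega.copy()
        else:
            self.omega_divergence = np.asarray(self.omega_divergence, dtype=float)
            if len(self.omega_divergence) != len(self.omega):
                raise ValueError("divergence omega track length mismatch")

    @property
    def n_codons(self) -> int:
        return len(self.omega)


def make_two_clade_tree(
    n_a: int,
    n_b: int,
    within_depth: float,
    between_depth: float,
    seed: int,
    species: tuple[str, str] = ("scer", "spar"),
) -> StrainTree:
    """Random strain phylogeny with one ultrametric clade per species.

    Each clade has root-to-tip depth ``within_depth``; the two clade roots are
    joined through the global root by branches of length ``between_depth``
    each (separation 2 x between_depth).  Topologies are random coalescent
    joins.  Lengths are expected substitutions per codon site for a neutral
    site.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 strains per species for polymorphism")
    if within_depth < 0 or between_depth < 0:
        raise ValueError("depths must be non-negative")
    if between_depth < within_depth:
        raise ValueError("between_depth must be >= within_depth")
    rng = np.random.default_rng(seed)
    names = [f"{species[0]}_{i + 1}" for i in range(n_a)] + [
        f"{species[1]}_{i + 1}" for i in range(n_b)
    ]
    n_total = n_a + n_b
    parent = [-1] * n_total
    lengths = [0.0] * n_total
    heights = {}

    def build_clade(leaf_ids: list[int]) -> int:
        k = len(leaf_ids)
        if k == 1:
            heights[leaf_ids[0]] = 0.0
            return leaf_ids[0]
        joins = np.sort(rng.uniform(0.0, within_depth, size=k - 2)) if k > 2 else np.array([])
        joins = np.concatenate([joins, [within_depth]])
        active = list(leaf_ids)
        for lf in leaf_ids:
            heights[lf] = 0.0
        for h in joins:
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
            a, b = active[i], active[j]
            new = len(parent)
            parent.append(-1)
            lengths.append(0.0)
            heights[new] = float(h)
            for child in (a, b):
                parent[child] = new
                lengths[child] = float(h) - heights[child]
            active = [x for x in active if x not in (a, b)] + [new]
        return active[0]

    root_a = build_clade(list(range(n_a)))
    root_b = build_clade(list(range(n_a, n_total)))
    root = len(parent)
    parent.append(-1)
    lengths.append(0.0)
    for clade_root in (root_a, root_b):
        parent[clade_root] = root
        lengths[clade_root] = float(between_depth)
    tree = PhyloTree(names, np.asarray(parent), np.asarray(lengths))
    species_of = {n: (species[0] if i < n_a else species[1]) for i, n in enumerate(names)}
    return StrainTree(tree, species_of)


def simulate_gene(
    strain_tree: StrainTree,
    truth: TruthTrack,
    seed: int,
    gene_id: str = "gene",
    pos_freqs: np.ndarray | None = None,
) -> CodonAlignment:
    """Forward-simulate one gene along the strain tree.

    The root sequence is drawn from the stationary codon distribution and
    evolves by MG94xHKY85 with the per-site omega of ``truth``; the two
    branches joining the species clades use ``truth.omega_divergence``.  The
    result is a gap-free, stop-free in-frame alignment.  The root codon
    sequence and the derived seed are recorded in ``meta``.
    """
    tree = strain_tree.tree
    model = CodonModel(truth.kappa, pos_freqs if pos_freqs is not None else uniform_position_frequencies())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_sites = truth.n_codons

    decomps: dict[float, EigenDecomposition] = {}

    def decomp(omega: float) -> EigenDecomposition:
        if omega not in decomps:
            decomps[omega] = EigenDecomposition(model.generator(1.0, omega), model.pi)
        return decomps[omega]

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(len(SENSE_CODONS), size=n_sites, p=model.pi)
    stem_nodes = set(tree.children[tree.root])
    for v in tree.preorder:
        if v == tree.root:
            continue
        track = truth.omega_divergence if v in stem_nodes else truth.omega
        t = tree.lengths[v]
        par = states[tree.parent[v]]
        if t == 0.0:
            states[v] = par
            continue
        out = np.empty(n_sites, dtype=np.int64)
        for omega in np.unique(track):
            idx = np.flatnonzero(track == omega)
            p = decomp(float(omega)).prob_matrix(t)
            rows = p[par[idx]]
            rows /= rows.sum(axis=1, keepdims=True)
            u = rng.random(len(idx))
            out[idx] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
        states[v] = out

    codon_arr = np.array(SENSE_CODONS)
    rows = [
        AlignmentRow(
            name,
            strain_tree.species_of[name],
            "".join(codon_arr[states[i]]),
        )
        for i, name in enumerate(tree.leaf_names)
    ]
    root_seq = "".join(codon_arr[states[tree.root]])
    meta = {"root_sequence": root_seq, "seed": int(seed), "kappa": truth.kappa}
    return CodonAlignment(gene_id, rows, meta)


def emit_confidence_tracks(
    truth: TruthTrack,
    noise_flip_prob: float,
    seed: int,
    protein_seq: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue structure-confidence files for one protein.

    Returns a PSIPRED-style table (0-based index, residue, state H/E/C,
    integer confidence 0-9) and a VSL2-style table (index, residue, disorder
    score in [0, 1]).  With probability 1 - noise_flip_prob a truly structured
    residue receives confidence >= 8 (otherwise < 8) and a truly disordered
    residue a score >= 0.8 (otherwise < 0.5); non-members are scored on the
    opposite side of the cutoffs likewise.
    """
    if not 0 <= noise_flip_prob < 0.5:
        raise ValueError("noise_flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = truth.n_codons
    if protein_seq is None:
        protein_seq = "X" * n
    states, confs, scores = [], [], []
    for i, cls in enumerate(truth.classes):
        flip_ss = rng.random() < noise_flip_prob
        flip_dis = rng.random() < noise_flip_prob
        if cls == "helix":
            states.append("H")
            confs.append(int(rng.integers(8, 10)) if not flip_ss else int(rng.integers(0, 8)))
        elif cls == "strand":
            states.append("E")
            confs.append(int(rng.integers(8, 10)) if not flip_ss else int(rng.integers(0, 8)))
        else:
            states.append("C")
            confs.append(int(rng.integers(0, 10)))
        truly_idr = cls == "idr"
        high = truly_idr != flip_dis
        scores.append(rng.uniform(0.8, 1.0) if high else rng.uniform(0.0, 0.5))
    ss = pd.DataFrame(
        {"index": np.arange(n), "residue": list(protein_seq), "state": states, "conf": confs}
    )
    dis = pd.DataFrame(
        {"index": np.arange(n), "residue": list(protein_seq), "score": np.round(scores, 4)}
    )
    return ss, dis


def place_functional_sites(
    truth: TruthTrack, rate_idr: float, rate_other: float, seed: int
) -> set[int]:
    """Bernoulli functional-site placement with a class-dependent per-residue rate."""
    if not (0 <= rate_idr <= 1 and 0 <= rate_other <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.random(truth.n_codons)
    rates = np.where(truth.classes == "idr", rate_idr, rate_other)
    return set(np.flatnonzero(u < rates).tolist())


# -- proteome-scale fixtures --------------------------------------------------
@dataclass
class ProteomeConfig:
    """Study conditions for a synthetic proteome.

    Defaults mirror the strain-panel scale of a two-species yeast resequencing
    panel (37 + 27 strains), 200 genes of 100-500 codons, about 23% of
    residues in disordered segments, and a fifth of genes carrying an
    adaptive (omega > 1) segment.  ``omega_by_class`` maps each conformation
    class to its (polymorphism omega, divergence omega) pair for background
    sites; adaptive segments override both with ``omega_adaptive``.
    """

    n_a: int = 37
    n_b: int = 27
    within_depth: float = 0.01
    between_depth: float = 0.15
    n_genes: int = 200
    min_codons: int = 100
    max_codons: int = 500
    kappa: float = 2.0
    idr_fraction: float = 0.23
    helix_fraction: float = 0.26
    strand_fraction: float = 0.06
    frac_adaptive_genes: float = 0.2
    omega_adaptive: tuple[float, float] = (4.0, 4.0)  # (polymorphism, divergence)
    adaptive_segment_length: int = 30
    adaptive_in_idr: bool = True
    omega_by_class: dict = field(
        default_factory=lambda: {
            "helix": (0.2, 0.2),
            "strand": (0.2, 0.2),
            "idr": (0.2, 0.2),
            "none": (0.2, 0.2),
        }
    )
    site_rate_idr: float = 0.05
    site_rate_other: float = 0.025
    track_noise: float = 0.0


def _mean_run(cls: str) -> float:
    # typical segment lengths: disordered runs long enough for the >=30 class
    return {"helix": 12.0, "strand": 6.0, "idr": 45.0, "none": 18.0}[cls]


def generate_truth(n_codons: int, cfg: ProteomeConfig, rng: np.random.Generator,
                   adaptive: bool = False) -> TruthTrack:
    """Segmental class track plus per-site omega for one gene.

    Class residues are budgeted per gene (quota = fraction x length) and laid
    out as shuffled runs with class-typical lengths, so even short genes
    realize approximately the configured composition.
    """
    p_none = max(1.0 - cfg.idr_fraction - cfg.helix_fraction - cfg.strand_fraction, 0.0)
    fractions = {"helix": cfg.helix_fraction, "strand": cfg.strand_fraction,
                 "idr": cfg.idr_fraction, "none": p_none}
    runs: list[tuple[str, int]] = []
    for cls, frac in fractions.items():
        remaining = int(round(frac * n_codons))
        while remaining > 0:
            run = min(remaining, 1 + int(rng.geometric(1.0 / _mean_run(cls))))
            runs.append((cls, run))
            remaining -= run
    rng.shuffle(runs)
    classes: list[str] = []
    for cls, run in runs:
        classes.extend([cls] * run)
    classes_arr = np.array(classes[:n_codons], dtype=object)
    if len(classes_arr) < n_codons:
        classes_arr = np.concatenate([classes_arr, np.array(["none"] * (n_codons - len(classes_arr)), dtype=object)])

    omega = np.empty(n_codons)
    omega_div = np.empty(n_codons)
    for cls, (om_p, om_d) in cfg.omega_by_class.items():
        m = classes_arr == cls
        omega[m] = om_p
        omega_div[m] = om_d
    if adaptive:
        length = min(cfg.adaptive_segment_length, n_codons)
        seg_mask = np.zeros(n_codons, dtype=bool)
        if cfg.adaptive_in_idr:
            # anchor the segment at the start of a disordered run (longest
            # first) so the planted signal sits squarely inside the class
            idr_runs = []
            i = 0
            while i < n_codons:
                if classes_arr[i] == "idr":
                    j = i
                    while j < n_codons and classes_arr[j] == "idr":
                        j += 1
                    idr_runs.append((j - i, i, j))
                    i = j
                else:
                    i += 1
            if idr_runs:
                _, start, end = max(idr_runs)
                seg_mask[start : min(start + length, end)] = True
            else:
                start = int(rng.integers(n_codons))
                seg_mask[start : start + length] = True
        else:
            start = int(rng.integers(n_codons))
            seg_mask[start : start + length] = True
        omega[seg_mask] = cfg.omega_adaptive[0]
        omega_div[seg_mask] = cfg.omega_adaptive[1]
    return TruthTrack(omega=omega, classes=classes_arr, kappa=cfg.kappa,
                      omega_divergence=omega_div)


@dataclass
class SyntheticGene:
    gene_id: str
    truth: TruthTrack
    alignment: CodonAlignment
    ss_track: pd.DataFrame
    disorder_track: pd.DataFrame
    functional_sites: set[int]


def generate_proteome(cfg: ProteomeConfig, seed: int) -> tuple[StrainTree, list[SyntheticGene]]:
    """Simulate a full synthetic proteome under one strain tree.

    A single integer seed drives a splittable generator; each gene's derived
    seed is recorded in its alignment metadata.
    """
    root_ss = np.random.SeedSequence(seed)
    tree_seed, gene_seed0 = (int(s.generate_state(1)[0] % 2**31) for s in root_ss.spawn(2))
    tree = make_two_clade_tree(cfg.n_a, cfg.n_b, cfg.within_depth, cfg.between_depth, tree_seed)
    genes = []
    child_seqs = np.random.SeedSequence(gene_seed0).spawn(cfg.n_genes)
    for g, ss_child in enumerate(child_seqs):
        sub = [int(s.generate_state(1)[0] % 2**31) for s in ss_child.spawn(4)]
        rng = np.random.default_rng(sub[0])
        n_codons = int(rng.integers(cfg.min_codons, cfg.max_codons + 1))
        adaptive = rng.random() < cfg.frac_adaptive_genes
        truth = generate_truth(n_codons, cfg, rng, adaptive=adaptive)
        gene_id = f"g{g + 1:04d}"
        aln = simulate_gene(tree, truth, sub[1], gene_id=gene_id)
        protein = "".join(translate_codon(aln.rows[0].seq[k:k + 3]) for k in range(0, aln.length_nt, 3))
        ss_track, dis_track = emit_confidence_tracks(truth, cfg.track_noise, sub[2], protein)
        sites = place_functional_sites(truth, cfg.site_rate_idr, cfg.site_rate_other, sub[3])
        genes.append(SyntheticGene(gene_id, truth, aln, ss_track, dis_track, sites))
    return tree, genes


def neutral_proteome_config(
    n_genes: int = 100,
    n_codons: int = 200,
    n_a: int = 8,
    n_b: int = 8,
) -> ProteomeConfig:
    """Neutral study conditions: omega = 1 at every site and on every branch.

    Divergence and within-species depths are set high enough (0.4 / 0.04
    expected substitutions per codon) that each gene accrues the tens of
    fixed differences and polymorphisms the MK ratio needs to be informative.
    """
    one = {c: (1.0, 1.0) for c in CLASSES}
    return ProteomeConfig(
        n_a=n_a, n_b=n_b, within_depth=0.04, between_depth=0.4,
        n_genes=n_genes, min_codons=n_codons, max_codons=n_codons,
        frac_adaptive_genes=0.0, omega_by_class=one,
    )


def contrast_proteome_config(
    n_genes: int = 36,
    n_codons: int = 120,
    n_a: int = 8,
    n_b: int = 8,
) -> ProteomeConfig:
    """Disorder-contrast study conditions.

    Structured classes evolve under purifying selection that suppresses
    fixation more strongly than polymorphism (omega 0.4 within species, 0.08
    on the inter-species stems, so their fixation index falls well below 1),
    the disordered background is mildly constrained and balanced (0.3 / 0.3),
    and every gene carries one adaptive disordered segment whose
    non-synonymous changes fix preferentially (omega 1 within species, 4 on
    the stems).  This is the regime in which positively selected codons
    concentrate in IDRs and the composite fixation index is highest for
    disordered regions, against the purifying structured classes.
    """
    return ProteomeConfig(
        n_a=n_a, n_b=n_b, within_depth=0.08, between_depth=0.8,
        n_genes=n_genes, min_codons=n_codons, max_codons=n_codons,
        idr_fraction=0.25,
        frac_adaptive_genes=1.0, omega_adaptive=(1.0, 4.0), adaptive_in_idr=True,
        omega_by_class={
            "helix": (0.4, 0.08),
            "strand": (0.4, 0.08),
            "idr": (0.3, 0.3),
            "none": (0.4, 0.08),
        },
    )


def write_truth_track(truth: TruthTrack, path) -> None:
    """TSV truth export: residue_index (0-based), class, omega, is_functional."""
    df = pd.DataFrame(
        {
            "residue_index": np.arange(truth.n_codons),
            "class": truth.classes,
            "omega": truth.omega,
            "is_functional": [int(i in truth.functional_sites) for i in range(truth.n_codons)],
        }
    )
    df.to_csv(path, sep="\t", index=False)
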