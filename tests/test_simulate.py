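import numpy as np
import pytest

from idrsel.codons import mutation_opportunities
from idrsel.simulate import (
    TruthTrack,
    emit_confidence_tracks,
    generate_proteome,
    make_two_clade_tree,
    neutral_proteome_config,
    place_functional_sites,
    simulate_gene,
)
from idrsel.structure import call_classes


def flat_truth(n, omega=1.0, cls="none", kappa=2.0):
    return TruthTrack(np.full(n, omega), np.array([cls] * n, dtype=object), kappa=kappa)


# -- strain trees --------------------------------------------------------------
def test_zero_within_depth_gives_star_clades():
    st = make_two_clade_tree(2, 2, 0.0, 0.1, seed=1)
    depths = st.tree.depths()
    assert np.allclose(depths[: st.tree.n_leaves], 0.1)
    # all within-clade branches have length 0
    stems = set(st.tree.children[st.tree.root])
    for v in range(st.tree.n_nodes):
        if v != st.tree.root and v not in stems:
            assert st.tree.lengths[v] == 0.0


def test_panel_scale_tree_has_right_clade_sizes():
    st = make_two_clade_tree(37, 27, 0.01, 0.15, seed=7)
    assert st.tree.n_leaves == 64
    by_species = {"scer": 0, "spar": 0}
    for name in st.tree.leaf_names:
        by_species[st.species_of[name]] += 1
    assert by_species == {"scer": 37, "spar": 27}


def test_root_to_tip_depths_match_path_traversal_oracle():
    st = make_two_clade_tree(3, 3, 0.02, 0.02, seed=2)
    tree = st.tree

    def path_length(leaf):  # explicit edge-sum over the root-to-leaf path
        total, v = 0.0, leaf
        while tree.parent[v] >= 0:
            total += tree.lengths[v]
            v = tree.parent[v]
        return total

    oracle = [path_length(v) for v in range(tree.n_leaves)]
    assert np.allclose(tree.depths()[: tree.n_leaves], oracle)
    assert np.allclose(oracle, 0.02 + 0.02)  # ultrametric at within+between


def test_tree_requires_two_strains_per_species():
    with pytest.raises(ValueError):
        make_two_clade_tree(1, 5, 0.01, 0.1, seed=0)


def test_tree_deterministic_given_seed():
    a = make_two_clade_tree(6, 4, 0.02, 0.2, seed=11).tree.to_newick()
    b = make_two_clade_tree(6, 4, 0.02, 0.2, seed=11).tree.to_newick()
    c = make_two_clade_tree(6, 4, 0.02, 0.2, seed=12).tree.to_newick()
    assert a == b
    assert a != c


# -- gene simulation -----------------------------------------------------------
def test_zero_branch_lengths_reproduce_root_sequence():
    st = make_two_clade_tree(3, 3, 0.0, 0.0, seed=5)
    aln = simulate_gene(st, flat_truth(40), seed=9)
    root = aln.meta["root_sequence"]
    assert all(r.seq == root for r in aln.rows)


def test_simulation_is_deterministic_and_seed_sensitive():
    st = make_two_clade_tree(3, 3, 0.02, 0.2, seed=1)
    truth = flat_truth(60)
    a = simulate_gene(st, truth, seed=42)
    b = simulate_gene(st, truth, seed=42)
    c = simulate_gene(st, truth, seed=43)
    assert [r.seq for r in a.rows] == [r.seq for r in b.rows]
    assert [r.seq for r in a.rows] != [r.seq for r in c.rows]


def test_alignment_is_gap_free_stop_free_in_frame():
    st = make_two_clade_tree(4, 3, 0.05, 0.5, seed=3)
    aln = simulate_gene(st, flat_truth(120, omega=2.0), seed=8)
    for r in aln.rows:
        assert "-" not in r.seq
        assert len(r.seq) == 360
    assert "*" not in "".join(aln.translated_rows())


def aa_of(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def test_neutral_simulation_opportunity_ratio():
    """Pooled non-synonymous/synonymous changes per opportunity ~ 1 at omega=1.

    Counted against the recorded root sequence on a two-clade star tree with
    kappa = 1, with opportunities from exhaustive single-mutation enumeration;
    only single-hit codons are classified (multiple hits are rare at this
    depth).
    """
    st = make_two_clade_tree(2, 2, 0.0, 0.12, seed=4)
    truth = flat_truth(3000, omega=1.0, kappa=1.0)
    aln = simulate_gene(st, truth, seed=77)
    root = aln.meta["root_sequence"]
    syn_opp = nonsyn_opp = 0.0
    for k in range(0, len(root), 3):
        s, n = mutation_opportunities(root[k : k + 3], kappa=1.0)
        syn_opp += s
        nonsyn_opp += n
    syn_changes = nonsyn_changes = 0
    for r in aln.rows:
        for k in range(0, len(root), 3):
            a, b = root[k : k + 3], r.seq[k : k + 3]
            ndiff = sum(x != y for x, y in zip(a, b))
            if ndiff == 1:
                if aa_of(a) == aa_of(b):
                    syn_changes += 1
                else:
                    nonsyn_changes += 1
    ratio = (nonsyn_changes / nonsyn_opp) / (syn_changes / syn_opp)
    assert 0.85 < ratio < 1.15


def test_adaptive_segment_elevates_nonsynonymous_density():
    n = 400
    omega = np.full(n, 0.1)
    omega[100:130] = 5.0
    truth = TruthTrack(omega, np.array(["none"] * n, dtype=object), kappa=2.0)
    st = make_two_clade_tree(2, 2, 0.0, 0.3, seed=6)
    aln = simulate_gene(st, truth, seed=13)
    root = aln.meta["root_sequence"]

    def nonsyn_changes(lo, hi):
        total = 0
        for r in aln.rows:
            for k in range(lo, hi):
                a, b = root[3 * k : 3 * k + 3], r.seq[3 * k : 3 * k + 3]
                if a != b and aa_of(a) != aa_of(b):
                    total += 1
        return total

    inside = nonsyn_changes(100, 130) / 30
    outside = nonsyn_changes(0, 100) / 100
    assert inside > 3 * outside


# -- confidence tracks ---------------------------------------------------------
def test_noiseless_tracks_round_trip_to_truth_classes():
    rng = np.random.default_rng(0)
    classes = np.array(rng.choice(["helix", "strand", "idr", "none"], size=500), dtype=object)
    truth = TruthTrack(np.ones(500), classes)
    ss, dis = emit_confidence_tracks(truth, 0.0, seed=1)
    mask = call_classes(ss, dis, ss_cutoff=8, idr_cutoff=0.8)
    assert (mask.classes == classes).all()


def test_noisy_tracks_agree_about_90_percent():
    rng = np.random.default_rng(1)
    classes = np.array(rng.choice(["helix", "strand", "idr", "none"], size=10_000), dtype=object)
    truth = TruthTrack(np.ones(10_000), classes)
    ss, dis = emit_confidence_tracks(truth, 0.1, seed=2)
    mask = call_classes(ss, dis, ss_cutoff=8, idr_cutoff=0.8)
    agreement = float(np.mean(mask.classes == classes))
    # each residue passes through two independent 10% flips
    assert 0.78 < agreement < 0.93


def test_all_none_truth_passes_no_threshold():
    truth = TruthTrack(np.ones(200), np.array(["none"] * 200, dtype=object))
    ss, dis = emit_confidence_tracks(truth, 0.0, seed=3)
    assert (ss["conf"] < 8).all() or (ss["state"] == "C").all()
    assert (dis["score"] < 0.8).all()
    mask = call_classes(ss, dis)
    assert (mask.classes == "none").all()


def test_track_length_equals_protein_length():
    truth = TruthTrack(np.ones(77), np.array(["idr"] * 77, dtype=object))
    ss, dis = emit_confidence_tracks(truth, 0.2, seed=4)
    assert len(ss) == 77 and len(dis) == 77


# -- functional sites ----------------------------------------------------------
def test_zero_rates_place_no_sites():
    truth = TruthTrack(np.ones(100), np.array(["idr"] * 100, dtype=object))
    assert place_functional_sites(truth, 0.0, 0.0, seed=1) == set()


def test_site_placement_rates_differ_by_class():
    n = 40_000
    classes = np.array(["idr"] * (n // 2) + ["helix"] * (n // 2), dtype=object)
    truth = TruthTrack(np.ones(n), classes)
    sites = place_functional_sites(truth, 0.2, 0.1, seed=5)
    idr_rate = len([s for s in sites if s < n // 2]) / (n // 2)
    other_rate = len([s for s in sites if s >= n // 2]) / (n // 2)
    assert idr_rate == pytest.approx(0.2, abs=0.01)
    assert other_rate == pytest.approx(0.1, abs=0.01)


def test_site_placement_deterministic():
    truth = TruthTrack(np.ones(1000), np.array(["idr"] * 1000, dtype=object))
    assert place_functional_sites(truth, 0.1, 0.1, 7) == place_functional_sites(truth, 0.1, 0.1, 7)


# -- proteome generation -------------------------------------------------------
def test_generate_proteome_is_reproducible_and_consistent():
    cfg = neutral_proteome_config(n_genes=3, n_codons=60, n_a=3, n_b=3)
    tree1, genes1 = generate_proteome(cfg, seed=5)
    tree2, genes2 = generate_proteome(cfg, seed=5)
    assert tree1.tree.to_newick() == tree2.tree.to_newick()
    for g1, g2 in zip(genes1, genes2):
        assert [r.seq for r in g1.alignment.rows] == [r.seq for r in g2.alignment.rows]
        assert g1.functional_sites == g2.functional_sites
    for g in genes1:
        assert g.alignment.n_codons == g.truth.n_codons == 60
        assert len(g.ss_track) == 60
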