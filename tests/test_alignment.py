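import numpy as np
import pytest

from conftest import build_alignment, random_toy_alignment
from idrsel.alignment import (
    AlignmentRow,
    CodonAlignment,
    FrameError,
    InsufficientPanelError,
    MappingError,
    UndefinedPairError,
    filter_gene_set,
    gc_content,
    mask_low_frequency_polymorphisms,
    protein_identity,
    read_codon_alignment,
)


def simple_alignment(n_codons=4):
    seq = "ATGGCTGAAACT"[: 3 * n_codons]
    return build_alignment("g1", [seq, seq], [seq, seq])


# -- container and i/o ---------------------------------------------------------
def test_reads_toy_fasta(tmp_path):
    fasta = tmp_path / "g1.fasta"
    fasta.write_text(">s1|scer\nATGGCTAAA\n>s2|scer\nATGGCTAAA\n>p1|spar\nATGGCCAAA\n>p2|spar\nATGGCCAAA\n")
    aln = read_codon_alignment(fasta)
    assert aln.n_codons == 3
    assert aln.species == ("scer", "spar")


def test_species_map_resolution_and_mapping_error(tmp_path):
    fasta = tmp_path / "g2.fasta"
    fasta.write_text(">s1\nATGGCT\n>s2\nATGGCT\n>p1\nATGGCC\n>p2\nATGGCC\n")
    aln = read_codon_alignment(fasta, species_map={"s1": "a", "s2": "a", "p1": "b", "p2": "b"})
    assert len(aln.rows) == 4
    with pytest.raises(MappingError):
        read_codon_alignment(fasta, species_map={"s1": "a"})


def test_length_not_divisible_by_three_is_frame_error():
    with pytest.raises(FrameError):
        build_alignment("bad", ["ATGGCTGAAA", "ATGGCTGAAA"], ["ATGGCTGAAA", "ATGGCTGAAA"])


def test_internal_stop_is_frame_error():
    seq_stop = "ATGTAAGCT"  # TAA at codon 2 of 3
    with pytest.raises(FrameError):
        build_alignment("bad", [seq_stop, seq_stop], [seq_stop, seq_stop])


def test_single_strain_panel_rejected():
    rows = [
        AlignmentRow("s1", "scer", "ATGGCT"),
        AlignmentRow("p1", "spar", "ATGGCT"),
        AlignmentRow("p2", "spar", "ATGGCT"),
    ]
    with pytest.raises(InsufficientPanelError):
        CodonAlignment("bad", rows)


def test_shared_terminal_stop_column_is_stripped(tmp_path):
    fasta = tmp_path / "g3.fasta"
    fasta.write_text(">s1|a\nATGGCTTAA\n>s2|a\nATGGCTTAA\n>p1|b\nATGGCCTGA\n>p2|b\nATGGCCTGA\n")
    aln = read_codon_alignment(fasta)
    assert aln.n_codons == 2


def test_write_read_round_trip(tmp_path, rng):
    aln = random_toy_alignment(rng)
    path = tmp_path / "toy.fasta"
    aln.write_fasta(path)
    back = read_codon_alignment(path, gene_id="toy")
    assert [(r.strain, r.species, r.seq) for r in back.rows] == [
        (r.strain, r.species, r.seq) for r in aln.rows
    ]


# -- protein identity ----------------------------------------------------------
def test_identity_of_identical_rows_is_one():
    assert protein_identity(simple_alignment()) == 1.0


def test_identity_fraction_simple_case():
    # rows differing at 3 of 10 comparable residues -> 0.7 for that pair
    base = ["GCT"] * 10  # Ala x10
    var = list(base)
    for k in range(3):
        var[k] = "CGT"  # Arg
    a, b = "".join(base), "".join(var)
    aln = build_alignment("g", [a, a], [b, b])
    # pairs: within-species 1.0 (x2), cross pairs 0.7 (x4)
    assert protein_identity(aln) == pytest.approx((2 * 1.0 + 4 * 0.7) / 6)


def test_identity_matches_bruteforce_oracle(rng):
    for _ in range(5):
        aln = random_toy_alignment(rng)
        prots = aln.translated_rows()
        vals = []
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                comparable = ident = 0
                for x, y in zip(prots[i], prots[j]):
                    if x != "-" and y != "-":
                        comparable += 1
                        ident += x == y
                vals.append(ident / comparable)
        assert protein_identity(aln) == pytest.approx(sum(vals) / len(vals))


def test_identity_invariant_to_row_permutation(rng):
    aln = random_toy_alignment(rng)
    ref = protein_identity(aln)
    rows = list(aln.rows)
    rng.shuffle(rows)
    shuffled = CodonAlignment(aln.gene_id, rows)
    assert protein_identity(shuffled) == pytest.approx(ref)


def test_identity_undefined_when_no_comparable_positions():
    aln = build_alignment("g", ["GCT---", "GCT---"], ["---GCT", "---GCT"])
    with pytest.raises(UndefinedPairError):
        protein_identity(aln)


# -- filtering -----------------------------------------------------------------
def alignment_with_identity(gene_id, target):
    """Mean pairwise identity (2 + 4x)/6 where x is the cross-species identity."""
    m = 40
    x = (6 * target - 2) / 4
    k = round(m * (1 - x))
    base = ["GCT"] * m
    var = list(base)
    for i in range(k):
        var[i] = "CGT"
    return build_alignment(gene_id, ["".join(base)] * 2, ["".join(var)] * 2)


def test_filter_keeps_genes_above_threshold():
    alns = [alignment_with_identity(g, t) for g, t in [("a", 0.65), ("b", 0.75), ("c", 0.85)]]
    kept, reports = filter_gene_set(alns, identity_threshold=0.7)
    assert {a.gene_id for a in kept} == {"b", "c"}
    reasons = {r.gene_id: r.excluded_reason for r in reports}
    assert reasons == {"a": "low_identity", "b": "none", "c": "none"}


def test_zero_threshold_keeps_everything(rng):
    alns = [random_toy_alignment(rng) for _ in range(4)]
    for i, a in enumerate(alns):
        a.gene_id = f"g{i}"
    kept, _ = filter_gene_set(alns, identity_threshold=0.0)
    assert len(kept) == 4


def test_blacklist_overrides_identity():
    alns = [alignment_with_identity("good", 0.9)]
    kept, reports = filter_gene_set(alns, 0.7, recombination_blacklist={"good"})
    assert kept == []
    assert reports[0].excluded_reason == "recombination_blacklist"


def test_filtering_is_idempotent(rng):
    alns = [random_toy_alignment(rng) for _ in range(6)]
    for i, a in enumerate(alns):
        a.gene_id = f"g{i}"
    kept1, _ = filter_gene_set(alns, 0.8)
    kept2, _ = filter_gene_set(kept1, 0.8)
    assert [a.gene_id for a in kept1] == [a.gene_id for a in kept2]


# -- GC content ----------------------------------------------------------------
@pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("AAAA", 0.0), ("GCGC", 1.0)])
def test_gc_content_simple(seq, expected):
    assert gc_content(seq) == expected


def test_gc_content_matches_tally_oracle(rng):
    seq = "".join(rng.choice(list("ACGT-"), size=999))
    ungapped = seq.replace("-", "")
    expected = sum(c in "GC" for c in ungapped) / len(ungapped)
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_all_gaps_is_error():
    with pytest.raises(ValueError):
        gc_content("---")


# -- low-frequency masking -----------------------------------------------------
def ten_strain_alignment(n_variant):
    base = "GCTGCTGCT"
    variant = "GTTGCTGCT"  # C->T at position 1 (non-synonymous Ala->Val)
    seqs_a = [variant] * n_variant + [base] * (10 - n_variant)
    seqs_b = [base] * 4
    return build_alignment("g", seqs_a, seqs_b)


def test_singleton_below_threshold_is_replaced():
    aln = ten_strain_alignment(1)  # 10% < 15%
    masked = mask_low_frequency_polymorphisms(aln, 0.15)
    col = {r.seq[1] for r in masked.rows_of("scer")}
    assert col == {"C"}


def test_variant_at_20_percent_is_kept():
    aln = ten_strain_alignment(2)
    masked = mask_low_frequency_polymorphisms(aln, 0.15)
    assert [r.seq for r in masked.rows] == [r.seq for r in aln.rows]


def test_masking_is_idempotent(rng):
    for _ in range(5):
        aln = random_toy_alignment(rng)
        once = mask_low_frequency_polymorphisms(aln, 0.15)
        twice = mask_low_frequency_polymorphisms(once, 0.15)
        assert [r.seq for r in once.rows] == [r.seq for r in twice.rows]


def test_masking_preserves_fixed_differences():
    a = "GCTGCTGCT"
    b = "GCCGCTGCT"  # fixed difference at position 2
    aln = build_alignment("g", [a] * 5, [b] * 5)
    masked = mask_low_frequency_polymorphisms(aln, 0.15)
    assert [r.seq for r in masked.rows] == [r.seq for r in aln.rows]


def test_planted_singletons_removed_nonsingletons_survive():
    base = "GCTGAAACTCCT" * 2
    seqs_a = [list(base) for _ in range(10)]
    seqs_a[0][0] = "A"  # singleton (10%)
    seqs_a[1][6] = "G"
    seqs_a[2][6] = "G"  # doubleton (20%)
    aln = build_alignment("g", ["".join(s) for s in seqs_a], [base] * 4)
    masked = mask_low_frequency_polymorphisms(aln, 0.15)
    mat = np.array([list(r.seq) for r in masked.rows_of("scer")])
    segregating = [c for c in range(mat.shape[1]) if len(set(mat[:, c])) > 1]
    assert segregating == [6]
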