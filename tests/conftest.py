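import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from idrsel.alignment import AlignmentRow, CodonAlignment
from idrsel.codons import SENSE_CODONS, STOP_CODONS


def build_alignment(gene_id, seqs_a, seqs_b, species=("scer", "spar")):
    """Alignment from raw per-species sequence lists."""
    rows = [AlignmentRow(f"{species[0]}_{i + 1}", species[0], s) for i, s in enumerate(seqs_a)]
    rows += [AlignmentRow(f"{species[1]}_{i + 1}", species[1], s) for i, s in enumerate(seqs_b)]
    return CodonAlignment(gene_id, rows)


def random_toy_alignment(rng, max_strains=6, max_codons=15, mutation_rate=0.35):
    """Random two-species toy with planted multi-hit codons and no stops.

    Mutations are applied per nucleotide with independent species-specific
    and strain-specific changes, so some codons carry several variant
    positions (the multi-hit cases that exercise path averaging).
    """
    n_codons = int(rng.integers(3, max_codons + 1))
    n_a = int(rng.integers(2, max_strains + 1))
    n_b = int(rng.integers(2, max_strains + 1))
    sense = [c for c in SENSE_CODONS]
    base = "".join(rng.choice(sense) for _ in range(n_codons))

    def mutate(seq, n_hits):
        s = list(seq)
        for _ in range(n_hits):
            pos = int(rng.integers(len(s)))
            s[pos] = "ACGT"[int(rng.integers(4))]
            k = pos // 3
            if "".join(s[3 * k : 3 * k + 3]) in STOP_CODONS:
                s[pos] = seq[pos]  # keep the panel stop-free
        return "".join(s)

    # species-level divergence, then strain-level polymorphism
    anc_a = mutate(base, int(rng.integers(0, n_codons)))
    anc_b = mutate(base, int(rng.integers(0, n_codons)))
    seqs_a = [mutate(anc_a, int(rng.integers(0, max(1, int(n_codons * mutation_rate))))) for _ in range(n_a)]
    seqs_b = [mutate(anc_b, int(rng.integers(0, max(1, int(n_codons * mutation_rate))))) for _ in range(n_b)]
    return build_alignment("toy", seqs_a, seqs_b)


@pytest.fixture
def rng():
    return np.random.default_rng(20110719)
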