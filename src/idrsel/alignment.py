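"""Codon alignment container, QC filtering, and low-frequency SNP masking.

A gene enters the analysis as an in-frame multiple alignment of all strain
orthologues from two species.  This module validates frame and panel
structure, scores mean pairwise protein identity for the filtering funnel,
and removes SNPs segregating below a minor-strain-fraction threshold within
each species (a standard guard against slightly deleterious polymorphisms
inflating pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .codons import STOP_CODONS, translate_codon

VALID_CHARS = frozenset("ACGT-")


class FrameError(ValueError):
    """Alignment length or stop-codon structure incompatible with a codon frame."""


class MappingError(KeyError):
    """A strain label has no species assignment."""


class InsufficientPanelError(ValueError):
    """Fewer than two strains in one of the species panels."""


class UndefinedPairError(ValueError):
    """A sequence pair shares no ungapped positions to compare."""


@dataclass
class AlignmentRow:
    strain: str
    species: str
    seq: str


@dataclass
class CodonAlignment:
    """One gene's in-frame aligned codon sequences tagged with species/strain."""

    gene_id: str
    rows: list[AlignmentRow]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------------
    @property
    def length_nt(self) -> int:
        return len(self.rows[0].seq)

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    @property
    def species(self) -> tuple[str, str]:
        return tuple(sorted({r.species for r in self.rows}))  # type: ignore[return-value]

    def rows_of(self, species: str) -> list[AlignmentRow]:
        return [r for r in self.rows if r.species == species]

    def codon(self, row_index: int, codon_index: int) -> str:
        return self.rows[row_index].seq[3 * codon_index : 3 * codon_index + 3]

    def column_codons(self, codon_index: int) -> list[str]:
        return [r.seq[3 * codon_index : 3 * codon_index + 3] for r in self.rows]

    def translated_rows(self) -> list[str]:
        return [
            "".join(translate_codon(r.seq[k : k + 3]) for k in range(0, self.length_nt, 3))
            for r in self.rows
        ]

    def validate(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0].seq)
        for r in self.rows:
            if len(r.seq) != n:
                raise FrameError(f"{self.gene_id}: rows differ in length")
            if not set(r.seq) <= VALID_CHARS:
                bad = sorted(set(r.seq) - VALID_CHARS)
                raise ValueError(f"{self.gene_id}: invalid characters {bad}")
        if n == 0 or n % 3 != 0:
            raise FrameError(f"{self.gene_id}: length {n} not divisible by 3")
        species = {r.species for r in self.rows}
        if len(species) != 2:
            raise InsufficientPanelError(f"{self.gene_id}: need exactly two species, got {sorted(species)}")
        for sp in species:
            if len(self.rows_of(sp)) < 2:
                raise InsufficientPanelError(f"{self.gene_id}: fewer than 2 strains for {sp}")
        last = self.n_codons - 1
        for r in self.rows:
            for k in range(last):  # terminal column may hold a shared stop
                codon = r.seq[3 * k : 3 * k + 3]
                if "-" not in codon and codon in STOP_CODONS:
                    raise FrameError(f"{self.gene_id}: internal stop codon in {r.strain} at codon {k + 1}")

    # -- i/o -----------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.rows:
                fh.write(f">{r.strain}|{r.species}\n")
                for k in range(0, len(r.seq), 70):
                    fh.write(r.seq[k : k + 70] + "\n")


def read_codon_alignment(
    path: str | Path,
    species_map: dict[str, str] | None = None,
    gene_id: str | None = None,
) -> CodonAlignment:
    """Read a gene alignment from multi-FASTA.

    Headers are either ``strain|species`` or a bare strain label resolved via
    ``species_map``.  A terminal stop-codon column shared by every ungapped row
    is stripped.
    """
    path = Path(path)
    gene_id = gene_id or path.stem
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "|" in name:
            strain, species = name.split("|", 1)
        elif species_map and name in species_map:
            strain, species = name, species_map[name]
        else:
            raise MappingError(f"{gene_id}: no species mapping for strain {name!r}")
        rows.append(AlignmentRow(strain, species, str(rec.seq).upper()))
    if not rows:
        raise FrameError(f"{gene_id}: no sequences in {path}")
    aln = CodonAlignment(gene_id, rows)
    last = aln.n_codons - 1
    terminal = [r.seq[3 * last : 3 * last + 3] for r in aln.rows]
    if last >= 1 and all(c in STOP_CODONS for c in terminal):
        rows = [AlignmentRow(r.strain, r.species, r.seq[: 3 * last]) for r in aln.rows]
        aln = CodonAlignment(gene_id, rows, dict(aln.meta))
    return aln


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV of strain label -> species label."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        strain, species = line.split("\t")[:2]
        out[strain] = species
    return out


# -- QC ----------------------------------------------------------------------
@dataclass
class QCReport:
    gene_id: str
    mean_pairwise_protein_identity: float
    passed_threshold: bool
    excluded_reason: str  # low_identity | recombination_blacklist | frame_error | none


def protein_identity(aln: CodonAlignment) -> float:
    """Mean pairwise amino-acid identity over positions ungapped in both rows."""
    prot = np.array([list(s) for s in aln.translated_rows()])
    n = len(prot)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = (prot[i] != "-") & (prot[j] != "-")
            comparable = int(ok.sum())
            if comparable == 0:
                raise UndefinedPairError(
                    f"{aln.gene_id}: rows {aln.rows[i].strain}/{aln.rows[j].strain} share no comparable sites"
                )
            total += float((prot[i][ok] == prot[j][ok]).sum()) / comparable
            pairs += 1
    return total / pairs


def filter_gene_set(
    alignments: list[CodonAlignment],
    identity_threshold: float = 0.7,
    recombination_blacklist: set[str] | None = None,
) -> tuple[list[CodonAlignment], list[QCReport]]:
    """Apply the identity filter and the recombination blacklist to a gene set."""
    blacklist = recombination_blacklist or set()
    kept, reports = [], []
    for aln in alignments:
        ident = protein_identity(aln)
        if aln.gene_id in blacklist:
            reports.append(QCReport(aln.gene_id, ident, False, "recombination_blacklist"))
        elif ident < identity_threshold:
            reports.append(QCReport(aln.gene_id, ident, False, "low_identity"))
        else:
            reports.append(QCReport(aln.gene_id, ident, True, "none"))
            kept.append(aln)
    return kept, reports


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T) of a nucleotide sequence; gaps excluded."""
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no ungapped nucleotides")
    return (counts["G"] + counts["C"]) / denom


# -- low-frequency SNP masking -----------------------------------------------
def _species_matrix(aln: CodonAlignment, species: str) -> np.ndarray:
    return np.array([list(r.seq) for r in aln.rows_of(species)])


def low_frequency_positions(aln: CodonAlignment, min_freq: float = 0.15) -> set[int]:
    """Nucleotide columns where some within-species allele is below min_freq."""
    out: set[int] = set()
    for sp in aln.species:
        mat = _species_matrix(aln, sp)
        n = mat.shape[0]
        for col in range(mat.shape[1]):
            alleles, counts = np.unique(mat[:, col], return_counts=True)
            keep = alleles != "-"
            alleles, counts = alleles[keep], counts[keep]
            if len(alleles) > 1 and (counts / n < min_freq).any():
                out.add(col)
    return out


def mask_low_frequency_polymorphisms(
    aln: CodonAlignment, min_freq: float = 0.15
) -> CodonAlignment:
    """Replace within-species alleles carried by < min_freq of strains.

    At every nucleotide column, separately within each species, alleles below
    the frequency threshold are overwritten with that species' majority allele
    (ties broken toward the species' first row).  Replacement rather than
    column removal keeps the codon frame and coordinates intact.
    """
    seqs = {id(r): list(r.seq) for r in aln.rows}
    for sp in aln.species:
        rows = aln.rows_of(sp)
        mat = np.array([list(r.seq) for r in rows])
        n = len(rows)
        for col in range(mat.shape[1]):
            column = mat[:, col]
            alleles, counts = np.unique(column, return_counts=True)
            keep = alleles != "-"
            alleles, counts = alleles[keep], counts[keep]
            if len(alleles) < 2:
                continue
            freqs = counts / n
            low = freqs < min_freq
            if not low.any():
                continue
            top = counts.max()
            tied = set(alleles[counts == top])
            major = next(c for c in column if c in tied)
            for r, c in zip(rows, column):
                if c != "-" and c in set(alleles[low]):
                    seqs[id(r)][col] = major
    # masking may, in a multi-variant codon, assemble a stop from alleles that
    # never co-occurred in one strain; such codons revert to their originals
    for r in aln.rows:
        masked = seqs[id(r)]
        for k in range(0, len(masked), 3):
            codon = "".join(masked[k : k + 3])
            if "-" not in codon and codon in STOP_CODONS and r.seq[k : k + 3] not in STOP_CODONS:
                masked[k : k + 3] = list(r.seq[k : k + 3])
    new_rows = [AlignmentRow(r.strain, r.species, "".join(seqs[id(r)])) for r in aln.rows]
    return CodonAlignment(aln.gene_id, new_rows, dict(aln.meta))
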