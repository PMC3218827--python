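"""Conformational class calling from per-residue confidence tracks.

A residue is called helix or strand when its secondary-structure predictor
asserts state H or E with integer confidence at or above a cutoff (default 8
on the 0-9 scale), and intrinsically disordered when its disorder score meets
a cutoff (0.8 strict, 0.5 liberal).  Residues passing both a structured and
the disorder cutoff are contradictory predictions and are left unassigned, as
are residues passing neither.  Codon i of the gene encodes residue i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

UNASSIGNED = "none"
STRUCTURED_STATES = {"H": "helix", "E": "strand"}


@dataclass
class RegionClassMask:
    protein_id: str
    classes: np.ndarray  # helix | strand | idr | none per residue
    ss_cutoff: int = 8
    idr_cutoff: float = 0.8

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)

    def __len__(self) -> int:
        return len(self.classes)


@dataclass
class Region:
    protein_id: str
    cls: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


def read_ss_track(path: str | Path) -> pd.DataFrame:
    """Read a secondary-structure confidence track.

    Accepts the tabular format written by the simulator (index, residue,
    state, conf 0-9) or genuine PSIPRED .ss2 vertical output (index, residue,
    state, three class probabilities), which is mapped onto the 0-9 scale.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    if first[0].lower() == "index":  # header row of the simulator format
        return pd.read_csv(path, sep="\t", comment="#")
    rows = []
    for ln in lines:
        parts = ln.split()
        if len(parts) >= 6:  # .ss2: idx aa state pC pH pE
            idx, aa, state = int(parts[0]) - 1, parts[1], parts[2]
            conf = min(9, int(10 * max(float(parts[3]), float(parts[4]), float(parts[5]))))
        else:  # idx aa state conf
            idx, aa, state, conf = int(parts[0]), parts[1], parts[2], int(parts[3])
        rows.append((idx, aa, state, conf))
    return pd.DataFrame(rows, columns=["index", "residue", "state", "conf"])


def read_disorder_track(path: str | Path) -> pd.DataFrame:
    """Read a VSL2-style per-residue disorder score track (index[, residue], score)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if lines[0].split()[0].lower() == "index":
        return pd.read_csv(path, sep="\t", comment="#")
    rows = []
    for ln in lines:
        parts = ln.split()
        if len(parts) >= 3:
            rows.append((int(parts[0]), parts[1], float(parts[2])))
        else:
            rows.append((int(parts[0]), "X", float(parts[1])))
    return pd.DataFrame(rows, columns=["index", "residue", "score"])


def call_classes(
    ss_track: pd.DataFrame,
    disorder_track: pd.DataFrame,
    ss_cutoff: int = 8,
    idr_cutoff: float = 0.8,
    protein_id: str = "protein",
) -> RegionClassMask:
    """Threshold the two tracks into a per-residue conformational class mask."""
    if len(ss_track) != len(disorder_track):
        raise ValueError(f"{protein_id}: track length mismatch {len(ss_track)} vs {len(disorder_track)}")
    states = ss_track["state"].to_numpy()
    conf = ss_track["conf"].to_numpy()
    score = disorder_track["score"].to_numpy(dtype=float)
    structured = np.array([STRUCTURED_STATES.get(s, "") for s in states], dtype=object)
    is_structured = (structured != "") & (conf >= ss_cutoff)
    is_idr = score >= idr_cutoff
    classes = np.full(len(states), UNASSIGNED, dtype=object)
    classes[is_structured] = structured[is_structured]
    classes[is_idr] = "idr"
    classes[is_structured & is_idr] = UNASSIGNED  # contradictory predictions removed
    return RegionClassMask(protein_id, classes, ss_cutoff, idr_cutoff)


def segment_regions(mask: RegionClassMask, cls: str, min_length: int = 1) -> list[Region]:
    """Maximal same-class runs of at least min_length residues, sorted by start."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask.classes[i] == cls:
            j = i
            while j < n and mask.classes[j] == cls:
                j += 1
            if j - i >= min_length:
                out.append(Region(mask.protein_id, cls, i, j))
            i = j
        else:
            i += 1
    return out


def class_fraction(
    mask: RegionClassMask, cls: str, window: tuple[int, int] | None = None
) -> float:
    """Fraction of residues of a class, over the protein or a half-open window."""
    if window is None:
        sel = mask.classes
    else:
        start, end = window
        if not (0 <= start < end <= len(mask)):
            raise ValueError(f"window {window} out of bounds or empty")
        sel = mask.classes[start:end]
    return float(np.mean(sel == cls))


def write_mask_tsv(mask: RegionClassMask, path: str | Path) -> None:
    """Mask export: protein_id, 1-based position, class."""
    df = pd.DataFrame(
        {
            "protein_id": mask.protein_id,
            "position": np.arange(1, len(mask) + 1),
            "class": mask.classes,
        }
    )
    df.to_csv(path, sep="\t", index=False)
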