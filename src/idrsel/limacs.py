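"""Functional-sites index contrasting site density in IDRs vs non-IDRs.

Within mapped domain regions, residues are cross-classified as functional
site or not (LI/LnI in IDRs, nLI/nLnI outside) and the odds-ratio-style
index (LI/nLI)/(LnI/nLnI) measures relative functional-site abundance in
disordered regions: above one, functional sites are relatively enriched in
IDRs; below one, depleted.  A chi-square test on the 2x2 table accompanies
the index.  Residues in a domain that are not confidently disordered count
as non-IDR by default (the dichotomy is IDR vs everything else); duplicate
occurrences of the same domain can be filtered to the first-seen region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import contingency_chi2
from .structure import RegionClassMask, call_classes


@dataclass
class FunctionalSiteSet:
    protein_id: str
    domain_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    functional_positions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.protein_id}/{self.domain_id}: empty region")
        bad = {p for p in self.functional_positions if not self.start <= p < self.end}
        if bad:
            raise ValueError(f"{self.protein_id}/{self.domain_id}: sites outside region: {sorted(bad)}")


@dataclass
class LimacsResult:
    index: float  # nan when a denominator cell is empty
    chi2: float
    p: float
    table: np.ndarray  # [[LI, LnI], [nLI, nLnI]]
    n_regions: int


def limacs_index(
    site_sets: list[FunctionalSiteSet],
    masks: dict[str, RegionClassMask],
    dedupe_domains: bool = False,
    strict_classes_only: bool = False,
) -> LimacsResult:
    """Compute the functional-sites index over mapped domain regions.

    ``strict_classes_only`` restricts the non-IDR cell to residues confidently
    called helix or strand instead of all non-IDR residues.
    """
    li = lni = nli = nlni = 0
    seen: set[str] = set()
    n_regions = 0
    for ss in site_sets:
        if dedupe_domains:
            if ss.domain_id in seen:
                continue
            seen.add(ss.domain_id)
        mask = masks.get(ss.protein_id)
        if mask is None:
            continue
        if ss.end > len(mask):
            raise ValueError(f"{ss.protein_id}/{ss.domain_id}: region beyond mask length")
        n_regions += 1
        for pos in range(ss.start, ss.end):
            cls = mask.classes[pos]
            if strict_classes_only and cls not in ("idr", "helix", "strand"):
                continue
            in_idr = cls == "idr"
            functional = pos in ss.functional_positions
            if functional and in_idr:
                li += 1
            elif functional:
                lni += 1
            elif in_idr:
                nli += 1
            else:
                nlni += 1
    table = np.array([[li, lni], [nli, nlni]], dtype=float)
    if nli > 0 and lni > 0 and nlni > 0:
        index = (li / nli) / (lni / nlni)
    else:
        index = float("nan")
    if table.sum() > 0 and not (table.sum(0) == 0).any() and not (table.sum(1) == 0).any():
        chi2, p = contingency_chi2([[li, lni], [nli, nlni]])
    else:
        chi2, p = float("nan"), float("nan")
    return LimacsResult(float(index), chi2, p, table.astype(int), n_regions)


def index_threshold_sweep(
    site_sets: list[FunctionalSiteSet],
    ss_tracks: dict[str, pd.DataFrame],
    disorder_tracks: dict[str, pd.DataFrame],
    cutoffs: list[float],
    dedupe_domains: bool = False,
    ss_cutoff: int = 8,
) -> pd.DataFrame:
    """Index and mean domain IDR fraction across disorder-score cutoffs.

    Cutoffs must be sorted ascending; the mean IDR fraction in mapped domains
    is non-increasing along the sweep (thresholding is monotone).
    """
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    rows = []
    for cutoff in cutoffs:
        masks = {
            pid: call_classes(ss_tracks[pid], disorder_tracks[pid],
                              ss_cutoff=ss_cutoff, idr_cutoff=cutoff, protein_id=pid)
            for pid in ss_tracks
        }
        res = limacs_index(site_sets, masks, dedupe_domains=dedupe_domains)
        in_domain_idr = in_domain = 0
        seen: set[str] = set()
        for ss in site_sets:
            if dedupe_domains:
                if ss.domain_id in seen:
                    continue
                seen.add(ss.domain_id)
            mask = masks.get(ss.protein_id)
            if mask is None:
                continue
            seg = mask.classes[ss.start : ss.end]
            in_domain += len(seg)
            in_domain_idr += int(np.sum(seg == "idr"))
        rows.append(
            {
                "cutoff": cutoff,
                "index": res.index,
                "chi2_p": res.p,
                "domain_idr_fraction": in_domain_idr / in_domain if in_domain else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def read_site_sets(path: str | Path) -> list[FunctionalSiteSet]:
    """Site-set TSV: protein_id, domain_id, region_start, region_end,
    comma-separated site positions; 1-based inclusive coordinates in files."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "protein_id")):
            continue
        parts = line.rstrip("\n").split("\t")
        protein, domain, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
        sites = set()
        if len(parts) > 4 and parts[4].strip():
            sites = {int(x) - 1 for x in parts[4].split(",")}
        out.append(FunctionalSiteSet(protein, domain, start - 1, end, sites))
    return out


def write_site_sets(site_sets: list[FunctionalSiteSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_id\tregion_start\tregion_end\tsite_positions\n")
        for ss in site_sets:
            sites = ",".join(str(p + 1) for p in sorted(ss.functional_positions))
            fh.write(f"{ss.protein_id}\t{ss.domain_id}\t{ss.start + 1}\t{ss.end}\t{sites}\n")
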