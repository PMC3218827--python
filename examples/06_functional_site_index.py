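"""Functional-sites index: are functional residues depleted in IDRs?

Places functional sites twice as densely in disordered residues, then
computes the odds-ratio-style index (LI/nLI)/(LnI/nLnI) within mapped domain
regions, across a sweep of disorder-score cutoffs.
"""

import numpy as np

from idrsel import (
    FunctionalSiteSet,
    TruthTrack,
    emit_confidence_tracks,
    index_threshold_sweep,
    limacs_index,
    place_functional_sites,
)
from idrsel.structure import RegionClassMask

n = 20_000
classes = np.array(["idr"] * (n // 3) + ["none"] * (n - n // 3), dtype=object)
truth = TruthTrack(np.ones(n), classes)
sites = place_functional_sites(truth, rate_idr=0.06, rate_other=0.03, seed=2)
domain = FunctionalSiteSet("demo", "DOM1", 0, n, sites)

res = limacs_index([domain], {"demo": RegionClassMask("demo", classes)})
li, lni = res.table[0]
nli, nlni = res.table[1]
print(f"2x2 table: functional in IDR {li}, functional elsewhere {lni}, "
      f"non-functional in IDR {nli}, elsewhere {nlni}")
print(f"index = {res.index:.2f} (chi2 p = {res.p:.2e})")
# index near 2 recovers the 2:1 placement-rate contrast: functional sites
# are, if anything, enriched in disordered regions here

ss, dis = emit_confidence_tracks(truth, noise_flip_prob=0.05, seed=3)
sweep = index_threshold_sweep([domain], {"demo": ss}, {"demo": dis},
                              cutoffs=[0.3, 0.5, 0.8, 0.9])
print("\ncutoff sweep (stricter cutoff -> smaller IDR fraction):")
for _, row in sweep.iterrows():
    print(f"  cutoff {row['cutoff']:.1f}: index {row['index']:.2f}, "
          f"domain IDR fraction {row['domain_idr_fraction']:.3f}")
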