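"""Screen a small library, then compute enrichment metrics on a score set.

Part 1 docks a seeded 6-molecule library into a planted site and prints the
score table.  Part 2 evaluates the standard enrichment metrics (AUC,
adjusted logAUC, EF1) on synthetic ligand/decoy score sets at two separation
levels: zero separation should look random (adjusted logAUC ~ 0), strong
separation close to perfect (~85 is the ceiling).
"""

from minidock import DockParams, enrichment_stats, screen_library
from minidock.fixtures import make_library, make_planted_site, make_score_set
from minidock.matching import MatchParams

bundle, rec_spheres, _, _ = make_planted_site(seed=3)
library = make_library(6, seed=3)
table, outcomes = screen_library(library, rec_spheres, bundle,
                                 DockParams(match=MatchParams(match_goal=30)))
print(table.to_string(index=False))
print()

for sep in (0.0, 3.0):
    result = make_score_set(n_ligands=100, n_decoys=1000, separation=sep, seed=11)
    s = enrichment_stats(result)
    print(f"separation {sep}: AUC {s.auc:.3f}, adjusted logAUC {s.adjusted_log_auc:6.2f}, "
          f"EF1 {s.ef1:.1f}")
print("a zero-separation screen is indistinguishable from random "
      "(AUC ~ 0.5, adjusted logAUC ~ 0); separation pushes both up")
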