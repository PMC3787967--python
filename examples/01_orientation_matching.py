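"""Clique matching on the toy sphere system.

Builds the 3-sphere ligand / 4-sphere receptor toy system, enumerates
orientational matches at two distance tolerances, and runs the adaptive
matcher.  Shows the tolerance-superset property: every match found at the
tighter tolerance reappears at the looser one.
"""

from minidock import adaptive_match, enumerate_matches
from minidock.fixtures import make_fig1_system
from minidock.matching import MatchParams, ToleranceSchedule

lig, rec = make_fig1_system()
print(f"ligand spheres: {len(lig)}, receptor spheres: {len(rec)}")

at_01 = enumerate_matches(lig, rec, tolerance=0.1, node_count=3)
at_02 = enumerate_matches(lig, rec, tolerance=0.2, node_count=3)
print(f"matches at 0.1 A tolerance: {len(at_01)}")
print(f"matches at 0.2 A tolerance: {len(at_02)}")
assert {c.pairs for c in at_01} <= {c.pairs for c in at_02}
print("every 0.1 A match is contained in the 0.2 A set (superset property)")

for c in at_02:
    tag = "also at 0.1" if c in at_01 else "only at 0.2"
    print(f"  ligand {c.ligand_indices} -> receptor {c.receptor_indices}  ({tag})")

# the adaptive driver escalates tolerance until the match goal is reached
res = adaptive_match(lig, rec, MatchParams(match_goal=3, node_count=3),
                     ToleranceSchedule(0.05, 0.05, 1.0))
print(f"adaptive match, goal 3: {len(res.correspondences)} matches "
      f"at final tolerance {res.tolerance:.2f} A (goal met: {res.goal_met})")
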