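"""Enumerate off-target sites for a guide under the 2/2/4 flaw budget.

Builds a 2 kb synthetic genome with four planted protospacer sites of known
seed/non-seed mismatch partitions — (0,2), (2,0), (2,2) and an over-budget
(3,0) decoy — then scans both strands for NGG-adjacent matches.
"""

import numpy as np

import crispri_specificity as cs
from crispri_specificity.simulate import PlantSpec, make_planted_genome

rng = np.random.default_rng(0)
spacer_seq = "".join(rng.choice(list("ACGT"), size=20))
specs = [
    PlantSpec(spacer_seq, "chr1", 100, "+", seed_flaws=0, nonseed_flaws=2),
    PlantSpec(spacer_seq, "chr1", 600, "-", seed_flaws=2, nonseed_flaws=0),
    PlantSpec(spacer_seq, "chr1", 1100, "+", seed_flaws=2, nonseed_flaws=2),
    PlantSpec(spacer_seq, "chr1", 1600, "+", seed_flaws=3, nonseed_flaws=0),
]
genome, truth = make_planted_genome({"chr1": 2000}, specs, rng_seed=1)

spacer = cs.Spacer(guide_id="sg1", sequence=spacer_seq)
sites = cs.enumerate_sites(genome, spacer, cs.FlawBudget(2, 2, 4), pam="NGG")

print(f"spacer: {spacer_seq}")
print("sites found (the (3,0) decoy exceeds the seed cap and is absent):")
for s in sites:
    print(f"  {s.chromosome}:{s.start}-{s.end} {s.strand}  "
          f"seed={s.seed_flaws} nonseed={s.nonseed_flaws} PAM={s.pam_sequence}")
# Each line is one candidate binding site; seed/nonseed are the mismatch
# counts in the 12 PAM-proximal vs the remaining bases of the protospacer.
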