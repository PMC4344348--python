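"""Rank candidate EGFR-targeting molecules against the natural ligand.

Feeds point estimates of K_D (from SPR) and adhesion force (from AFM) for
the natural ligand EGF, the targeting peptide GE11 and an anti-receptor
monoclonal antibody into the screening report.
"""

from bindscreen import screenreport as sr

kd_M = {"EGF": 1.77e-7, "GE11": 4.59e-4, "mAb": 2.07e-9}
adhesion_pN = {"EGF": 209.41, "GE11": 59.51, "mAb": 210.99}

table = sr.compare_to_reference(kd_M, adhesion_pN, reference="EGF")
print(table.summary())

# Affinity rank 1 = smallest K_D (affinity is inverse to K_D); adhesion rank
# 1 = largest rupture force.  A candidate that beats the reference on both
# axes (here the antibody) is a molecule that could outcompete the natural
# ligand for receptor binding.
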