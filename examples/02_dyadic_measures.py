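"""Compute the dyadic rate measures: association (DA), grooming (GA),
communication (CA).

DA = 60 * P10/PSP is the minutes per hour a focal spends within 10 m of a partner
while in the same party (0-60). GA and CA condition on time within 10 m instead,
so they measure behavior given closeness, independently of the choice to be close.
"""

import numpy as np

import chimpnet as cn
from chimpnet import measures as cm

attrs, model, scans, events = cn.generate_dataset(cn.CommunityConfig(seed=42))

counts = cn.count_dyads(scans)
sequences = cm.assemble_sequences(events)          # 30-s rule, same dyad/goal/context
comm = cm.count_sequences(sequences, events)

prox = cn.association_matrix(counts)
groom = cn.grooming_matrix(counts, "mutual")
gest = cm.combined_gesture_matrix(comm, counts)

v = prox.offdiag_values()
print(f"DA over {v.size} ordered dyads: mean {v.mean():.2f} min/h, "
      f"range {v.min():.1f}-{v.max():.1f}")
print(f"mutual grooming: mean {np.nanmean(groom.offdiag_values()):.2f} min/h")
print(f"all gesture sequences: mean {np.nanmean(gest.offdiag_values()):.2f} /h")
print(f"{len(sequences)} gesture sequences assembled from "
      f"{sum(1 for e in events if e.is_gesture)} gesture events")

kappa = cm.cohens_kappa(list("aabbccab"), list("aabbccba"))
print(f"example Cohen's kappa on 8 paired labels: {kappa:.3f}")
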