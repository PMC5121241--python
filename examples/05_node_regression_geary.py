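"""Node-level permutation regression and Geary's C autocorrelation.

Node-level regression asks which individual-level behaviors predict the size of
an individual's proximity network (in-degree on the preferred-partner network),
permuting the outcome across nodes for significance. Geary's C checks whether a
node attribute (here observation effort) is autocorrelated with the network:
1.0 means no association, below 1.0 a positive one.
"""

import pandas as pd

import chimpnet as cn
from chimpnet import measures as cm
from chimpnet import networks as nets
from chimpnet import permstats as ps

attrs, model, scans, events = cn.generate_dataset(cn.CommunityConfig(seed=42))
counts = cn.count_dyads(scans)
comm = cm.count_sequences(cm.assemble_sequences(events), events)
focal = sorted(attrs.loc[attrs.is_focal, "id"])

prox = cn.association_matrix(counts, focal)
bonds, _ = nets.classify_bonds(prox)
outcome = nets.degree_centrality(bonds.preferred_partner, "in")

at = attrs.set_index("id").loc[focal]
predictors = pd.DataFrame({
    "gesture_out": nets.degree_centrality(
        cm.combined_gesture_matrix(comm, counts, focal), "out"),
    "sex_male": (at["sex"] == "M").astype(float),
    "age_years": at["age_years"].astype(float),
})
res = ps.node_regression(outcome, predictors, n_perm=10_000, seed=42)
print(res.to_frame().round(4).to_string(index=False))

minutes = at["minutes_observed"].astype(float)
g = ps.gearys_c(minutes, prox, n_perm=2000, seed=42)
print(f"\nGeary's C (observation minutes vs proximity): {g.c:.3f} "
      f"({g.direction} association), p = {g.p_perm:.3f}")
print(f"null mean over {g.n_perm} permutations: {g.null_mean:.3f} (expected 1.0)")
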