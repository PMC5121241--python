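"""MRQAP: which dyadic behaviors predict proximity between pairs?

Double-semi-partialling MRQAP regresses the proximity matrix on attribute
similarity and behavioral rate matrices. Coefficients are plain OLS on the
vectorized dyads; p-values come from QAP permutations (node relabelings) of each
predictor's residual matrix, so the dyadic dependence structure is respected.
"""

import chimpnet as cn
from chimpnet import measures as cm
from chimpnet import networks as nets
from chimpnet import permstats as ps

attrs, model, scans, events = cn.generate_dataset(cn.CommunityConfig(seed=42))
counts = cn.count_dyads(scans)
comm = cm.count_sequences(cm.assemble_sequences(events), events)
focal = sorted(attrs.loc[attrs.is_focal, "id"])

y = cn.association_matrix(counts, focal)
predictors = [
    nets.similarity_matrix(attrs, "kin"),
    nets.similarity_matrix(attrs, "sex"),
    cn.grooming_matrix(counts, "mutual", focal),
    cm.combined_gesture_matrix(comm, counts, focal),
]

res = ps.mrqap_dsp(y, predictors, n_perm=2000, seed=42)
print(res.to_frame().round(4).to_string(index=False))
print(f"\nr^2 = {res.r_squared:.3f} over {res.n_obs} dyads, "
      f"{res.n_perm} permutations")
print("beta: change in proximity (min/h) per unit of the predictor; "
      "p_perm: two-tailed QAP p-value.")
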