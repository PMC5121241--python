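"""Classify proximity bonds and summarize network connectedness.

Dyads at or above mean + SD/2 of the directed proximity values are 'preferred'
(reciprocated if both directions qualify); dyads at or below mean - SD/2 are
'non-preferred'. Mean degree of a dichotomized, OR-symmetrized network is the
proportion of possible ties present.
"""

import chimpnet as cn
from chimpnet import measures as cm
from chimpnet import networks as nets

attrs, model, scans, events = cn.generate_dataset(cn.CommunityConfig(seed=42))
counts = cn.count_dyads(scans)
prox = cn.association_matrix(counts)

bonds, thr = nets.classify_bonds(prox)
print(f"thresholds: mean {thr.mean:.2f} min/h, SD {thr.sd:.2f} "
      f"-> preferred >= {thr.upper:.2f}, non-preferred <= {thr.lower:.2f}")

for cls_name in nets.BOND_CLASSES:
    md, (lo, hi) = nets.mean_degree(nets.symmetrize_or(bonds[cls_name]))
    print(f"{cls_name:28s} {md:5.1f}% of possible ties (range {lo:.0f}-{hi:.0f}%)")

sym = nets.symmetrize_or(nets.dichotomize(prox))
md, (lo, hi) = nets.mean_degree(sym)
print(f"\noverall proximity network density: {md:.1f}% (range {lo:.0f}-{hi:.0f}%)")
deg = nets.degree_centrality(bonds.preferred_partner, "in")
print("proximity in-degree (preferred partners), top 3:")
print(deg.sort_values(ascending=False).head(3).round(3).to_string())
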