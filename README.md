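# chimpnet

Dyadic behavioral rates, proximity-bond networks and permutation inference for
fission–fusion primate communities.

`chimpnet` is a Python library for behavioral ecologists analysing focal-follow
data from species with fission–fusion dynamics (the motivating system is a wild
chimpanzee community sampled in 18-minute focal follows of nine instantaneous
scans at 2-minute intervals). It turns scan records (party membership, within-10-m
proximity, grooming state) and continuous communication event records (gestures,
pant-hoots, pant-grunts) into weighted directed social networks, classifies
proximity bonds, and performs permutation-based inference that respects the
non-independence of dyadic data.

## The measures and statistics

For an ordered dyad (A, B), with `P10` the number of scans A was within 10 m of B,
`PSP` the number of scans A was in the same party as B, `GR` the number of scans A
groomed with B, and `C` the number of gesture sequences (or call events) A directed
at B, the package computes per-hour rates from 2-minute scans:

- **Dyadic association** `DA = ((P10 × 2) × 60) / (PSP × 2)` — minutes within 10 m
  per hour spent in the same party, on [0, 60]. `DAK` and `DAR` are the same
  quantity restricted to kin dyads and to oestrous-female focals.
- **Dyadic grooming** `GA = ((GR × 2) × 60) / (P10 × 2)` — grooming minutes per
  hour within 10 m, per category (given / received / mutual).
- **Dyadic communication** `CA = (C × 60) / (P10 × 2)` — gesture sequences per hour
  within 10 m, per functional category. Sequences group consecutive gestures by one
  signaller to one recipient with the same goal and context at gaps ≤ 30 s.

A dyad with a zero denominator is *missing*, never zero. Networks are built per
behavior (12 × 12, directed, weighted), optionally dichotomized (value > 0 → tie)
and OR-symmetrized. Proximity bonds are classed against thresholds at the mean
± SD/2 of the directed dyad values: *preferred reciprocated* (both directions at
or above mean + SD/2), *preferred non-reciprocated*, *non-preferred* (at or below
mean − SD/2), and the reciprocation-agnostic *preferred partners*. Centrality is
normalized degree (row/column means), robust to partial sampling of a community.

Inference:

- **MRQAP** (double-semi-partialling): OLS over the vectorized off-diagonal dyads;
  per-predictor p-values from QAP permutations (joint row/column relabelings) of
  that predictor's residual matrix, compared two-tailed on the t-like pivot.
- **Node-level regression**: OLS on per-node quantities, permuting the outcome
  across nodes.
- **Geary's C**: autocorrelation between a node attribute and network weights;
  1.0 under no association, < 1.0 positive.

A synthetic generator (`chimpnet.synth`) plants a latent symmetric dyadic affinity
and a dominance order, then simulates party co-membership, proximity given party
(logistic in affinity), grooming given proximity, and per-category communication
events per hour in proximity — so every downstream stage can be tested against a
known truth.

## Worked example

```python
import chimpnet as cn
from chimpnet import measures as cm, networks as nets, permstats as ps

attrs, model, scans, events = cn.generate_dataset(cn.CommunityConfig(seed=42))
counts = cn.count_dyads(scans)
comm = cm.count_sequences(cm.assemble_sequences(events), events)

prox = cn.association_matrix(counts)
bonds, thr = nets.classify_bonds(prox)
res = ps.mrqap_dsp(
    prox,
    [nets.similarity_matrix(attrs, "kin"),
     nets.similarity_matrix(attrs, "sex"),
     cn.grooming_matrix(counts, "mutual"),
     cm.combined_gesture_matrix(comm, counts)],
    n_perm=2000, seed=42,
)
```

This prints (via `examples/03_bond_networks.py` and `examples/04_mrqap.py`):

```
thresholds: mean 20.47 min/h, SD 22.27 -> preferred >= 31.61, non-preferred <= 9.33
preferred_reciprocated        25.8% of possible ties (range 9-45%)
...
                 predictor     beta  std_beta       t  p_perm  r_squared
           grooming:mutual   3.5227    0.1670  1.5600  0.0935     0.5722
communication:all-gestures   4.1745    0.5278  4.9746  0.0005     0.5722
```

Mean association is 20.5 min/h with bond thresholds at 31.6 and 9.3 min/h; the
rate of gestural communication between two individuals strongly predicts how much
time they spend in close proximity (the generator plants exactly that
dependence through the shared affinity), while grooming adds a weaker positive
signal. The `examples/` directory has one short narrative script per capability;
a thin CLI (`chimpnet all --seed 1 --out run/`) runs the whole
generate → measure → network → inference pipeline and writes a reproducible
result bundle.

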