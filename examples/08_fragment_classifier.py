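"""Predict hit/miss responses from chemical fragments.

Labels sensor-compound pairs from fold-change confidence intervals, builds
a circular-fragment vocabulary over the compound library, and evaluates a
leave-one-out random forest for a sensor whose hits share a substructure.
"""

import pandas as pd

import cleavekit as ck
from cleavekit.fragments import aggregate_metrics, loo_evaluate

# hits are exactly the pyridine-bearing compounds
smiles, rows = {}, []
for i in range(24):
    cid = f"c{i:02d}"
    if i % 2 == 0:
        smiles[cid] = "c1ccncc1" + "C" * (1 + i % 3)
        lo, hi = 2.5, 6.0
    else:
        smiles[cid] = "C1CCCCC1" + "O" * (i % 2)
        lo, hi = 0.7, 1.5
    rows.append(("sensor1", cid, (lo + hi) / 2, lo, hi))

records = pd.DataFrame(rows, columns=["sensor_id", "compound_id", "fc", "ci90_lo", "ci90_hi"])
labels = ck.label_pairs(records)
print(labels["label"].value_counts().to_string())

vocab = ck.build_fragments(list(smiles.values()), radius_max=3)
print(f"\nfragment vocabulary: {len(vocab)} circular environments (radius <= 3)")

ev = loo_evaluate(labels, vocab, smiles, min_hits=3, seed=0)
agg = aggregate_metrics([ev])
print(f"confusion TN={agg.tn} FP={agg.fp} FN={agg.fn} TP={agg.tp}")
print(f"precision {agg.precision:.2f}, pooled AUC {agg.auc:.2f}")
print("(structure fully determines the label here, so both should be 1.00)")
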