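"""Validate the Nebula predictor by leave-one-out and two-fold cross-validation.

On the planted-module benchmark every edge is predicted from the network
with that edge removed (LOO), and the edge set is repeatedly split in half
with each half predicting the other (2-fold CV).  Reports sensitivity,
specificity, accuracy and the midrank AUC.
"""

from hlanet import (
    build_network,
    generate_network,
    leave_one_out,
    benchmark_small,
    repeated_kfold,
)
from hlanet.nebula import NebulaConfig
from hlanet.validation import summarize_reports

records, _ = generate_network(benchmark_small(seed=1))
net = build_network(records)
config = NebulaConfig(denominator_mode="absolute")

loo = leave_one_out(net, config)
print(f"leave-one-out over {loo.n_edges} edges:")
print(f"  sensitivity {loo.sensitivity:.3f}  specificity {loo.specificity:.3f}  "
      f"accuracy {loo.accuracy:.3f}  AUC {loo.auc:.3f}")
print(f"  fallback usage: {loo.fallback_counts}")

reports = repeated_kfold(net, k=2, iterations=10, base_seed=0, config=config)
s = summarize_reports(reports)
print(f"\n2-fold cross-validation, {s['iterations']} iterations:")
print(f"  accuracy {s['accuracy']['mean']:.3f} +/- {s['accuracy']['sd']:.3f}  "
      f"AUC {s['auc']['mean']:.3f} +/- {s['auc']['sd']:.3f}")
print("CV withholds half of the edges at a time, so its metrics sit slightly")
print("below leave-one-out; close agreement means the predictor is not")
print("overfitting the network it was scored on.")
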