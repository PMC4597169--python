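"""Score individual HLA-peptide pairs with the Nebula predictor.

Builds a small hand-readable network and walks through a prediction: the
two one-sided neighbour-edge estimates, their average F, and the categorical
call at the unbiased leverage UL = 1.5 (positive iff F >= UL).
"""

import numpy as np

from hlanet import predict
from hlanet.nebula import NebulaConfig
from hlanet.network import BipartiteNetwork

edges = {
    ("HLA-A*02:01", "SIINFEKL"): 2, ("HLA-A*02:01", "GILGFVFTL"): 2,
    ("HLA-A*02:02", "SIINFEKL"): 2, ("HLA-A*02:02", "GILGFVFTL"): 2,
    ("HLA-B*57:01", "SIINFEKL"): 1, ("HLA-B*57:01", "KAFSPEVI"): 2,
    ("HLA-A*02:01", "KAFSPEVI"): 1, ("HLA-A*02:02", "NLVPMVATV"): 2,
    ("HLA-B*57:01", "NLVPMVATV"): 1,
}
hlas = sorted({h for h, _ in edges})
peps = sorted({p for _, p in edges})
W = np.zeros((len(hlas), len(peps)))
for (h, p), w in edges.items():
    W[hlas.index(h), peps.index(p)] = w
net = BipartiteNetwork(hlas, peps, W)

# absolute mode divides the neighbour deviations by sum |S|, the classical
# collaborative-filtering convention that is immune to cancellation between
# positively and negatively correlated neighbours
config = NebulaConfig(denominator_mode="absolute")

for query in [("HLA-A*02:01", "NLVPMVATV"), ("HLA-B*57:01", "GILGFVFTL")]:
    res = predict(net, *query, config)
    print(f"{query[0]} x {query[1]}:")
    print(f"  HLA-side estimate     {res.side_hla:.3f} ({res.side_hla_flag})")
    print(f"  peptide-side estimate {res.side_peptide:.3f} ({res.side_peptide_flag})")
    print(f"  F = {res.F:.3f} -> call {res.C} (threshold UL = 1.5)")

print("F near 2 means the neighbour edges behave like positive binders;")
print("F near 1 like negatives.  The call is positive when F >= 1.5.")
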