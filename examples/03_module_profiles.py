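"""Characterise the peptides and alleles inside each binding module.

Tabulates peptide length buckets per module, the per-position residue
category profile of 9-mers (polar charged / polar uncharged / apolar), and
the within- vs between-module identity of position-specific HLA
pseudo-sequences extracted at the P2 contact residues.
"""

from hlanet import (
    build_network,
    fast_greedy_modules,
    generate_hla_alignment,
    generate_network,
    length_distribution,
    benchmark_small,
    position_category_profile,
    within_between_identity,
)
from hlanet.profiles import pseudo_sequences

spec = benchmark_small(seed=1)
records, truth = generate_network(spec)
net = build_network(records)
partition = fast_greedy_modules(net)

table = length_distribution(partition, net)
print("peptides per module and length bucket:")
print(table.counts.to_string())

nine_mers_m1 = [p for p in net.peptide_names
                if len(p) == 9 and partition.peptide_modules[p] == 1]
profile = position_category_profile(nine_mers_m1, 9)
print("\nresidue-category fractions of module 1's 9-mers (anchor bias at P2/P9):")
print(profile.round(2).to_string())

alignment, contact_map = generate_hla_alignment(spec)
pseudo = pseudo_sequences(alignment, contact_map, peptide_position=2)
identity = within_between_identity(partition.hla_modules, pseudo)
print("\nP2 pseudo-sequence identities (within vs between modules):")
print(identity.round(4).to_string())
print("Within-module identities are much higher than between-module ones:")
print("alleles clustered by binding behaviour share groove residues at the")
print("positions contacting peptide position 2.")
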