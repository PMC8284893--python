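"""Stable motifs, trap spaces, and driver nodes on the expanded network.

The parity-expanded network has two virtual nodes per variable, (i,1) and
(i,0), and one hyperedge per prime implicant of f_i and of !f_i.  A stable
motif is a minimal self-sustaining consistent set of virtual nodes; once
its values are attained the dynamics can never leave the associated trap
space.  A driver is a single virtual node whose logical domain of
influence (LDOI) switches an entire motif on.
"""

from paritybn import (
    build_parity_expanded_network,
    compute_ldoi,
    find_stable_motifs,
    motif_trap_space,
    single_node_drivers,
)
from paritybn.fixtures import motif_avoidant_demo

sys = motif_avoidant_demo()
pen = build_parity_expanded_network(sys)
print(f"{len(pen.hyperedges)} hyperedges, {len(pen.composite_nodes())} composite nodes")

motifs = find_stable_motifs(pen)
for m in motifs:
    print("stable motif:", sorted(f"{n}={s}" for n, s in m.nodes),
          "-> trap space", motif_trap_space(m).as_dict())

delta = single_node_drivers(pen, motifs)
print("single-node drivers (Delta):", sorted(f"{n}={s}" for n, s in delta))

for node in [("C", 1), ("C", 0), ("A", 1)]:
    res = compute_ldoi(pen, {node})
    print(f"LDOI({node[0]}={node[1]}) = {sorted(f'{n}={s}' for n, s in res.ldoi)}")

# Fixing C=1 percolates to the whole motif {A=1, B=1, C=1}; fixing C=0 or
# A=1 forces nothing, which is why an attractor can avoid the motif only by
# keeping C at 0.
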