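"""The succession diagram: cumulative stable-motif commitments.

Each node of the diagram is the union of motif vertex sets committed so
far; each edge is one irreversible decision.  Attractors attach either at
fully reduced nodes (all variables fixed) or as motif-avoidant attractors
found inside the terminal restriction space R(X) of a partially reduced
system.
"""

from paritybn import build_succession_diagram, terminal_restriction_space
from paritybn.fixtures import cascaded_switch, motif_avoidant_demo

sys = cascaded_switch()
sd = build_succession_diagram(sys)
print(f"cascade: {len(sd.nodes)} diagram nodes, "
      f"{len(sd.all_attractors())} attractors at the leaves")
for a in sd.all_attractors():
    print("  attractor:", a.state_strings())

# The cascade decides twice: first the A/B switch (off = one attractor;
# on fixes C=D=1), then the residual E/F toggle (two more attractors).

demo = motif_avoidant_demo()
trs = terminal_restriction_space(demo)
print("demo restriction predicate R(X):", trs.predicate.to_dnf_str())
print("admissible states:", [demo.state_to_str(s) for s in trs.states])
sd2 = build_succession_diagram(demo)
maa = sd2.nodes[frozenset()].motif_avoidant[0]
print("motif-avoidant attractor found there:", maa.state_strings())
# Only three states satisfy R(X) = !C & (!A | !B); the oscillation through
# exactly those three states is the demo's second attractor.
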