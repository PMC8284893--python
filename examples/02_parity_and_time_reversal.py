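"""Parity and time reversal of a Boolean system.

Parity flips every variable (X_i -> !X_i); its state transition graph is
the original one reflected through the center of the state hypercube.
Time reversal (f_i^- = !f_i with the self-input negated) reverses every
transition, and its fixed points are exactly the Garden-of-Eden states of
the forward dynamics: states no trajectory can ever reach.
"""

from paritybn import build_stg, garden_of_eden_states, parity_transform, time_reverse
from paritybn.fixtures import motif_avoidant_demo
from paritybn.system import write_bnet

sys = motif_avoidant_demo()
print("original rules:")
print(write_bnet(sys), end="")

rev = time_reverse(sys)
print("time-reversed rules (canonical DNF):")
print(write_bnet(rev, canonical=True), end="")

fwd_edges = set(build_stg(sys).edges)
rev_edges = set(build_stg(rev).edges)
assert rev_edges == {(v, u) for u, v in fwd_edges}
print(f"edge-reversal law holds on all {len(fwd_edges)} transitions")

goe = [sys.state_to_str(s) for s in garden_of_eden_states(sys)]
tr_fixed = [sys.state_to_str(s) for s in range(8) if rev.is_fixed_point(s)]
print(f"Garden-of-Eden states {goe} = fixed points of the reversal {tr_fixed}")

par = parity_transform(sys)
print("parity image of f_C:", par.functions["C"].to_dnf_str())
# A & B turns into A | B: parity exchanges the roles of 0 and 1 everywhere.
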