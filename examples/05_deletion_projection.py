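"""Deletion projection: variable elimination that preserves point attractors.

Variables that do not self-regulate are removed by substituting their
update function into their targets'.  Point attractors survive exactly
(each projected fixed point lifts to a representative parent state);
complex attractors can only become more numerous, so projected counts are
upper bounds.
"""

from paritybn import brute_force_attractors, deletion_project
from paritybn.fixtures import projection_demo

sys = projection_demo()  # toggle switch A/B plus slave variable C
pm, projected = deletion_project(sys)
print("deleted:", list(pm.deleted), "->", "kept:", list(projected.variables))
for v in projected.variables:
    print(f"  projected rule: {v} <- {projected.functions[v].to_dnf_str()}")

for a in brute_force_attractors(projected):
    (s,) = a.states
    rep = pm.lift_state(s)
    print(f"projected fixed point {projected.state_to_str(s)} lifts to "
          f"representative state {sys.state_to_str(rep)}")

# The three-variable toggle collapses onto one self-activating variable;
# its two fixed points lift to 101 and 010, the two parent fixed points.
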