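# paritybn

Attractor analysis of Boolean networks under stochastic asynchronous update,
built on two global symmetries of the dynamics: **parity** (the inversion
X_i ↦ ¬X_i of every variable) and **time reversal**.

Boolean models are a workhorse of systems biology: each gene or protein is a
binary variable X_i updated by a logic rule f_i, and the long-term behaviors
(attractors) of the model correspond to cell fates or persistent activity
patterns. Under asynchronous update the state transition graph (STG) has 2^N
states, so brute-force attractor search dies quickly with model size. This
package identifies the full attractor repertoire without building the STG,
by combining:

- the **parity-expanded network**: a hypergraph with two *virtual nodes*
  (i,1), (i,0) per variable and one hyperedge per prime implicant of f_i and
  of ¬f_i;
- **stable motifs**: minimal self-sustaining consistent virtual-node sets,
  each fixing a *trap space* that trajectories can never leave, explored
  recursively to form a **succession diagram** of irreversible commitments;
- the **time-reversed system** f_i⁻ = ¬f_i(X_i = ¬X_i), whose STG is the
  forward STG with every edge reversed; its stable motifs mark
  Garden-of-Eden spaces (regions no trajectory can enter), and its fixed
  points are exactly the Garden-of-Eden states;
- a **terminal restriction space** R(X) = ⋀_{I∈¬Δ} (σ_I ∧ F_I ∧
  ⋀_{J∈LDOI(I)} σ_J), where Δ collects all single-node motif drivers: any
  *motif-avoidant* attractor (a complex attractor that never locks in a
  motif) is confined to the states with R(X)=1, which shrinks the search
  space by orders of magnitude;
- **deletion projection**: elimination of non-self-regulating variables,
  which preserves point attractors exactly and never decreases the number of
  complex attractors, providing upper bounds and terminality tests.

As an application, the package reproduces (at desk scale) the scaling of the
mean attractor count ⟨A⟩ in critical Kauffman ensembles — random N–K
networks with K=2 regulators per node and activation bias p=0.5, the
critical point of 2Kp(1−p)=1 — via the nonlinear fit ⟨A⟩ = a + bN^c.

## Worked example

The three-variable system f_A = f_B = (¬X_A ∧ ¬X_B) ∨ X_C, f_C = X_A ∧ X_B
has one stable motif but **two** attractors — the second oscillates without
ever activating the motif:

```python
from paritybn import enumerate_attractors, terminal_restriction_space
from paritybn.fixtures import motif_avoidant_demo

sys = motif_avoidant_demo()
trs = terminal_restriction_space(sys)
print(trs.predicate.to_dnf_str())
print([sys.state_to_str(s) for s in trs.states])
for a in enumerate_attractors(sys).attractors:
    print(a.state_strings(), a.fixed_variables())
```

prints

```
!A & !C | !B & !C
['000', '100', '010']
['111'] {'A': 1, 'B': 1, 'C': 1}
['000', '010', '100'] {'C': 0}
```

The restriction predicate ¬X_C ∧ (¬X_A ∨ ¬X_B) admits exactly three states;
the motif-avoidant attractor is the oscillation through precisely those
states with C frozen at 0, alongside the point attractor 111 reached by
committing the motif {A=1, B=1, C=1}.

The same analyses are available from the shell:

```bash
paritybn attractors model.bnet          # JSON attractor report
paritybn motifs model.bnet              # motifs, trap spaces, drivers, LDOIs
paritybn succession model.bnet --dot    # succession diagram (DOT)
paritybn reverse model.bnet             # time-reversed rule file
paritybn rbn-scaling --sizes 2,4,8,16 --reps 50 --seed 1
```

Models are plain-text rule files (one `target, expression` line per
variable, `#` comments; `!/&/|` or `not/and/or`); packaged examples are
addressable as `fixture:<name>`. See `examples/` for narrative scripts
covering each capability.

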