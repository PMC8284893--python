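"""Packaged example systems used throughout the documentation and tests.

Each fixture is stored as rule-file text (so every one round-trips through
the reader/writer) with a loader returning the parsed system.  Provenance is
stated per fixture: some are classic minimal circuits reconstructed from
qualitative descriptions, and the tristable switch is a synthetic stand-in
constructed by seeded search to exhibit a prescribed attractor repertoire.
"""

from __future__ import annotations

from .system import BooleanSystem, parse_bnet

__all__ = [
    "motif_avoidant_demo",
    "mutual_inhibition_switch",
    "cascaded_switch",
    "projection_demo",
    "phase_switch_synthetic",
    "FIXTURES",
]


MOTIF_AVOIDANT_DEMO = """\
# Three-variable system whose only stable motif fixes all variables at 1,
# while a second, motif-avoidant attractor keeps C at 0 with A and B
# oscillating: {000, 010, 100}.
A, (!A & !B) | C
B, (!A & !B) | C
C, A & B
"""


MUTUAL_INHIBITION_SWITCH = """\
# Toggle switch: mutual inhibition between A and B with a readout C.
# Two stable motifs, {A=1, B=0} and {A=0, B=1}, each fixing a trap space.
# Reconstructed from a qualitative description of the circuit, not from a
# printed rule set.
A, !B
B, !A
C, A | B
"""


CASCADED_SWITCH = """\
# Six-variable cascade: a mutual-activation switch on (A, B) that, once
# locked on, fixes C and D and leaves a bistable subsystem on (E, F); a
# second decision is then made between E=1,F=0 and E=0,F=1.  Three stable
# motifs in the full system, three point attractors overall.  Reconstructed
# from a qualitative description of the circuit, not from a printed rule set.
A, B
B, A
C, A
D, B
E, !F & C
F, !E
"""


PROJECTION_DEMO = """\
# Toggle switch driving a slave variable C; deleting C and then B projects
# the system onto a single self-activating variable A while preserving both
# point attractors (with representative states 101 and 010).  Reconstructed
# from a qualitative description of the circuit, not from a printed rule set.
A, !B
B, !A
C, A
"""


PHASE_SWITCH_SYNTHETIC = """\
# Synthetic tristable switch (stand-in, constructed by seeded search over
# quenched K=2 networks): exactly three point attractors and exactly three
# Garden-of-Eden states, the latter arising as the fixed points of the
# time-reversed system.  It emulates the attractor/Garden-of-Eden structure
# of a cell-cycle phase-switch circuit without reproducing its biology.
A, !B & !F
B, !A & B
C, A & E
D, !E & F
E, !C | E
F, !A | !E
"""


def motif_avoidant_demo() -> BooleanSystem:
    """The in-text three-variable system with a motif-avoidant attractor."""
    return parse_bnet(MOTIF_AVOIDANT_DEMO)


def mutual_inhibition_switch() -> BooleanSystem:
    """Toggle switch plus readout (caption-reconstructed)."""
    return parse_bnet(MUTUAL_INHIBITION_SWITCH)


def cascaded_switch() -> BooleanSystem:
    """Two-stage decision cascade (caption-reconstructed)."""
    return parse_bnet(CASCADED_SWITCH)


def projection_demo() -> BooleanSystem:
    """Toggle switch with a slave variable (caption-reconstructed)."""
    return parse_bnet(PROJECTION_DEMO)


def phase_switch_synthetic() -> BooleanSystem:
    """Synthetic tristable switch with three Garden-of-Eden states."""
    return parse_bnet(PHASE_SWITCH_SYNTHETIC)


FIXTURES = {
    "motif-avoidant-demo": motif_avoidant_demo,
    "mutual-inhibition-switch": mutual_inhibition_switch,
    "cascaded-switch": cascaded_switch,
    "projection-demo": projection_demo,
    "phase-switch-synthetic": phase_switch_synthetic,
}
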