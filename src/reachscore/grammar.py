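"""Canonical movement-element vocabulary for the single-pellet reaching task.

A successful reach decomposes into seven scored elements executed in a fixed
order (lift, aim, advance, pronation, grasp, supination I, supination II),
followed by a terminal eating phase.  Two further categories occur only in one
experimental condition: reaching for the pellet with the mouth (a compensatory
movement seen after motor-cortex stroke) and eating the pellet with both hands
(a normal terminal behavior that disappears after stroke).
"""

from __future__ import annotations

# Seven expert-scored reach elements, in execution order.
SCORED_ELEMENTS: tuple[str, ...] = (
    "lift",
    "aim",
    "advance",
    "pronation",
    "grasp",
    "supination_i",
    "supination_ii",
)

# Terminal phases.
EAT = "eat"
EAT_WITH_HANDS = "eat_with_hands"      # control-typical terminal behavior
REACH_WITH_MOUTH = "reach_with_mouth"  # stroke-typical compensatory movement

#: Every category the generator and the discovery analytics know about.
ALL_CATEGORIES: tuple[str, ...] = SCORED_ELEMENTS + (
    EAT,
    EAT_WITH_HANDS,
    REACH_WITH_MOUTH,
)

#: Label for clusters whose probe frames reach no category quorum.
NOT_CLEAR = "not_clear"

# Ordinal position of each category along the reach sequence.  Positions drive
# the +/-1-category tolerance when scoring automated segmentation: confusing a
# movement with its temporal neighbour is counted as a success.  The two
# condition-specific categories sit at the phase of the reach they replace:
# mouth-reaching substitutes for the mid-reach advance/pronation phase and both
# terminal eating styles share the final slot.
ORDINAL_POSITION: dict[str, int] = {
    "lift": 0,
    "aim": 1,
    "advance": 2,
    "pronation": 3,
    "grasp": 4,
    "supination_i": 5,
    "supination_ii": 6,
    EAT: 7,
    EAT_WITH_HANDS: 7,
    REACH_WITH_MOUTH: 3,
}

#: Integer id per category (stable encoding for classifier targets).
CATEGORY_INDEX: dict[str, int] = {c: i for i, c in enumerate(ALL_CATEGORIES)}
INDEX_CATEGORY: dict[int, str] = {i: c for c, i in CATEGORY_INDEX.items()}


def positions_of(labels) -> list[int]:
    """Map category names to their ordinal reach positions.

    Raises ``KeyError`` with the offending label for unknown categories, which
    is the configuration error surfaced when segmentation metrics are asked to
    compare timelines over an unordered vocabulary.
    """
    return [ORDINAL_POSITION[lab] for lab in labels]
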