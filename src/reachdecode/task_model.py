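"""Condition algebra for the bimanual reach-to-grasp task.

The experiment crosses two reaching directions (left/right handle of a
two-handle object), two hand actions (grasp vs. touch), and two effectors
(left/right hand), giving eight experimental conditions.  A condition is
written as a three-letter code ``<direction><action><hand>``; e.g. ``LGR``
is the right hand grasping the left handle.

Binary class labelings used by the decoders:

``action``
    grasp vs. touch; independent of direction and hand.
``extrinsic``
    object-centered spatial congruency — which handle is the target.
    Identical for both hands (``RGL`` and ``RGR`` share a class).
``intrinsic``
    limb-centered joint-space congruency — ipsilateral vs. contralateral
    reach.  Mirrored between hands (``RTL`` and ``LTR`` share a class,
    both being contralateral reaches).

Class-id convention (fixed so confusion matrices are comparable across
runs): class 0 = left handle / ipsilateral / touch; class 1 = the
complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Dict, List, Tuple

__all__ = [
    "Direction",
    "Action",
    "Hand",
    "TrialCondition",
    "ClassLabeling",
    "ClassifierSpec",
    "ALL_CONDITIONS",
    "parse_condition_code",
    "action_class",
    "extrinsic_class",
    "intrinsic_class",
    "within_hand_groups",
    "cross_hand_groups",
    "classifier_groups",
]


class Direction(Enum):
    """Target handle in object-centered coordinates."""

    LEFT = "L"
    RIGHT = "R"

    @property
    def other(self) -> "Direction":
        return Direction.LEFT if self is Direction.RIGHT else Direction.RIGHT


class Action(Enum):
    """Hand-object interaction type."""

    GRASP = "G"
    TOUCH = "T"


class Hand(Enum):
    """Effector performing the trial."""

    LEFT = "L"
    RIGHT = "R"

    @property
    def other(self) -> "Hand":
        return Hand.LEFT if self is Hand.RIGHT else Hand.RIGHT


@dataclass(frozen=True)
class TrialCondition:
    """One of the eight experimental conditions."""

    direction: Direction
    action: Action
    hand: Hand

    @property
    def code(self) -> str:
        """Three-letter code, e.g. ``LGR``."""
        return self.direction.value + self.action.value + self.hand.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code

    def __repr__(self) -> str:
        return f"TrialCondition({self.code!r})"


_FIELDS = (("direction", Direction), ("action", Action), ("hand", Hand))


def parse_condition_code(code: str) -> TrialCondition:
    """Parse a three-letter condition code into a :class:`TrialCondition`.

    Raises :class:`ValueError` naming the offending position for malformed
    codes.
    """
    if not isinstance(code, str) or len(code) != 3:
        raise ValueError(f"condition code must be a 3-character string, got {code!r}")
    values = []
    for pos, (name, enum_cls) in enumerate(_FIELDS):
        letter = code[pos].upper()
        try:
            values.append(enum_cls(letter))
        except ValueError:
            valid = "/".join(m.value for m in enum_cls)
            raise ValueError(
                f"invalid {name} letter {code[pos]!r} at position {pos + 1} of "
                f"condition code {code!r}; expected one of {valid}"
            ) from None
    return TrialCondition(*values)


ALL_CONDITIONS: Tuple[TrialCondition, ...] = tuple(
    TrialCondition(d, a, h) for d, a, h in product(Direction, Action, Hand)
)


def action_class(cond: TrialCondition) -> int:
    """Grasp/touch class: 0 = touch, 1 = grasp."""
    return 0 if cond.action is Action.TOUCH else 1


def extrinsic_class(cond: TrialCondition) -> int:
    """Object-centered class: 0 = left handle, 1 = right handle.

    Depends only on the direction field, so the same handle shares a class
    across hands.
    """
    return 0 if cond.direction is Direction.LEFT else 1


def intrinsic_class(cond: TrialCondition) -> int:
    """Limb-centered class: 0 = ipsilateral reach, 1 = contralateral.

    Ipsilateral iff the target handle is on the same side as the acting
    hand (direction letter equals hand letter).
    """
    return 0 if cond.direction.value == cond.hand.value else 1


class ClassLabeling(Enum):
    """Binary class labeling scheme applied to a condition pool."""

    EXTRINSIC = "extrinsic"
    INTRINSIC = "intrinsic"
    ACTION = "action"

    def class_of(self, cond: TrialCondition) -> int:
        if self is ClassLabeling.EXTRINSIC:
            return extrinsic_class(cond)
        if self is ClassLabeling.INTRINSIC:
            return intrinsic_class(cond)
        return action_class(cond)


_TARGETS = ("action", "direction")
_MONTAGE_MODES = ("standard", "mirror")


@dataclass(frozen=True)
class ClassifierSpec:
    """One binary classifier: its training conditions, test conditions
    (empty for within-hand cross-validation), decoded target, class
    labeling, and montage mode for the test data."""

    train_pair: Tuple[TrialCondition, TrialCondition]
    test_pair: Tuple[TrialCondition, ...]
    target: str
    labeling: ClassLabeling
    montage_mode: str = "standard"

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}, got {self.target!r}")
        if self.montage_mode not in _MONTAGE_MODES:
            raise ValueError(
                f"montage_mode must be one of {_MONTAGE_MODES}, got {self.montage_mode!r}"
            )
        if len(self.train_pair) != 2:
            raise ValueError("train_pair must hold exactly two conditions")
        if self.train_pair[0].hand is not self.train_pair[1].hand:
            raise ValueError("train_pair conditions must share a hand")
        if self.test_pair:
            if len(self.test_pair) != 2:
                raise ValueError("test_pair must be empty or hold two conditions")
            if self.test_pair[0].hand is not self.test_pair[1].hand:
                raise ValueError("test_pair conditions must share a hand")
            if self.test_pair[0].hand is self.train_pair[0].hand:
                raise ValueError("cross-hand test_pair must use the opposite hand")

    @property
    def is_within_hand(self) -> bool:
        return not self.test_pair

    @property
    def train_hand(self) -> Hand:
        return self.train_pair[0].hand

    @property
    def test_hand(self) -> Hand:
        if self.is_within_hand:
            return self.train_hand
        return self.test_pair[0].hand

    def class_of(self, cond: TrialCondition) -> int:
        """Binary class of a condition under this classifier.

        Action decoders always classify grasp vs. touch; direction
        decoders classify according to ``labeling``.
        """
        if self.target == "action":
            return action_class(cond)
        return self.labeling.class_of(cond)

    @property
    def name(self) -> str:
        train = "/".join(c.code for c in self.train_pair)
        if self.is_within_hand:
            return train
        return train + "->" + "/".join(c.code for c in self.test_pair)


def within_hand_groups() -> Dict[str, List[ClassifierSpec]]:
    """The two within-hand classifier groups (four classifiers each).

    The action group pairs conditions that differ only in action
    (LGL/LTL, RGL/RTL, LGR/LTR, RGR/RTR); the direction group pairs
    conditions that differ only in direction.
    """
    groups: Dict[str, List[ClassifierSpec]] = {"action": [], "direction": []}
    for hand in Hand:
        for d in Direction:
            pair = (TrialCondition(d, Action.GRASP, hand), TrialCondition(d, Action.TOUCH, hand))
            groups["action"].append(ClassifierSpec(pair, (), "action", ClassLabeling.ACTION))
        for a in Action:
            pair = (
                TrialCondition(Direction.LEFT, a, hand),
                TrialCondition(Direction.RIGHT, a, hand),
            )
            groups["direction"].append(
                ClassifierSpec(pair, (), "direction", ClassLabeling.EXTRINSIC)
            )
    return groups


def cross_hand_groups() -> Dict[Tuple[str, str, str], List[ClassifierSpec]]:
    """Cross-hand classifier groups keyed by (target, labeling, montage).

    Each group holds four classifiers covering both transfer directions
    (train left -> test right and vice versa) and both values of the
    non-decoded factor.  For direction decoders the class labeling
    (extrinsic/intrinsic) assigns classes to the same four-condition pool;
    for action decoders it selects which contralateral conditions are
    paired with the training pair (same handle for extrinsic, mirrored
    handle for intrinsic).
    """
    groups: Dict[Tuple[str, str, str], List[ClassifierSpec]] = {}
    for target in _TARGETS:
        for labeling in (ClassLabeling.EXTRINSIC, ClassLabeling.INTRINSIC):
            for montage_mode in _MONTAGE_MODES:
                specs: List[ClassifierSpec] = []
                for train_hand in Hand:
                    test_hand = train_hand.other
                    if target == "direction":
                        for a in Action:
                            train_pair = (
                                TrialCondition(Direction.LEFT, a, train_hand),
                                TrialCondition(Direction.RIGHT, a, train_hand),
                            )
                            test_pair = (
                                TrialCondition(Direction.LEFT, a, test_hand),
                                TrialCondition(Direction.RIGHT, a, test_hand),
                            )
                            specs.append(
                                ClassifierSpec(train_pair, test_pair, target, labeling, montage_mode)
                            )
                    else:
                        for d in Direction:
                            train_pair = (
                                TrialCondition(d, Action.GRASP, train_hand),
                                TrialCondition(d, Action.TOUCH, train_hand),
                            )
                            test_d = d if labeling is ClassLabeling.EXTRINSIC else d.other
                            test_pair = (
                                TrialCondition(test_d, Action.GRASP, test_hand),
                                TrialCondition(test_d, Action.TOUCH, test_hand),
                            )
                            specs.append(
                                ClassifierSpec(train_pair, test_pair, target, labeling, montage_mode)
                            )
                groups[(target, labeling.value, montage_mode)] = specs
    return groups


def classifier_groups() -> Dict[Tuple[str, ...], List[ClassifierSpec]]:
    """All classifier groups: within-hand and cross-hand.

    Keys are ``("within", target)`` and
    ``("cross", target, labeling, montage_mode)``.
    """
    out: Dict[Tuple[str, ...], List[ClassifierSpec]] = {}
    for target, specs in within_hand_groups().items():
        out[("within", target)] = specs
    for key, specs in cross_hand_groups().items():
        out[("cross",) + key] = specs
    return out
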