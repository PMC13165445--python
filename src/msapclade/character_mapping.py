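"""Parsimony mapping of binary morphological characters onto a fixed tree.

Given a phylogeny inferred from molecular markers, each binary
morphological/anatomical character (coded absent 0 / present 1) is optimized
on the tree under unordered (Fitch) parsimony.  The minimum number of state
changes, together with the outgroup-defined ancestral state, classifies the
character:

* ``plesiomorphic`` — invariant among scored taxa (0 steps);
* ``autapomorphy``  — a single change placing the derived state on one tip;
* ``synapomorphy``  — a single change placing the derived state on a clade
  of two or more tips (the character diagnoses that clade);
* ``homoplastic``   — more than one change: the derived state arose (or was
  lost) repeatedly, so the character conflicts with the tree.

Missing states are wildcards and force no changes.  Polytomies are handled
with Hartigan's generalization of the Fitch algorithm, which remains exact
for minimum-change counting on multifurcating trees.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

MISSING_STATE: int = -1

CLASS_PLESIOMORPHIC = "plesiomorphic"
CLASS_AUTAPOMORPHY = "autapomorphy"
CLASS_SYNAPOMORPHY = "synapomorphy"
CLASS_HOMOPLASTIC = "homoplastic"


class CharacterError(ValueError):
    """Character data inconsistent with the tree."""


@dataclass
class CharacterMatrix:
    """Taxa x binary characters, with an optional designated outgroup."""

    taxa: list[str]
    characters: list[str]
    values: np.ndarray  # int8 in {0, 1, MISSING_STATE}
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.taxa)) != len(self.taxa):
            raise CharacterError("duplicate taxon labels")
        if len(set(self.characters)) != len(self.characters):
            raise CharacterError("duplicate character labels")
        if self.values.shape != (len(self.taxa), len(self.characters)):
            raise CharacterError("values shape does not match labels")
        if not np.isin(self.values, (0, 1, MISSING_STATE)).all():
            raise CharacterError("states must be 0, 1 or missing")
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise CharacterError(f"outgroup {self.outgroup!r} not among taxa")

    def column(self, character: str) -> dict[str, int]:
        j = self.characters.index(character)
        return {t: int(v) for t, v in zip(self.taxa, self.values[:, j])}


def read_character_matrix(
    path: str | os.PathLike, outgroup: str | None = None
) -> CharacterMatrix:
    """Read a delimited taxa-x-characters table (0/1/?, header row)."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0)
    vals = df.map(lambda t: MISSING_STATE if str(t).strip() == "?" else int(t))
    return CharacterMatrix(
        taxa=[str(t) for t in df.index],
        characters=[str(c) for c in df.columns],
        values=vals.to_numpy(dtype=np.int8),
        outgroup=outgroup,
    )


# -- Fitch / Hartigan ------------------------------------------------------


def _leaf_states(t: TreeNode, states: Mapping[str, int]) -> dict[str, int]:
    tips = {tip.name for tip in t.tips()}
    missing = tips - set(states)
    if missing:
        raise CharacterError(f"no state for tree leaves: {sorted(missing)}")
    observed = [s for n, s in states.items() if n in tips and s != MISSING_STATE]
    if not observed:
        raise CharacterError("character has no observed state on the tree")
    return {n: int(states[n]) for n in tips}


def _hartigan_up(node: TreeNode, states: Mapping[str, int]) -> tuple[frozenset, int]:
    """Bottom-up pass: (state set, min changes) for the subtree at ``node``."""
    if node.is_tip():
        s = states[node.name]
        return (frozenset((0, 1)) if s == MISSING_STATE else frozenset((s,))), 0
    steps = 0
    count = {0: 0, 1: 0}
    for child in node.children:
        cs, c_steps = _hartigan_up(child, states)
        steps += c_steps
        for s in cs:
            count[s] += 1
    best = max(count.values())
    node_set = frozenset(s for s, k in count.items() if k == best)
    return node_set, steps + (len(node.children) - best)


def fitch_steps(t: TreeNode, states: Mapping[str, int]) -> int:
    """Minimum number of unordered state changes for one character.

    ``states`` maps every leaf name to 0, 1 or :data:`MISSING_STATE`
    (wildcard).  The count is invariant to the arbitrary rooting of an
    unrooted tree object.
    """
    leaf = _leaf_states(t, states)
    _, steps = _hartigan_up(t, leaf)
    return steps


def total_steps(t: TreeNode, m: CharacterMatrix) -> int:
    """Tree length: summed Fitch steps over all characters of ``m``."""
    return sum(fitch_steps(t, m.column(c)) for c in m.characters)


def _assign_states(
    t: TreeNode, states: Mapping[str, int]
) -> tuple[dict[int, int], bool]:
    """One optimal internal labeling (down-pass, ties prefer state 0).

    Returns ``(labels, ambiguous)`` where ``labels`` maps ``id(node)`` to a
    state and ``ambiguous`` flags the existence of other optimal labelings.
    """
    leaf = _leaf_states(t, states)
    sets: dict[int, frozenset] = {}
    for node in t.postorder():
        if node.is_tip():
            s = leaf[node.name]
            sets[id(node)] = (
                frozenset((0, 1)) if s == MISSING_STATE else frozenset((s,))
            )
        else:
            count = {0: 0, 1: 0}
            for child in node.children:
                for s in sets[id(child)]:
                    count[s] += 1
            best = max(count.values())
            sets[id(node)] = frozenset(s for s, k in count.items() if k == best)

    labels: dict[int, int] = {}
    ambiguous = False
    for node in t.preorder():
        cand = sets[id(node)]
        if node.is_root():
            choice = min(cand)
            ambiguous |= len(cand) > 1
        else:
            parent_state = labels[id(node.parent)]
            if parent_state in cand:
                choice = parent_state
            else:
                choice = min(cand)
                ambiguous |= len(cand) > 1
        labels[id(node)] = choice
    return labels, ambiguous


@dataclass
class CharacterFit:
    """Parsimony optimization result for one character on one tree."""

    character: str
    steps: int
    classification: str
    derived_state: int | None
    derived_tips: tuple[str, ...]
    node_states: dict[int, int] = field(repr=False, default_factory=dict)
    ambiguous: bool = False


def classify_character(
    t: TreeNode, states: Mapping[str, int], outgroup: str, character: str = ""
) -> CharacterFit:
    """Classify a binary character on an outgroup-rooted tree.

    The outgroup's state defines the plesiomorphic (ancestral) condition;
    the opposite state is derived.  Classification follows the step count
    and the distribution of the derived state over ingroup tips (see module
    docstring).  The outgroup state must be observed.
    """
    leaf = _leaf_states(t, states)
    if outgroup not in leaf:
        raise CharacterError(f"outgroup {outgroup!r} is not a leaf")
    anc = leaf[outgroup]
    if anc == MISSING_STATE:
        raise CharacterError("outgroup state is missing; cannot polarize")
    derived = 1 - anc
    steps = fitch_steps(t, leaf)
    node_states, ambiguous = _assign_states(t, leaf)
    derived_tips = tuple(
        n for n, s in leaf.items() if s == derived and n != outgroup
    )
    if steps == 0:
        cls = CLASS_PLESIOMORPHIC
    elif steps == 1 and len(derived_tips) == 1:
        cls = CLASS_AUTAPOMORPHY
    elif steps == 1 and len(derived_tips) >= 2:
        cls = CLASS_SYNAPOMORPHY
    else:
        cls = CLASS_HOMOPLASTIC
    return CharacterFit(
        character=character,
        steps=steps,
        classification=cls,
        derived_state=derived if steps > 0 else None,
        derived_tips=derived_tips,
        node_states=node_states,
        ambiguous=ambiguous,
    )


def classify_all(
    t: TreeNode, m: CharacterMatrix, outgroup: str | None = None
) -> pd.DataFrame:
    """Step counts and classifications for every character of ``m``."""
    og = outgroup or m.outgroup
    if og is None:
        raise CharacterError("an outgroup is required for classification")
    fits = [classify_character(t, m.column(c), og, character=c) for c in m.characters]
    return pd.DataFrame(
        {
            "character": [f.character for f in fits],
            "steps": [f.steps for f in fits],
            "classification": [f.classification for f in fits],
            "derived_tips": [";".join(f.derived_tips) for f in fits],
            "ambiguous": [f.ambiguous for f in fits],
        }
    )
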