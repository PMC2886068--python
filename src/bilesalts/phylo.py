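"""Mapping discrete bile-salt characters onto phylogenies.

Three comparative operations live here:

* **Conservation screening**: for each taxonomic group (family, order), the
  set of profile classes among its members, a heterogeneity flag when more
  than one class occurs, and an overlap flag when all members still share at
  least one compound type at the 10% threshold.
* **Parsimony ancestral reconstruction**: minimum-change (Fitch-style)
  reconstruction of a discrete character on a rooted tree, generalized to
  polytomies.  The implementation is exact unit-cost parsimony by dynamic
  programming (Sankoff recursion with an up- and a down-pass), which on
  binary trees reduces to the classic Fitch set algorithm and on polytomies
  still attains the global minimum — the naive "iterate intersection/union
  over children" shortcut can undercount changes at polytomies (four children
  in states A, A, B, B need two changes whichever state the node takes, but
  sequential set-merging reports one).  Per node the *full* set of states
  attainable in some most-parsimonious labeling is reported; ties are
  information, not errors.
* **Pairwise protein identity**: global alignment (BLOSUM62, gap open 10,
  extend 0.5) with identity computed over all alignment columns including
  gaps — the convention matters and is therefore fixed and documented here.

Trees are dendropy objects; tips are matched to character states by taxon
label.  Tips without a state are pruned (set ``missing_policy="error"`` to
refuse instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import dendropy

from .diet import round_half_up
from .errors import ConfigurationError, MissingDataError, ValidationError
from .profiles import ProfileClass, SpeciesProfile, TYPE_THRESHOLD, assign_class, type_aggregates
from .compounds import CompoundType

__all__ = [
    "CharacterMatrix",
    "AncestralReconstruction",
    "fitch_ancestral",
    "conservation_report",
    "GroupConservation",
    "pairwise_identity",
    "presence_characters",
]

_INF = float("inf")


# ---------------------------------------------------------------------------
# Character matrices
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Species x discrete-character states; missing data encoded as None."""

    species: list
    characters: dict  # name -> {species: state or None}

    def column(self, name: str) -> dict:
        if name not in self.characters:
            raise ConfigurationError(f"unknown character {name!r}")
        return {
            sp: st for sp, st in self.characters[name].items() if st is not None
        }

    def alphabet(self, name: str) -> tuple:
        return tuple(sorted({v for v in self.column(name).values()}, key=str))


def presence_characters(profiles: Sequence[SpeciesProfile]) -> CharacterMatrix:
    """Binary presence/absence characters per compound type (>=10% rule).

    These are the characters used for ancestral inference: gains and losses
    of whole compound types, not the seven-level class character.
    """
    species = [p.species for p in profiles]
    chars: dict[str, dict] = {
        "C27_alcohol_present": {},
        "C27_acid_present": {},
        "C24_acid_present": {},
    }
    for p in profiles:
        agg = type_aggregates(p)
        chars["C27_alcohol_present"][p.species] = (
            "present" if agg.get(CompoundType.C27_ALCOHOL, 0.0) >= TYPE_THRESHOLD else "absent"
        )
        chars["C27_acid_present"][p.species] = (
            "present" if agg.get(CompoundType.C27_ACID, 0.0) >= TYPE_THRESHOLD else "absent"
        )
        chars["C24_acid_present"][p.species] = (
            "present" if agg.get(CompoundType.C24_ACID, 0.0) >= TYPE_THRESHOLD else "absent"
        )
    return CharacterMatrix(species=species, characters=chars)


# ---------------------------------------------------------------------------
# Exact unit-cost parsimony
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Most-parsimonious state sets per node plus the minimal change count."""

    change_count: int
    node_states: dict  # dendropy.Node -> frozenset of states
    alphabet: tuple

    def states_by_label(self) -> dict:
        """State sets keyed by node label (internal) or taxon label (tips)."""
        out = {}
        for node, states in self.node_states.items():
            if node.taxon is not None:
                out[node.taxon.label] = states
            elif node.label:
                out[node.label] = states
        return out

    @property
    def root_states(self) -> frozenset:
        return min(
            (states for node, states in self.node_states.items()
             if node.parent_node is None),
            default=frozenset(),
        )


def _tip_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def fitch_ancestral(
    tree: dendropy.Tree,
    states: Mapping[str, Hashable],
    alphabet: Sequence[Hashable] | None = None,
    missing_policy: str = "prune",
) -> AncestralReconstruction:
    """Exact minimum-change ancestral reconstruction on a rooted tree.

    ``states`` maps tip labels to discrete states.  Tips absent from the
    mapping are pruned (ignored) under the default policy, or rejected with
    :class:`MissingDataError` under ``missing_policy="error"``.  Polytomies
    are handled exactly; the returned per-node sets contain every state that
    occurs at that node in at least one globally most-parsimonious labeling.
    """
    if missing_policy not in ("prune", "error"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")

    leaves = [n for n in tree.leaf_node_iter()]
    if not leaves:
        raise ConfigurationError("tree has no leaves")
    missing = [
        _tip_label(n) for n in leaves
        if _tip_label(n) not in states
    ]
    if missing and missing_policy == "error":
        raise MissingDataError(
            f"tips without character states: {sorted(map(str, missing))}"
        )
    scored = {lbl: st for lbl, st in states.items()}
    if alphabet is None:
        alphabet = tuple(sorted({v for v in scored.values()}, key=str))
    else:
        alphabet = tuple(alphabet)
        extra = {v for v in scored.values()} - set(alphabet)
        if extra:
            raise ValidationError(f"tip states outside alphabet: {sorted(map(str, extra))}")
    if not alphabet:
        raise MissingDataError("no tip carries a character state")
    index = {s: i for i, s in enumerate(alphabet)}
    k = len(alphabet)

    # A node is active if at least one descendant tip has a state.
    active: dict[dendropy.Node, bool] = {}
    up: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        children = [c for c in node.child_nodes() if active.get(c, False)]
        if node.is_leaf():
            lbl = _tip_label(node)
            if lbl in scored:
                active[node] = True
                costs = [_INF] * k
                costs[index[scored[lbl]]] = 0.0
                up[node] = costs
            else:
                active[node] = False
        elif children:
            active[node] = True
            costs = []
            for s in range(k):
                total = 0.0
                for c in children:
                    total += min(
                        up[c][t] + (0.0 if t == s else 1.0) for t in range(k)
                    )
                costs.append(total)
            up[node] = costs
        else:
            active[node] = False

    root = tree.seed_node
    if not active.get(root, False):
        raise MissingDataError("no tip carries a character state")
    change_count = min(up[root])

    # Down-pass: cost of the rest of the tree given this node's state.
    down: dict[dendropy.Node, list[float]] = {root: [0.0] * k}
    for node in tree.preorder_node_iter():
        if not active.get(node, False) or node not in down:
            continue
        children = [c for c in node.child_nodes() if active.get(c, False)]
        for c in children:
            siblings = [x for x in children if x is not c]
            c_down = []
            for s in range(k):
                best = _INF
                for t in range(k):
                    cost = down[node][t] + (0.0 if t == s else 1.0)
                    for x in siblings:
                        cost += min(
                            up[x][u] + (0.0 if u == t else 1.0) for u in range(k)
                        )
                    best = min(best, cost)
                c_down.append(best)
            down[c] = c_down

    node_states: dict[dendropy.Node, frozenset] = {}
    for node in tree.preorder_node_iter():
        if not active.get(node, False):
            continue
        totals = [up[node][s] + down[node][s] for s in range(k)]
        node_states[node] = frozenset(
            alphabet[s] for s in range(k) if totals[s] == change_count
        )
    return AncestralReconstruction(
        change_count=int(change_count),
        node_states=node_states,
        alphabet=alphabet,
    )


# ---------------------------------------------------------------------------
# Within-group conservation screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupConservation:
    group: str
    n_species: int
    classes: frozenset  # ProfileClass values among members
    heterogeneous: bool  # more than one class in the group
    types_overlap: bool  # all members share >=1 compound type at threshold


def conservation_report(
    profiles: Sequence[SpeciesProfile],
    rank: str = "family",
) -> list[GroupConservation]:
    """Per-group profile-class conservation summary.

    ``rank`` selects the grouping attribute: ``"family"`` or
    ``"order_or_group"``.  Groups are returned sorted by name.
    """
    if rank not in ("family", "order_or_group"):
        raise ConfigurationError(f"unknown taxonomy rank {rank!r}")
    groups: dict[str, list[SpeciesProfile]] = {}
    for p in profiles:
        key = getattr(p, rank)
        if not key:
            continue
        groups.setdefault(key, []).append(p)

    out = []
    for name in sorted(groups):
        members = groups[name]
        classes = frozenset(assign_class(p) for p in members)
        type_sets = [
            frozenset(
                t for t, pct in type_aggregates(p).items()
                if t is not CompoundType.OTHER and pct >= TYPE_THRESHOLD
            )
            for p in members
        ]
        shared = frozenset.intersection(*type_sets) if type_sets else frozenset()
        out.append(
            GroupConservation(
                group=name,
                n_species=len(members),
                classes=classes,
                heterogeneous=len(classes) > 1,
                types_overlap=bool(shared),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pairwise protein identity
# ---------------------------------------------------------------------------

_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBZX")


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent identity from a global protein alignment.

    BLOSUM62 scoring with affine gaps (open 10, extend 0.5 by default);
    identity is identical aligned positions divided by total alignment
    columns (gap columns included), times 100, rounded half-up to one
    decimal.  When several alignments are co-optimal the first reported by
    the aligner is used; identity differences between co-optimal alignments
    are below the reporting precision in practice.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for label, seq in (("first", seq_a), ("second", seq_b)):
        if not seq:
            raise ValidationError(f"{label} sequence is empty")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValidationError(
                f"{label} sequence contains non-amino-acid characters: {sorted(bad)}"
            )

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return round_half_up(100.0 * counts.identities / columns)
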