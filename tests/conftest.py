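import itertools

import dendropy
import numpy as np
import pytest

from bilesalts.compounds import parse_name
from bilesalts.profiles import ProfileComponent, SpeciesProfile

# Representative compounds per broad type, used to build toy profiles.
TYPE_REPRESENTATIVE = {
    "C27_alcohol": "5b-cholestane-3a,7a,12a,26-tetrol",
    "C27_acid": "3a,7a,12a-trihydroxy-5b-cholestan-27-oic acid",
    "C24_acid": "cholic acid",
}


def make_profile(percents_by_type, species="sp", diet=None, family="famX"):
    """Profile with one representative compound per broad type."""
    components = tuple(
        ProfileComponent(descriptor=parse_name(TYPE_REPRESENTATIVE[t]),
                         percent=pct, name=TYPE_REPRESENTATIVE[t])
        for t, pct in percents_by_type.items() if pct > 0
    )
    return SpeciesProfile(species=species, family=family, diet=diet,
                          components=components)


def profile_from_names(named_percents, species="sp", diet=None, family="famX"):
    components = tuple(
        ProfileComponent(descriptor=parse_name(name), percent=pct, name=name)
        for name, pct in named_percents
    )
    return SpeciesProfile(species=species, family=family, diet=diet,
                          components=components)


def random_polytomous_tree(rng, labels):
    """Rooted tree over ``labels`` with random multifurcations (2-4 children)."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def grow(node, members):
        if len(members) == 1:
            node.taxon = taxa.new_taxon(label=members[0])
            return
        k = int(rng.integers(2, min(4, len(members)) + 1))
        cuts = sorted(rng.choice(np.arange(1, len(members)), size=k - 1,
                                 replace=False)) if k > 1 else []
        parts, prev = [], 0
        for c in list(cuts) + [len(members)]:
            parts.append(members[prev:c])
            prev = c
        for part in parts:
            grow(node.new_child(), part)

    shuffled = list(labels)
    rng.shuffle(shuffled)
    grow(tree.seed_node, shuffled)
    return tree


def exhaustive_min_changes(tree, states, alphabet=None):
    """Brute-force parsimony minimum over all internal labelings."""
    if alphabet is None:
        alphabet = sorted(set(states.values()))
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((node.parent_node, node))
    best = None
    best_root_states = set()
    root = tree.seed_node
    for assignment in itertools.product(alphabet, repeat=len(internals)):
        labeling = dict(zip(internals, assignment))
        for leaf in tree.leaf_node_iter():
            labeling[leaf] = states[leaf.taxon.label]
        changes = sum(1 for p, c in edges if labeling[p] != labeling[c])
        if best is None or changes < best:
            best = changes
            best_root_states = {labeling[root]}
        elif changes == best:
            best_root_states.add(labeling[root])
    if not internals:  # single-tip tree
        leaf = next(tree.leaf_node_iter())
        best, best_root_states = 0, {states[leaf.taxon.label]}
    return best, frozenset(best_root_states)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
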