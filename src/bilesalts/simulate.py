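"""Synthetic survey data with the statistical structure the analysis assumes.

Real comparative bile-salt data are species-by-compound percentage tables
with strong family-level conservation: profile classes change slowly across
the family backbone and species within a family nearly always share their
family's class.  The generator reproduces exactly that structure so that
every pipeline stage — table reading, classification, diet cross-tabs,
conservation screening, ancestral reconstruction — can be exercised and
calibrated without any external data:

1. a Yule (pure-birth) backbone tree over families, rescaled to unit height;
2. a discrete profile-class character evolved along the backbone by a
   continuous-time Mk process (all transitions equally likely, total leaving
   rate = expected changes per unit branch length);
3. species grafted under each family tip, copying the family state with a
   small flip probability;
4. per-species compositions drawn from a Dirichlet whose support matches the
   assigned class (a class VI species gets only C24-acid components, etc.),
   with a per-diet-group "complexity" coin that decides whether the species
   receives three components at the 10% threshold or one dominant compound;
5. diets drawn per family from fixed category probabilities.

Everything flows from one seeded :class:`numpy.random.Generator`; identical
seed + config gives byte-identical output tables.

What this generator does *not* emulate: measurement noise in the reported
percentages, unidentified material, secondary (microbial) bile-salt
modification, or correlation between diet and class — diet is independent of
the class character by construction, matching the survey's negative finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .compounds import BileSaltDescriptor, parse_name
from .diet import DietCategory
from .errors import ConfigurationError
from .phylo import CharacterMatrix
from .profiles import ProfileComponent, SpeciesProfile

__all__ = [
    "SimulationConfig",
    "yule_tree",
    "evolve_mk",
    "simulate_tree_and_characters",
    "TreeCharacters",
    "generate_profile_table",
    "simulate_peak_list",
    "CLASS_MENUS",
]


# Compound menus per broad type; drawn without replacement per profile.
_C24_MENU = ("cholic acid", "chenodeoxycholic acid", "deoxycholic acid",
             "ursodeoxycholic acid", "lithocholic acid")
_C27_ACID_MENU = ("3a,7a,12a-trihydroxy-5b-cholestan-27-oic acid",
                  "varanic acid",
                  "3a,7a,24R-trihydroxy-5b-cholestan-27-oic acid")
_C27_ALCOHOL_MENU = ("5b-cholestane-3a,7a,12a,26-tetrol",
                     "5b-cholestane-3a,7a,12a,25,26-pentol",
                     "5b-cholestane-3a,7a,12a,24,26-pentol")

#: Profile class -> tuple of compound menus (one menu per required type).
CLASS_MENUS: dict[str, tuple] = {
    "I": (_C27_ALCOHOL_MENU,),
    "II": (_C27_ALCOHOL_MENU, _C27_ACID_MENU),
    "III": (_C27_ALCOHOL_MENU, _C24_MENU),
    "IV": (_C27_ACID_MENU,),
    "V": (_C27_ACID_MENU, _C24_MENU),
    "VI": (_C24_MENU,),
}

_SIMPLE_WEIGHTS = (0.97, 0.03)
_COMPLEX_WEIGHTS = (0.45, 0.33, 0.22)
_TWO_TYPE_WEIGHTS = (0.62, 0.38)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror a mammal-survey-sized cohort: ~320 species in 40
    families, diet-category frequencies of roughly 32/46/22% (carnivore/
    herbivore/omnivore) and per-diet complex-profile probabilities of
    0.398/0.705/0.500.  The class character evolves at 0.05 expected changes
    per unit backbone height, with a 0.5% within-family flip probability —
    low enough that heterogeneous families are rare (a few percent of
    families), mirroring real surveys where only a handful of families mix
    classes.
    """

    n_families: int = 40
    species_per_family: int = 8
    yule_birth_rate: float = 1.0
    character_rate: float = 0.05
    within_family_flip_prob: float = 0.005
    class_alphabet: tuple = ("I", "IV", "VI")
    concentration: float = 50.0
    diet_probs: tuple = (("carnivore", 0.32), ("herbivore", 0.46), ("omnivore", 0.22))
    complexity_q: tuple = (("carnivore", 0.398), ("herbivore", 0.705), ("omnivore", 0.500))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.species_per_family < 1:
            raise ConfigurationError("need at least one family and one species")
        for name in ("yule_birth_rate", "character_rate", "concentration"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.yule_birth_rate == 0 or self.concentration == 0:
            raise ConfigurationError("yule_birth_rate and concentration must be > 0")
        if not 0.0 <= self.within_family_flip_prob <= 1.0:
            raise ConfigurationError("within_family_flip_prob outside [0, 1]")
        for label, p in tuple(self.diet_probs) + tuple(self.complexity_q):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability for {label} outside [0, 1]")
        for cls in self.class_alphabet:
            if cls not in CLASS_MENUS:
                raise ConfigurationError(f"class {cls!r} has no component menu")
        total = sum(p for _, p in self.diet_probs)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"diet probabilities sum to {total}, not 1")

    # -- flat key=value serialization ----------------------------------------

    def to_flat(self) -> str:
        lines = []
        for key in ("n_families", "species_per_family", "yule_birth_rate",
                    "character_rate", "within_family_flip_prob",
                    "concentration", "seed"):
            lines.append(f"{key}={getattr(self, key)}")
        lines.append("class_alphabet=" + ",".join(self.class_alphabet))
        for label, p in self.diet_probs:
            lines.append(f"diet_probs.{label}={p}")
        for label, q in self.complexity_q:
            lines.append(f"complexity_q.{label}={q}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "SimulationConfig":
        kwargs: dict = {}
        diet, q = {}, {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"bad config line {line!r}")
            key, value = (t.strip() for t in line.split("=", 1))
            if key.startswith("diet_probs."):
                diet[key.split(".", 1)[1]] = float(value)
            elif key.startswith("complexity_q."):
                q[key.split(".", 1)[1]] = float(value)
            elif key == "class_alphabet":
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif key in ("n_families", "species_per_family", "seed"):
                kwargs[key] = int(value)
            elif key in ("yule_birth_rate", "character_rate",
                         "within_family_flip_prob", "concentration"):
                kwargs[key] = float(value)
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        if diet:
            kwargs["diet_probs"] = tuple(sorted(diet.items()))
        if q:
            kwargs["complexity_q"] = tuple(sorted(q.items()))
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Tree simulation and character evolution
# ---------------------------------------------------------------------------

def yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    rng: np.random.Generator | None = None,
    labels: Sequence[str] | None = None,
    height: float | None = 1.0,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree, optionally rescaled to a height.

    Lineages split at rate ``birth_rate`` each; after the last split the tree
    grows for one more exponential waiting time so tips have pendant edges.
    """
    if n_tips < 1:
        raise ConfigurationError("a tree needs at least one tip")
    if birth_rate <= 0:
        raise ConfigurationError("birth_rate must be positive")
    rng = np.random.default_rng() if rng is None else rng
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ConfigurationError("label count does not match tip count")

    taxa = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    lineages = [tree.seed_node]
    now = 0.0
    while len(lineages) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(lineages)))
        parent = lineages.pop(int(rng.integers(len(lineages))))
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = now
            lineages.append(child)
    now += rng.exponential(1.0 / (birth_rate * len(lineages)))

    order = rng.permutation(n_tips)
    for i, leaf in enumerate(lineages):
        leaf.taxon = taxa.new_taxon(label=labels[order[i]])
    for node in tree.preorder_node_iter():
        start = node.parent_node.birth_time if node.parent_node else 0.0
        end = node.birth_time if node.child_nodes() else now
        node.edge.length = end - start
        node.depth = end

    if height is not None and now > 0:
        factor = height / now
        for node in tree.preorder_node_iter():
            node.edge.length *= factor
            node.depth *= factor
    return tree


def evolve_mk(
    tree: dendropy.Tree,
    alphabet: Sequence[str],
    rate: float,
    rng: np.random.Generator,
    root_state: str | None = None,
) -> tuple[dict, dict]:
    """Evolve one discrete character by a continuous-time Mk process.

    ``rate`` is the total leaving rate, i.e. the expected number of state
    changes per unit branch length; at an event the chain jumps to a
    uniformly chosen *different* state.  Returns (tip states by label, states
    for every node keyed by node object).
    """
    if rate < 0:
        raise ConfigurationError("rate must be >= 0")
    alphabet = list(alphabet)
    if len(alphabet) < 1:
        raise ConfigurationError("alphabet must be non-empty")
    node_states: dict = {}
    tip_states: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = root_state if root_state is not None \
                else alphabet[int(rng.integers(len(alphabet)))]
        else:
            state = node_states[node.parent_node]
            length = node.edge.length or 0.0
            if len(alphabet) > 1:
                for _ in range(rng.poisson(rate * length)):
                    others = [s for s in alphabet if s != state]
                    state = others[int(rng.integers(len(others)))]
        node_states[node] = state
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            tip_states[label] = state
    return tip_states, node_states


@dataclass
class TreeCharacters:
    """Output of :func:`simulate_tree_and_characters`."""

    tree: dendropy.Tree          # species-level tree (families as clades)
    matrix: CharacterMatrix      # "profile_class" character per species
    true_states: dict            # node object -> generating state (all nodes)
    family_of: dict              # species -> family name
    root_state: str


def simulate_tree_and_characters(cfg: SimulationConfig,
                                 rng: np.random.Generator | None = None) -> TreeCharacters:
    """Backbone-plus-families tree with a conserved profile-class character."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    families = [f"fam{i + 1:02d}" for i in range(cfg.n_families)]
    if cfg.n_families == 1:
        backbone = yule_tree(1, cfg.yule_birth_rate, rng, labels=families)
    else:
        backbone = yule_tree(cfg.n_families, cfg.yule_birth_rate, rng, labels=families)
    family_tip_states, backbone_states = evolve_mk(
        backbone, cfg.class_alphabet, cfg.character_rate, rng
    )

    species_states: dict[str, str] = {}
    family_of: dict[str, str] = {}
    true_states: dict = dict(backbone_states)
    k = len(cfg.class_alphabet)
    for leaf in list(backbone.leaf_node_iter()):
        family = leaf.taxon.label
        family_state = family_tip_states[family]
        leaf.label = family
        leaf.taxon = None  # becomes the family crown node
        species = [f"{family}_sp{j + 1:02d}" for j in range(cfg.species_per_family)]
        if cfg.species_per_family == 1:
            child = leaf.new_child(edge_length=0.1)
            child.taxon = backbone.taxon_namespace.new_taxon(label=species[0])
            tips = [child]
        else:
            sub = yule_tree(cfg.species_per_family, cfg.yule_birth_rate, rng,
                            labels=species, height=0.1,
                            taxon_namespace=backbone.taxon_namespace)
            for child in sub.seed_node.child_nodes():
                leaf.add_child(child)
            tips = [n for n in leaf.leaf_iter()]
        for tip in tips:
            sp = tip.taxon.label
            state = family_state
            if k > 1 and rng.random() < cfg.within_family_flip_prob:
                others = [s for s in cfg.class_alphabet if s != state]
                state = others[int(rng.integers(len(others)))]
            species_states[sp] = state
            family_of[sp] = family
            true_states[tip] = state

    matrix = CharacterMatrix(
        species=sorted(species_states),
        characters={"profile_class": dict(sorted(species_states.items()))},
    )
    root_state = backbone_states[backbone.seed_node]
    return TreeCharacters(
        tree=backbone, matrix=matrix, true_states=true_states,
        family_of=family_of, root_state=root_state,
    )


# ---------------------------------------------------------------------------
# Profile tables and peak lists
# ---------------------------------------------------------------------------

def _draw_composition(cls: str, complex_profile: bool, concentration: float,
                      rng: np.random.Generator) -> list[tuple[str, float]]:
    menus = CLASS_MENUS[cls]
    if len(menus) == 1:
        menu = menus[0]
        if complex_profile:
            names = list(rng.choice(menu, size=3, replace=False))
            weights = _COMPLEX_WEIGHTS
        else:
            names = list(rng.choice(menu, size=2, replace=False))
            weights = _SIMPLE_WEIGHTS
    else:
        first = str(rng.choice(menus[0]))
        second = str(rng.choice(menus[1]))
        if complex_profile:
            extra = str(rng.choice([m for m in menus[0] if m != first]))
            names = [first, second, extra]
            weights = _COMPLEX_WEIGHTS
        else:
            names = [first, second]
            weights = _TWO_TYPE_WEIGHTS
    alpha = np.asarray(weights, dtype=float) * concentration
    fractions = rng.dirichlet(alpha)
    return [(str(n), float(100.0 * f)) for n, f in zip(names, fractions)]


def generate_profile_table(
    cfg: SimulationConfig,
    characters: CharacterMatrix,
    family_of: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> list[SpeciesProfile]:
    """Draw per-species compositions and diets consistent with the class
    character.

    Components come from the class's compound menus via a Dirichlet with
    total concentration ``cfg.concentration``; the per-diet complexity coin
    decides between a dominant-compound draw and a three-component draw.
    Diets are drawn once per family.  For single-type classes the complexity
    coin is the only source of complex profiles, so the observed complex
    fraction per diet group estimates the configured q directly; two-type
    classes (II/III/V) are complex by construction.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    class_of = characters.column("profile_class")
    diet_labels = [d for d, _ in cfg.diet_probs]
    diet_p = np.asarray([p for _, p in cfg.diet_probs])
    q_of = dict(cfg.complexity_q)

    family_diet: dict[str, str] = {}
    for family in sorted(set(family_of.values())):
        family_diet[family] = str(diet_labels[int(rng.choice(len(diet_labels), p=diet_p))])

    profiles = []
    for species in characters.species:
        cls = class_of[species]
        family = family_of[species]
        diet = family_diet[family]
        complex_profile = bool(rng.random() < q_of.get(diet, 0.0))
        parts = _draw_composition(cls, complex_profile, cfg.concentration, rng)
        components = tuple(
            ProfileComponent(descriptor=parse_name(name), percent=pct, name=name)
            for name, pct in parts
        )
        profiles.append(
            SpeciesProfile(
                species=species,
                family=family,
                order_or_group="synthetic",
                diet=diet,
                components=components,
            )
        )
    return profiles


def simulate_peak_list(
    profile: SpeciesProfile,
    rng: np.random.Generator,
    mz_sd: float = 0.01,
    n_noise_peaks: int = 0,
    mz_range: tuple = (350.0, 600.0),
) -> list[tuple[float, float]]:
    """Negative-mode peak list for one species: one [M-H]- peak per component.

    Intensities are proportional to pool percentages; m/z values get small
    Gaussian jitter.  Optional uniform noise peaks emulate non-bile-salt
    background.  The result is sorted by m/z.
    """
    from .compounds import mz_mh_minus

    peaks = []
    for c in profile.components:
        mz = mz_mh_minus(c.descriptor) + rng.normal(0.0, mz_sd)
        peaks.append((float(mz), float(max(c.percent, 0.1))))
    for _ in range(n_noise_peaks):
        peaks.append(
            (float(rng.uniform(*mz_range)), float(rng.uniform(0.05, 1.0)))
        )
    return sorted(peaks)
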