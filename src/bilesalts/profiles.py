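"""Species bile-salt profiles: the class I-VI scheme, complexity, major/minor.

A species' biliary bile-salt pool is a composition: each identified compound
contributes some percentage of the total.  Comparative work collapses this
composition in three ways:

* **Profile class** (I-VI): which of the three broad compound types (C27
  bile alcohols, C27 bile acids, C24 bile acids) reach 10% or more of the
  pool.  One type at threshold gives classes I/IV/VI; the three pairwise
  combinations give II/III/V; all three at threshold is reported distinctly
  as "mixed" rather than silently coerced.
* **Complexity**: a profile is complex when two compound types each reach
  10%, and/or when three or more individual bile salts each reach 10%.
* **Major/minor/trace**: a single compound above 50% of the pool is the
  major bile salt; compounds above 10% (but at most 50%) are minor; the
  rest are trace.  These are the conventions used when overlaying profiles
  on phylogenies.

Thresholds follow the sources exactly: "10% or greater" is inclusive for
classification and complexity; "more than 50%" is strict for major; minor is
the interval (10, 50].  Percentages are used as reported, without
renormalizing away unidentified material, and conjugation state is ignored
when aggregating by type (a glycine- and a taurine-conjugate of the same
aglycone are pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .compounds import BileSaltDescriptor, CompoundType, classify_type
from .errors import ClassificationError, ValidationError

__all__ = [
    "ProfileComponent",
    "SpeciesProfile",
    "ProfileClass",
    "type_aggregates",
    "assign_class",
    "is_complex",
    "major_minor",
    "MajorMinorPartition",
]

#: Allowed excess of summed percentages over 100 (approximate "~100" entries
#: plus independently rounded minor components can overshoot slightly).
PERCENT_SUM_SLACK = 5.0

#: Pool-fraction threshold (percent) for a compound type to "count".
TYPE_THRESHOLD = 10.0

#: Threshold (percent) above which a single compound is the major bile salt.
MAJOR_THRESHOLD = 50.0


class ProfileClass(str, Enum):
    I = "I"        # C27 bile alcohols only
    II = "II"      # C27 bile alcohols + C27 bile acids
    III = "III"    # C27 bile alcohols + C24 bile acids
    IV = "IV"      # C27 bile acids only
    V = "V"        # C27 bile acids + C24 bile acids
    VI = "VI"      # C24 bile acids only
    MIXED = "mixed"  # all three types at threshold


_CLASS_BY_TYPESET = {
    frozenset({CompoundType.C27_ALCOHOL}): ProfileClass.I,
    frozenset({CompoundType.C27_ALCOHOL, CompoundType.C27_ACID}): ProfileClass.II,
    frozenset({CompoundType.C27_ALCOHOL, CompoundType.C24_ACID}): ProfileClass.III,
    frozenset({CompoundType.C27_ACID}): ProfileClass.IV,
    frozenset({CompoundType.C27_ACID, CompoundType.C24_ACID}): ProfileClass.V,
    frozenset({CompoundType.C24_ACID}): ProfileClass.VI,
    frozenset({CompoundType.C27_ALCOHOL, CompoundType.C27_ACID,
               CompoundType.C24_ACID}): ProfileClass.MIXED,
}


@dataclass(frozen=True)
class ProfileComponent:
    """One compound in a species' biliary pool."""

    descriptor: BileSaltDescriptor
    percent: float
    approximate: bool = False  # source wrote "~" before the number
    name: str | None = None    # compound name as given in the source table

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValidationError(
                f"component percent {self.percent} outside [0, 100]"
            )


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    family: str = ""
    order_or_group: str = ""
    diet: str | None = None  # "carnivore" / "herbivore" / "omnivore" / None
    components: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        total = sum(c.percent for c in self.components)
        if total > 100.0 + PERCENT_SUM_SLACK:
            raise ValidationError(
                f"{self.species}: component percents sum to {total:.1f} > 100"
            )
        seen = set()
        for c in self.components:
            if c.descriptor in seen:
                raise ValidationError(
                    f"{self.species}: duplicate compound {c.descriptor}"
                )
            seen.add(c.descriptor)


@dataclass(frozen=True)
class MajorMinorPartition:
    major: tuple
    minor: tuple
    trace: tuple


def type_aggregates(profile: SpeciesProfile) -> dict[CompoundType, float]:
    """Aggregate percent per compound type, on the aglycone."""
    agg: dict[CompoundType, float] = {}
    for c in profile.components:
        t = classify_type(c.descriptor.deconjugated())
        agg[t] = agg.get(t, 0.0) + c.percent
    return agg


def assign_class(profile: SpeciesProfile) -> ProfileClass:
    """Assign the profile class from the types reaching the 10% threshold.

    The OTHER bucket (C23 acids and such) never defines a class.  A profile
    in which no type reaches 10% cannot be classified and raises
    :class:`ClassificationError` naming the species.
    """
    if not any(c.percent > 0 for c in profile.components):
        raise ClassificationError(f"{profile.species}: empty or all-zero profile")
    agg = type_aggregates(profile)
    at_threshold = frozenset(
        t for t, pct in agg.items()
        if t is not CompoundType.OTHER and pct >= TYPE_THRESHOLD
    )
    cls = _CLASS_BY_TYPESET.get(at_threshold)
    if cls is None:
        raise ClassificationError(
            f"{profile.species}: no compound type reaches "
            f"{TYPE_THRESHOLD:.0f}% of the pool"
        )
    return cls


def is_complex(profile: SpeciesProfile) -> bool:
    """Complex = two types each at >=10%, and/or >=3 compounds each at >=10%."""
    agg = type_aggregates(profile)
    types_at_threshold = sum(
        1 for t, pct in agg.items()
        if t is not CompoundType.OTHER and pct >= TYPE_THRESHOLD
    )
    components_at_threshold = sum(
        1 for c in profile.components if c.percent >= TYPE_THRESHOLD
    )
    return types_at_threshold >= 2 or components_at_threshold >= 3


def major_minor(profile: SpeciesProfile) -> MajorMinorPartition:
    """Partition components into major (>50%), minor ((10, 50]), trace (<=10%)."""
    major, minor, trace = [], [], []
    for c in profile.components:
        if c.percent > MAJOR_THRESHOLD:
            major.append(c)
        elif c.percent > TYPE_THRESHOLD:
            minor.append(c)
        else:
            trace.append(c)
    key = lambda c: -c.percent
    return MajorMinorPartition(
        tuple(sorted(major, key=key)),
        tuple(sorted(minor, key=key)),
        tuple(sorted(trace, key=key)),
    )
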