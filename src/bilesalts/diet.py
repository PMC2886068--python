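"""Diet categories and diet x bile-salt-profile cross-tabulations.

Species are binned into three diet categories — carnivore (> 90% meat),
herbivore (> 90% plant matter), omnivore (everything else) — either from raw
diet fractions or from labels carried in the input table.  The cross-tab
reports, per diet group: sample size, the fraction of species with complex
bile-salt profiles, the fractions whose major bile salt is cholic acid (CA),
chenodeoxycholic acid (CDCA), or another C24 acid, and the fraction whose
pool is primarily (aggregate > 50%) C27 bile acids.

"Primarily C27 bile acids" has no formal definition in the comparative
literature; here it means the C27-acid aggregate exceeds 50% of the pool, and
the output carries that definition in its metadata.  Percentages are rounded
half-up to one decimal.  No hypothesis testing is attempted: the report is a
descriptive cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .compounds import CompoundType, parse_name
from .errors import ClassificationError, ValidationError
from .profiles import (
    MAJOR_THRESHOLD,
    SpeciesProfile,
    is_complex,
    major_minor,
    type_aggregates,
)

__all__ = ["DietCategory", "assign_diet", "GroupStats", "CrosstabReport",
           "diet_crosstab", "round_half_up"]

PRIMARILY_DEFINITION = "aggregate C27 bile-acid percent > 50 of total pool"

_CA = parse_name("cholic acid")
_CDCA = parse_name("chenodeoxycholic acid")


class DietCategory(str, Enum):
    CARNIVORE = "carnivore"
    HERBIVORE = "herbivore"
    OMNIVORE = "omnivore"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def assign_diet(percent_meat: float, percent_plant: float) -> DietCategory:
    """Carnivore iff meat > 90%; herbivore iff plant > 90%; else omnivore."""
    for label, v in (("meat", percent_meat), ("plant", percent_plant)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"percent_{label} {v} outside [0, 100]")
    if percent_meat + percent_plant > 100.0 + 1e-9:
        raise ValidationError(
            f"diet fractions sum to {percent_meat + percent_plant} > 100"
        )
    if percent_meat > 90.0:
        return DietCategory.CARNIVORE
    if percent_plant > 90.0:
        return DietCategory.HERBIVORE
    return DietCategory.OMNIVORE


@dataclass(frozen=True)
class GroupStats:
    """Counts and percentages for one diet group.

    Every percentage keeps its numerator so nothing has to be reverse
    engineered from rounded values.
    """

    diet: DietCategory
    n: int
    n_complex: int
    n_major_ca: int
    n_major_cdca: int
    n_major_other_c24: int
    n_primarily_c27_acids: int

    def _pct(self, num: int) -> float:
        return round_half_up(100.0 * num / self.n) if self.n else 0.0

    @property
    def pct_complex(self) -> float:
        return self._pct(self.n_complex)

    @property
    def pct_major_ca(self) -> float:
        return self._pct(self.n_major_ca)

    @property
    def pct_major_cdca(self) -> float:
        return self._pct(self.n_major_cdca)

    @property
    def pct_major_other_c24(self) -> float:
        return self._pct(self.n_major_other_c24)

    @property
    def pct_primarily_c27_acids(self) -> float:
        return self._pct(self.n_primarily_c27_acids)


@dataclass(frozen=True)
class CrosstabReport:
    groups: tuple  # GroupStats per diet category present
    n_total: int
    n_unlabeled: int  # species excluded for missing diet labels
    primarily_definition: str = PRIMARILY_DEFINITION

    def group(self, diet: DietCategory | str) -> GroupStats:
        diet = DietCategory(diet)
        for g in self.groups:
            if g.diet is diet:
                return g
        raise KeyError(diet)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "diet": g.diet.value,
                "n": g.n,
                "pct_complex": g.pct_complex,
                "pct_major_CA": g.pct_major_ca,
                "pct_major_CDCA": g.pct_major_cdca,
                "pct_major_other_C24": g.pct_major_other_c24,
                "pct_primarily_C27_acids": g.pct_primarily_c27_acids,
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)


def _major_descriptor(profile: SpeciesProfile):
    majors = major_minor(profile).major
    return majors[0].descriptor.deconjugated() if majors else None


def diet_crosstab(profiles: Sequence[SpeciesProfile]) -> CrosstabReport:
    """Cross-tabulate bile-salt profile features against diet groups.

    Species without a diet label are excluded and counted in
    ``n_unlabeled``; an entirely empty cohort raises
    :class:`ClassificationError`.  Results are invariant to the order of the
    input profiles.
    """
    if not profiles:
        raise ClassificationError("empty cohort: nothing to cross-tabulate")
    buckets: dict[DietCategory, list[SpeciesProfile]] = {d: [] for d in DietCategory}
    n_unlabeled = 0
    for p in profiles:
        if p.diet is None or str(p.diet).strip() == "":
            n_unlabeled += 1
            continue
        buckets[DietCategory(str(p.diet).lower())].append(p)

    groups = []
    for diet in DietCategory:
        members = buckets[diet]
        if not members:
            continue
        n_complex = sum(1 for p in members if is_complex(p))
        n_ca = n_cdca = n_other_c24 = n_c27 = 0
        for p in members:
            major = _major_descriptor(p)
            if major is not None:
                if major == _CA:
                    n_ca += 1
                elif major == _CDCA:
                    n_cdca += 1
                elif major.carbon_count == 24 and major.terminal_group.value == "carboxylic_acid":
                    n_other_c24 += 1
            agg = type_aggregates(p)
            if agg.get(CompoundType.C27_ACID, 0.0) > MAJOR_THRESHOLD:
                n_c27 += 1
        groups.append(
            GroupStats(diet, len(members), n_complex, n_ca, n_cdca,
                       n_other_c24, n_c27)
        )
    return CrosstabReport(
        groups=tuple(groups),
        n_total=sum(g.n for g in groups),
        n_unlabeled=n_unlabeled,
    )
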