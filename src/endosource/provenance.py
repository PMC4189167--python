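"""Peak provenance: seed inheritance versus soil uptake by co-occurrence.

Each TRFLP category present in a soil-grown plant is assigned to exactly
one of five categories by strict rule precedence:

1. ``SEED`` — shared with the parental seed profile;
2. ``PLANT_ON_SAND`` — shared with the same genotype grown on sterile
   sand (but not with seed);
3. ``SOIL_OR_PLANT_ON_SOIL`` — shared with the plant grown on the
   opposite soil or with the opposite soil itself (promiscuous soil
   uptake);
4. ``SAME_SOIL_ONLY`` — shared only with the soil the plant grew on
   (soil-specific uptake);
5. ``NO_MATCH`` — found in none of the reference profiles.

Categories 1+2 constitute evidence of vertical transmission; 3 and 4
are soil-derived; 5 is ambiguous.  Classification operates by default
on whole-plant unions of present categories over tissues and both dye
channels.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from ._util import round_half_up


class ProvenanceCategory(enum.Enum):
    SEED = "Seed"
    PLANT_ON_SAND = "Plant on Sand"
    SOIL_OR_PLANT_ON_SOIL = "Soil or Plant on Soil"
    SAME_SOIL_ONLY = "Same Soil Match Only"
    NO_MATCH = "No Match"


CATEGORIES = tuple(ProvenanceCategory)


@dataclass(frozen=True)
class ReferenceSets:
    """Reference presence sets used to classify one plant group's peaks."""

    seed: frozenset
    sand_plant: frozenset
    opposite_soil_plant: frozenset
    same_soil: frozenset
    opposite_soil: frozenset

    @classmethod
    def make(cls, seed=(), sand_plant=(), opposite_soil_plant=(),
             same_soil=(), opposite_soil=()) -> "ReferenceSets":
        return cls(
            seed=frozenset(seed),
            sand_plant=frozenset(sand_plant),
            opposite_soil_plant=frozenset(opposite_soil_plant),
            same_soil=frozenset(same_soil),
            opposite_soil=frozenset(opposite_soil),
        )


def classify_peak(
    category, refs: ReferenceSets, rule3: str = "or"
) -> ProvenanceCategory:
    """Classify one peak category by strict precedence.

    ``rule3`` selects whether promiscuous soil uptake requires
    co-occurrence in the opposite-soil plant OR the opposite soil
    (default) or in both (``"and"``).
    """
    if rule3 not in ("or", "and"):
        raise ValueError("rule3 must be 'or' or 'and'")
    if category in refs.seed:
        return ProvenanceCategory.SEED
    if category in refs.sand_plant:
        return ProvenanceCategory.PLANT_ON_SAND
    in_opp_plant = category in refs.opposite_soil_plant
    in_opp_soil = category in refs.opposite_soil
    hit = (in_opp_plant or in_opp_soil) if rule3 == "or" else (in_opp_plant and in_opp_soil)
    if hit:
        return ProvenanceCategory.SOIL_OR_PLANT_ON_SOIL
    if category in refs.same_soil:
        return ProvenanceCategory.SAME_SOIL_ONLY
    return ProvenanceCategory.NO_MATCH


@dataclass
class ProvenanceBreakdown:
    """Counts and fractions of a plant profile over the five categories."""

    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, cat: ProvenanceCategory) -> float:
        return self.counts.get(cat, 0) / self.total

    @property
    def fractions(self) -> dict:
        return {cat: self.fraction(cat) for cat in CATEGORIES}

    # derived summaries
    @property
    def vertical_transmission(self) -> float:
        """Fraction explained by inheritance (seed + sand-plant sharing)."""
        return (self.fraction(ProvenanceCategory.SEED)
                + self.fraction(ProvenanceCategory.PLANT_ON_SAND))

    @property
    def soil_shared(self) -> float:
        return self.fraction(ProvenanceCategory.SOIL_OR_PLANT_ON_SOIL)

    @property
    def soil_unique(self) -> float:
        return self.fraction(ProvenanceCategory.SAME_SOIL_ONLY)

    @property
    def ambiguous(self) -> float:
        return self.fraction(ProvenanceCategory.NO_MATCH)

    @property
    def soil_derived_total(self) -> float:
        return self.soil_shared + self.soil_unique

    def percent(self, cat: ProvenanceCategory) -> int:
        """Display rounding: integer percent, half up."""
        return round_half_up(100.0 * self.fraction(cat))

    def to_dict(self) -> dict:
        return {
            "counts": {cat.value: self.counts.get(cat, 0) for cat in CATEGORIES},
            "fractions": {cat.value: self.fraction(cat) for cat in CATEGORIES},
            "percent": {cat.value: self.percent(cat) for cat in CATEGORIES},
            "total_peaks": self.total,
            "vertical_transmission": self.vertical_transmission,
            "soil_shared": self.soil_shared,
            "soil_unique": self.soil_unique,
            "ambiguous": self.ambiguous,
            "soil_derived_total": self.soil_derived_total,
        }


def breakdown(
    plant_profile: Iterable, refs: ReferenceSets, rule3: str = "or"
) -> ProvenanceBreakdown:
    """Classify every present peak of a plant profile.

    Raises on an empty profile (fractions would be undefined).
    """
    cats = frozenset(plant_profile)
    if not cats:
        raise ValueError("plant profile is empty; provenance fractions undefined")
    counts = {cat: 0 for cat in CATEGORIES}
    for c in sorted(cats):
        counts[classify_peak(c, refs, rule3=rule3)] += 1
    return ProvenanceBreakdown(counts={k: v for k, v in counts.items()})


def whole_plant_union(*tissue_profiles: Iterable) -> frozenset:
    """Union of present categories across tissues (and both dyes)."""
    out: frozenset = frozenset()
    for prof in tissue_profiles:
        out |= frozenset(prof)
    return out


def plot_breakdown_pie(bd: ProvenanceBreakdown, ax=None, title: str | None = None):
    """Render a breakdown as a pie chart (matplotlib Axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {
        ProvenanceCategory.SEED: "#f3e24c",
        ProvenanceCategory.PLANT_ON_SAND: "#a7d46a",
        ProvenanceCategory.SOIL_OR_PLANT_ON_SOIL: "#a0522d",
        ProvenanceCategory.SAME_SOIL_ONLY: "#000000",
        ProvenanceCategory.NO_MATCH: "#9e9e9e",
    }
    cats = [c for c in CATEGORIES if bd.counts.get(c, 0) > 0]
    ax.pie(
        [bd.counts[c] for c in cats],
        labels=[f"{c.value} ({bd.percent(c)}%)" for c in cats],
        colors=[colors[c] for c in cats],
    )
    if title:
        ax.set_title(title)
    return ax
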