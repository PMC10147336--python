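"""Geography, island-emergence schedule, time strata and range state space.

The biogeographic scene for an island radiation: a fixed set of discrete
regions (islands or mainland areas), some of which only became available
after their geological emergence.  Region availability partitions
root-to-present time into *strata*; within a stratum the set of available
regions is constant, and moving toward the present regions only appear,
never disappear.

A lineage's geographic range is a subset of regions.  The model state
space enumerates every subset up to a maximum range size, plus the empty
(null) range used as an absorbing "globally extirpated" state in the
likelihood bookkeeping.  The null range is never a valid tip observation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Geography:
    """An ordered set of region codes with optional emergence ages.

    Parameters
    ----------
    regions
        Ordered region codes (short strings, unique).
    emergence_age
        Map region code -> age of emergence in myr before present.
        Regions absent from the map are available throughout.
    names
        Optional map region code -> long name (informational only).
    """

    regions: tuple[str, ...]
    emergence_age: dict[str, float] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region code")
        for code, age in self.emergence_age.items():
            if code not in self.regions:
                raise ValueError(f"emergence age for unknown region {code!r}")
            if age < 0:
                raise ValueError(f"negative emergence age for region {code!r}")
        if len(self.emergence_age) == len(self.regions):
            raise ValueError("at least one region must be available throughout")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index(self, code: str) -> int:
        return self.regions.index(code)

    def available_at(self, age: float) -> frozenset[int]:
        """Region indices available at ``age`` myr before present."""
        return frozenset(
            i
            for i, code in enumerate(self.regions)
            if self.emergence_age.get(code, float("inf")) >= age
            or code not in self.emergence_age
        )


@dataclass(frozen=True)
class TimeStrata:
    """Root-to-present time partition with per-stratum availability masks.

    ``boundaries`` are the strictly descending internal stratum limits in
    myr (the present, age 0, is always an implicit lower limit).  Stratum
    ``k`` covers ages in ``(boundaries[k], boundaries[k-1]]`` with stratum 0
    open-ended toward the root.  ``masks[k]`` is the frozenset of available
    region indices in stratum ``k``; masks grow toward the present.
    """

    boundaries: tuple[float, ...]
    masks: tuple[frozenset[int], ...]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.boundaries, self.boundaries[1:])):
            pass  # descending check below
        if list(self.boundaries) != sorted(self.boundaries, reverse=True):
            raise ValueError("stratum boundaries must be strictly descending")
        if len(set(self.boundaries)) != len(self.boundaries):
            raise ValueError("stratum boundaries must be strictly descending")
        if len(self.masks) != len(self.boundaries) + 1:
            raise ValueError("need exactly one mask per stratum")
        for older, younger in zip(self.masks, self.masks[1:]):
            if not older <= younger:
                raise ValueError("availability masks must grow toward the present")

    @property
    def n_strata(self) -> int:
        return len(self.masks)

    def stratum_at(self, age: float) -> int:
        """Index of the stratum containing ``age`` (boundaries belong to the
        older stratum)."""
        for k, b in enumerate(self.boundaries):
            if age >= b:
                return k
        return len(self.boundaries)

    def mask_at(self, age: float) -> frozenset[int]:
        return self.masks[self.stratum_at(age)]

    def segment_branch(self, older_age: float, younger_age: float):
        """Split a branch interval at stratum boundaries.

        Returns a list of ``(stratum_index, dt)`` tuples ordered from the
        older end toward the younger end.
        """
        if younger_age > older_age:
            raise ValueError("branch must run from older to younger age")
        cuts = [older_age]
        for b in self.boundaries:
            if younger_age < b < older_age:
                cuts.append(b)
        cuts.append(younger_age)
        segments = []
        for hi, lo in zip(cuts, cuts[1:]):
            mid = 0.5 * (hi + lo)
            segments.append((self.stratum_at(mid), hi - lo))
        return segments


def build_geography(
    regions,
    emergence_age: dict[str, float] | None = None,
    *,
    root_age: float | None = None,
    names: dict[str, str] | None = None,
) -> tuple[Geography, TimeStrata]:
    """Build a :class:`Geography` and its :class:`TimeStrata`.

    Stratum boundaries are exactly the distinct emergence ages that fall
    within the tree's depth (``root_age``); with no emergence ages there is
    a single stratum in which every region is available.  An emergence age
    exceeding ``root_age`` triggers a warning (the region is then simply
    available throughout the observed history) rather than an error.
    """
    geo = Geography(
        regions=tuple(regions),
        emergence_age=dict(emergence_age or {}),
        names=dict(names or {}),
    )
    ages = sorted(set(geo.emergence_age.values()), reverse=True)
    if root_age is not None:
        kept = []
        for a in ages:
            if a >= root_age:
                warnings.warn(
                    f"emergence age {a} myr is at or beyond the root age "
                    f"{root_age} myr; no stratum boundary created for it",
                    stacklevel=2,
                )
            else:
                kept.append(a)
        ages = kept
    boundaries = tuple(ages)
    masks = []
    for k in range(len(boundaries) + 1):
        # representative age strictly inside stratum k
        if k == 0:
            rep = boundaries[0] + 1.0 if boundaries else 0.0
        else:
            rep = boundaries[k - 1]
        masks.append(geo.available_at(rep))
    return geo, TimeStrata(boundaries=boundaries, masks=tuple(masks))


def enumerate_ranges(
    n_regions: int, max_range_size: int, include_null: bool = True
) -> list[frozenset[int]]:
    """Enumerate the range state space in a deterministic order.

    States are ordered by range size, then lexicographically by region
    index; the null range (if included) comes first.  Every subset of size
    ``1..max_range_size`` appears exactly once.
    """
    if max_range_size < 1:
        raise ValueError("max_range_size must be >= 1")
    if max_range_size > n_regions:
        raise ValueError("max_range_size cannot exceed n_regions")
    states: list[frozenset[int]] = []
    if include_null:
        states.append(frozenset())
    for k in range(1, max_range_size + 1):
        for combo in itertools.combinations(range(n_regions), k):
            states.append(frozenset(combo))
    return states


@dataclass(frozen=True)
class StateSpace:
    """Indexed range state space bound to a geography.

    Wraps :func:`enumerate_ranges` with fast state<->index lookup and
    human-readable labels ("T+G" style).
    """

    geography: Geography
    max_range_size: int
    include_null: bool = True

    @property
    def states(self) -> list[frozenset[int]]:
        return self._states()

    def _states(self):
        if not hasattr(self, "_cache"):
            object.__setattr__(
                self,
                "_cache",
                enumerate_ranges(
                    self.geography.n_regions, self.max_range_size, self.include_null
                ),
            )
            object.__setattr__(
                self, "_index", {s: i for i, s in enumerate(self._cache)}
            )
        return self._cache

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, state: frozenset[int]) -> int:
        self._states()
        return self._index[state]

    def label(self, state: frozenset[int]) -> str:
        if not state:
            return "null"
        return "+".join(self.geography.regions[i] for i in sorted(state))

    def parse_label(self, label: str) -> frozenset[int]:
        if label == "null":
            return frozenset()
        return frozenset(self.geography.index(c) for c in label.split("+"))


# The study system: seven Canary Islands plus Madeira, Cape Verde, Morocco
# and East Africa, with Madeira, La Palma and El Hierro emerging at 5, 1.7
# and 1.1 myr before present.
STUDY_REGIONS = ("H", "P", "G", "T", "C", "F", "L", "Mc", "EA", "Md", "V")
STUDY_EMERGENCE = {"Md": 5.0, "P": 1.7, "H": 1.1}
STUDY_REGION_NAMES = {
    "H": "El Hierro",
    "P": "La Palma",
    "G": "La Gomera",
    "T": "Tenerife",
    "C": "Gran Canaria",
    "F": "Fuerteventura",
    "L": "Lanzarote",
    "Mc": "Morocco",
    "EA": "East Africa",
    "Md": "Madeira",
    "V": "Cape Verde",
}
STUDY_MAX_RANGE_SIZE = 5


def study_geography(root_age: float | None = None) -> tuple[Geography, TimeStrata]:
    """The 11-region, 4-stratum geography of the study system."""
    return build_geography(
        STUDY_REGIONS,
        STUDY_EMERGENCE,
        root_age=root_age,
        names=STUDY_REGION_NAMES,
    )
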