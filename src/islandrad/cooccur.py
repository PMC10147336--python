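"""Island-level co-occurrence and hybridization rate statistics.

Co-occurrence is binary per taxon pair per island (any overlap of
distribution areas counts); rates are reported relative to the number of
possible pairings.  For an island with ``n`` resident taxa the denominator
is ``C(n, 2)``; for a clade pair the denominator is ``C(n, 2)`` within a
clade and ``n1 * n2`` between two clades.  Hybridizing pairs are a subset
of co-occurring pairs, so hybridization rates never exceed co-occurrence
rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CooccurrenceData:
    """Taxon occupancy plus annotated co-occurring and hybridizing pairs.

    ``occupancy`` maps taxon -> set of island codes.  ``pairs`` maps an
    unordered taxon pair -> set of islands on which the two co-occur;
    ``hybrids`` likewise for published natural hybrids.  ``clades``
    optionally assigns each taxon to a clade for clade-pair rates.
    """

    occupancy: dict[str, set[str]]
    pairs: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    hybrids: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    clades: dict[str, str] = field(default_factory=dict)
    allow_hybrid_without_cooccurrence: bool = False

    def __post_init__(self):
        self.pairs = {_norm_pair(*k): set(v) for k, v in self.pairs.items()}
        self.hybrids = {_norm_pair(*k): set(v) for k, v in self.hybrids.items()}
        for pair, islands in list(self.pairs.items()) + list(self.hybrids.items()):
            for taxon in pair:
                if taxon not in self.occupancy:
                    raise ValueError(f"pair references unknown taxon {taxon!r}")
            for isl in islands:
                bad = [t for t in pair if isl not in self.occupancy[t]]
                if bad:
                    raise ValueError(
                        f"pair {pair} annotated on {isl!r} but {bad} do not "
                        "occur there"
                    )
        if not self.allow_hybrid_without_cooccurrence:
            for pair, islands in self.hybrids.items():
                if pair not in self.pairs or not islands <= self.pairs[pair]:
                    raise ValueError(
                        f"hybrid pair {pair} is not recorded as co-occurring "
                        "on the same island(s) (set "
                        "allow_hybrid_without_cooccurrence to override)"
                    )

    @property
    def islands(self) -> list[str]:
        return sorted(set().union(*self.occupancy.values()))

    def residents(self, island: str) -> list[str]:
        return sorted(t for t, occ in self.occupancy.items() if island in occ)


@dataclass(frozen=True)
class IslandRates:
    island: str
    n_taxa: int
    n_possible_pairs: int
    n_cooccurring: int
    n_hybridizing: int
    cooccurrence_rate: float | None   # None when fewer than 2 residents
    hybridization_rate: float | None


def island_rates(data: CooccurrenceData) -> dict[str, IslandRates]:
    """Per-island co-occurrence and hybridization rates.

    rate = (pairs co-occurring / hybridizing on the island) / C(n, 2);
    islands with fewer than two residents have undefined rates.
    """
    out = {}
    for island in data.islands:
        residents = data.residents(island)
        n = len(residents)
        possible = n * (n - 1) // 2
        co = sum(
            1 for pair, isl in data.pairs.items() if island in isl
        )
        hy = sum(
            1 for pair, isl in data.hybrids.items() if island in isl
        )
        out[island] = IslandRates(
            island=island,
            n_taxa=n,
            n_possible_pairs=possible,
            n_cooccurring=co,
            n_hybridizing=hy,
            cooccurrence_rate=co / possible if possible else None,
            hybridization_rate=hy / possible if possible else None,
        )
    return out


def clade_pair_rates(data: CooccurrenceData) -> pd.DataFrame:
    """Clade-by-clade co-occurrence and hybridization percentages.

    A pair is counted once if it co-occurs (or hybridizes) on any island.
    Within a clade the denominator is C(n, 2); between clades it is
    n1 * n2 (the number of possible pairings is 100 %).
    """
    if not data.clades:
        raise ValueError("no clade assignment present")
    missing = [t for t in data.occupancy if t not in data.clades]
    if missing:
        raise ValueError(f"taxa without clade assignment: {missing}")
    members: dict[str, list[str]] = {}
    for taxon, clade in data.clades.items():
        members.setdefault(clade, []).append(taxon)
    for clade, taxa in members.items():
        if not taxa:
            raise ValueError(f"empty clade {clade!r}")
    clades = sorted(members)
    rows = []
    for i, c1 in enumerate(clades):
        for c2 in clades[i:]:
            t1, t2 = members[c1], members[c2]
            if c1 == c2:
                denom = len(t1) * (len(t1) - 1) // 2
                pairs = {
                    _norm_pair(a, b)
                    for ai, a in enumerate(t1)
                    for b in t1[ai + 1:]
                }
            else:
                denom = len(t1) * len(t2)
                pairs = {_norm_pair(a, b) for a in t1 for b in t2}
            co = sum(1 for p in pairs if data.pairs.get(p))
            hy = sum(1 for p in pairs if data.hybrids.get(p))
            rows.append(
                {
                    "clade_1": c1,
                    "clade_2": c2,
                    "n_possible_pairs": denom,
                    "n_cooccurring": co,
                    "n_hybridizing": hy,
                    "cooccurrence_pct": 100.0 * co / denom if denom else np.nan,
                    "hybridization_pct": 100.0 * hy / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)


def rank_islands(
    rates: dict[str, float],
    habitation_ages: dict[str, float],
) -> pd.DataFrame:
    """Sort islands by rate, join first-colonization ages, and report a
    descriptive Spearman rank correlation between rate and age.

    ``rates`` maps island -> rate (fraction or percent, as given); islands
    missing an age get NaN and are excluded from the correlation.
    """
    defined = {k: v for k, v in rates.items() if v is not None}
    if len(defined) < 2:
        raise ValueError("need rates for at least two islands")
    df = pd.DataFrame(
        {
            "island": list(defined),
            "rate": [defined[i] for i in defined],
            "habitation_age_myr": [habitation_ages.get(i, np.nan)
                                   for i in defined],
        }
    ).sort_values("rate", ascending=True, kind="mergesort")
    df["rank"] = df["rate"].rank(method="average")
    both = df.dropna(subset=["habitation_age_myr"])
    if len(both) >= 2 and both["rate"].nunique() > 1 \
            and both["habitation_age_myr"].nunique() > 1:
        rho, p = stats.spearmanr(both["rate"], both["habitation_age_myr"])
    else:
        rho, p = np.nan, np.nan
    df.attrs["spearman_rho"] = float(rho) if rho == rho else np.nan
    df.attrs["spearman_p"] = float(p) if p == p else np.nan
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# construction from tabular inputs
# ---------------------------------------------------------------------------

def cooccurrence_from_tables(
    occupancy: pd.DataFrame,
    pair_list: pd.DataFrame,
    clades: dict[str, str] | None = None,
    allow_hybrid_without_cooccurrence: bool = False,
) -> CooccurrenceData:
    """Build :class:`CooccurrenceData` from an occupancy 0/1 table (taxa x
    islands) and a pair list with columns ``taxon_a``, ``taxon_b``,
    ``islands`` ('+'-separated codes) and ``is_hybrid``."""
    occ = {
        taxon: {isl for isl in occupancy.columns if occupancy.loc[taxon, isl]}
        for taxon in occupancy.index
    }
    pairs: dict[tuple[str, str], set[str]] = {}
    hybrids: dict[tuple[str, str], set[str]] = {}
    for _, row in pair_list.iterrows():
        pair = _norm_pair(str(row["taxon_a"]), str(row["taxon_b"]))
        islands = set(str(row["islands"]).split("+")) if row["islands"] else set()
        pairs.setdefault(pair, set()).update(islands)
        if bool(row.get("is_hybrid", False)):
            hybrids.setdefault(pair, set()).update(islands)
    return CooccurrenceData(
        occupancy=occ,
        pairs=pairs,
        hybrids=hybrids,
        clades=clades or {},
        allow_hybrid_without_cooccurrence=allow_hybrid_without_cooccurrence,
    )
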