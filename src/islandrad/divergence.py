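"""Trait coding and divergence statistics between sister lineages.

Morphological and ecological characters are coded onto a common [0, 1]
scale so that one fully differing character contributes one unit of
squared distance:

* binary characters -> {0, 1};
* ordinal characters with L levels (growth form, thermotype, ombrotype)
  -> equally spaced values 0, 1/(L-1), ..., 1;
* quantitative ranges (elevation) -> the range midpoint, min-max scaled
  by the stated scale bounds;
* categorical multistate characters -> one value per declared state,
  equally spaced, so the maximum pairwise distance is 1.

Divergence between the two lineages descending from a node is the raw
Euclidean distance (RED) between their per-lineage trait profiles, where
a lineage profile is the plain arithmetic mean over its member taxa
(missing entries skipped pairwise).  Fraction-valued means make sub-unit
REDs possible even for fully discrete characters.

Nodes enter the comparison only when they are recovered in every
phylogenetic analysis and highly supported (bootstrap = 100 or posterior
probability >= 0.99) in at least one.  A subclade whose internal topology
is inconsistent across analyses is pooled: the per-analysis REDs of its
nodes are averaged into a single record that replaces the whole subclade.
Intra- vs inter-island groups are compared with a two-sided two-sample
t-test (pooled variance by default, Welch optional).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trees import DatedTree


# ---------------------------------------------------------------------------
# trait coding
# ---------------------------------------------------------------------------

CHARACTER_KINDS = ("binary", "ordinal", "categorical", "quantitative-range")


@dataclass(frozen=True)
class CharacterSpec:
    """Coding declaration for one character.

    ``levels`` orders the states of binary/ordinal/categorical characters;
    ``bounds`` gives the (lo, hi) scale limits of a quantitative-range
    character.  ``char_class`` tags a character as morphological or
    ecological for downstream grouping.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    bounds: tuple[float, float] | None = None
    char_class: str = "morphological"

    def __post_init__(self):
        if self.kind not in CHARACTER_KINDS:
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.kind == "quantitative-range":
            if self.bounds is None or self.bounds[1] <= self.bounds[0]:
                raise ValueError(f"{self.name}: inverted or missing range bounds")
        elif not self.levels or len(self.levels) < 2:
            raise ValueError(f"{self.name}: needs >= 2 declared levels")

    def encode(self, raw) -> float:
        """Scalar code in [0, 1] for one observation (NaN for missing)."""
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            return math.nan
        if self.kind == "quantitative-range":
            lo, hi = _parse_range(raw)
            mid = 0.5 * (lo + hi)
            b0, b1 = self.bounds
            return (mid - b0) / (b1 - b0)
        raw = str(raw)
        if raw not in self.levels:
            raise ValueError(f"{self.name}: unknown level {raw!r}")
        if len(self.levels) == 1:
            return 0.0
        return self.levels.index(raw) / (len(self.levels) - 1)


def _parse_range(raw) -> tuple[float, float]:
    if isinstance(raw, (int, float)):
        return float(raw), float(raw)
    txt = str(raw).replace("–", "-")
    parts = txt.split("-")
    if len(parts) == 1:
        v = float(parts[0])
        return v, v
    lo, hi = float(parts[0]), float(parts[1])
    if hi < lo:
        raise ValueError(f"inverted range {raw!r}")
    return lo, hi


@dataclass
class TraitMatrix:
    """Coded taxa-by-characters matrix with missing-data mask."""

    values: pd.DataFrame                  # float codes in [0, 1], NaN = missing
    specs: dict[str, CharacterSpec]

    def __post_init__(self):
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("coded values must lie in [0, 1]")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def characters(self) -> list[str]:
        return list(self.values.columns)

    def columns_of_class(self, char_class: str) -> list[str]:
        return [c for c in self.characters
                if self.specs[c].char_class == char_class]

    def subset(self, char_class: str) -> "TraitMatrix":
        cols = self.columns_of_class(char_class)
        return TraitMatrix(self.values[cols],
                           {c: self.specs[c] for c in cols})


def encode_traits(raw_table: pd.DataFrame,
                  coding_spec: list[CharacterSpec]) -> TraitMatrix:
    """Code a raw taxa-by-characters table to the [0, 1] scale."""
    specs = {s.name: s for s in coding_spec}
    missing = [c for c in raw_table.columns if c not in specs]
    if missing:
        raise ValueError(f"characters without a coding spec: {missing}")
    coded = pd.DataFrame(index=raw_table.index, dtype=float)
    for name in raw_table.columns:
        coded[name] = [specs[name].encode(v) for v in raw_table[name]]
    if coded.isna().any().any():
        warnings.warn(
            "missing trait entries present; distances will be "
            "pairwise-complete", stacklevel=2,
        )
    return TraitMatrix(coded, {c: specs[c] for c in raw_table.columns})


# ---------------------------------------------------------------------------
# lineage profiles and RED
# ---------------------------------------------------------------------------

def lineage_profile(matrix: TraitMatrix, taxa: list[str]) -> pd.Series:
    """Per-character arithmetic mean over the member taxa of a lineage.

    Missing values are skipped; a character missing in every member yields
    a missing profile entry.
    """
    present = [t for t in taxa if t in matrix.values.index]
    if not present:
        raise ValueError("lineage has no taxon with trait data")
    return matrix.values.loc[present].mean(axis=0, skipna=True)


def lineage_profile_for_node(
    tree: DatedTree, node: int, side: int, matrix: TraitMatrix
) -> pd.Series:
    """Profile of one daughter lineage (``side`` 0 or 1) of ``node``."""
    child = tree.children[node][side]
    taxa = [tree.label[t] for t in tree.descend_tips(child)]
    return lineage_profile(matrix, taxa)


def red(v1: pd.Series, v2: pd.Series) -> float:
    """Raw Euclidean distance over pairwise-complete characters."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2.reindex(v1.index) if isinstance(v2, pd.Series)
                   and isinstance(v1, pd.Series) else v2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no overlapping characters between profiles")
    diff = a[ok] - b[ok]
    return float(np.sqrt((diff ** 2).sum()))


def node_red(tree: DatedTree, node: int, matrix: TraitMatrix) -> float:
    """RED between the two daughter lineages of an internal node."""
    return red(
        lineage_profile_for_node(tree, node, 0, matrix),
        lineage_profile_for_node(tree, node, 1, matrix),
    )


# ---------------------------------------------------------------------------
# node selection from support tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeSelectionCriteria:
    """Recovered in all analyses; BS = 100 or PP >= threshold in >= 1."""

    bootstrap_threshold: float = 100.0
    posterior_threshold: float = 0.99


def select_nodes(
    support_tables: pd.DataFrame,
    criteria: NodeSelectionCriteria = NodeSelectionCriteria(),
) -> list:
    """Nodes present in every analysis and highly supported in at least one.

    ``support_tables`` is long-form with columns ``analysis``, ``node_id``,
    ``support_type`` ('BS' or 'PP') and ``value``; a node absent from an
    analysis's rows was not recovered there.
    """
    required = {"analysis", "node_id", "support_type", "value"}
    if not required <= set(support_tables.columns):
        raise ValueError(f"support table needs columns {sorted(required)}")
    analyses = support_tables["analysis"].unique()
    per_analysis = {
        a: set(support_tables.loc[support_tables["analysis"] == a, "node_id"])
        for a in analyses
    }
    sets = list(per_analysis.values())
    universal = set.intersection(*sets) if sets else set()
    if sets and not universal and not set.intersection(
        *[s for s in sets]
    ):
        # disjoint node-id spaces are a data error, not an empty result
        if all(not (a & b) for i, a in enumerate(sets) for b in sets[i + 1:]):
            raise ValueError("analyses share no node identifiers")
    selected = []
    for node in sorted(universal):
        rows = support_tables[support_tables["node_id"] == node]
        bs_ok = (
            (rows["support_type"] == "BS")
            & (rows["value"] >= criteria.bootstrap_threshold)
        ).any()
        pp_ok = (
            (rows["support_type"] == "PP")
            & (rows["value"] >= criteria.posterior_threshold)
        ).any()
        if bs_ok or pp_ok:
            selected.append(node)
    return selected


# ---------------------------------------------------------------------------
# divergence records, pooling and group comparison
# ---------------------------------------------------------------------------

@dataclass
class DivergenceRecord:
    """Per-node morphological and ecological REDs with their
    biogeographical correlate (intra- vs inter-island)."""

    node: object
    morphological: float
    ecological: float
    correlate: str                      # intra | inter | ambiguous
    islands: str | None = None
    support: float | None = None
    n_characters_differing: float | None = None
    pooled_from: tuple = ()

    def __post_init__(self):
        if self.morphological < 0 or self.ecological < 0:
            raise ValueError("REDs must be non-negative")
        if self.correlate not in ("intra", "inter", "ambiguous"):
            raise ValueError(f"unknown correlate {self.correlate!r}")


def pool_incongruent(
    records: list[DivergenceRecord], node_label="pooled"
) -> DivergenceRecord:
    """Average the (node x analysis) REDs of an inconsistently resolved
    subclade into one record that replaces the whole subclade."""
    if not records:
        raise ValueError("nothing to pool")
    morph = float(np.mean([r.morphological for r in records]))
    eco = float(np.mean([r.ecological for r in records]))
    correlates = {r.correlate for r in records}
    correlate = correlates.pop() if len(correlates) == 1 else "ambiguous"
    ndiff = [r.n_characters_differing for r in records
             if r.n_characters_differing is not None]
    return DivergenceRecord(
        node=node_label,
        morphological=morph,
        ecological=eco,
        correlate=correlate,
        islands=records[0].islands if len({r.islands for r in records}) == 1
        else None,
        n_characters_differing=float(np.mean(ndiff)) if ndiff else None,
        pooled_from=tuple(r.node for r in records),
    )


@dataclass
class GroupComparison:
    trait_class: str
    n_intra: int
    n_inter: int
    mean_intra: float
    mean_inter: float
    sd_intra: float
    sd_inter: float
    t: float
    p: float
    equal_var: bool


def compare_divergence(
    records: list[DivergenceRecord], equal_var: bool = True
) -> dict[str, GroupComparison]:
    """Two-sided t-tests of intra- vs inter-island REDs per trait class.

    Student's pooled-variance test by default; ``equal_var=False`` switches
    to Welch.  Ambiguous records are excluded.
    """
    out = {}
    for trait_class, attr in (("morphological", "morphological"),
                              ("ecological", "ecological")):
        intra = [getattr(r, attr) for r in records if r.correlate == "intra"]
        inter = [getattr(r, attr) for r in records if r.correlate == "inter"]
        if len(intra) < 2 or len(inter) < 2:
            raise ValueError(
                f"{trait_class}: each group needs >= 2 records "
                f"(got {len(intra)} intra, {len(inter)} inter)"
            )
        if (np.std(intra) == 0 and np.std(inter) == 0
                and np.mean(intra) == np.mean(inter)):
            t_stat, p_val = 0.0, 1.0  # degenerate: identical constant groups
        else:
            t_stat, p_val = stats.ttest_ind(intra, inter, equal_var=equal_var)
        out[trait_class] = GroupComparison(
            trait_class=trait_class,
            n_intra=len(intra),
            n_inter=len(inter),
            mean_intra=float(np.mean(intra)),
            mean_inter=float(np.mean(inter)),
            sd_intra=float(np.std(intra, ddof=1)),
            sd_inter=float(np.std(inter, ddof=1)),
            t=float(t_stat),
            p=float(p_val),
            equal_var=equal_var,
        )
    return out


def permutation_pvalue(
    x, y, n_perm: int = 100000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for a difference in group means;
    independent check on the t-test."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    observed = abs(x.mean() - y.mean())
    n = len(x)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n].mean() - pooled[n:].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def records_to_dataframe(records: list[DivergenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [r.node for r in records],
            "correlate": [r.correlate for r in records],
            "islands": [r.islands for r in records],
            "support": [r.support for r in records],
            "morphological_RED": [r.morphological for r in records],
            "ecological_RED": [r.ecological for r in records],
            "n_characters_differing": [
                r.n_characters_differing for r in records
            ],
        }
    )
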