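"""Biogeographical stochastic mapping under a fitted range model.

Draws complete range-evolution histories (anagenetic gains/losses along
branches plus one cladogenetic event per internal node) from the joint
posterior of histories given the tip ranges, via backward pruning and
forward sampling:

1. the pruning pass stores per-node and per-branch-segment conditional
   likelihoods;
2. the root range is drawn from the root conditionals, each internal
   node's daughter pair from its cladogenetic table reweighted by the
   daughters' subtree conditionals, and each branch's segment-boundary
   states from transition probabilities reweighted the same way;
3. the path inside each branch segment is drawn exactly by
   endpoint-conditioned uniformization: the number of (possibly virtual)
   jumps comes from the conditional Poisson mixture, jump times are
   uniform order statistics, and intermediate states follow the
   discrete bridge over powers of the uniformized kernel.

Summaries tally event classes (founder vs sympatric cladogenesis,
anagenetic dispersal/extirpation), build region-by-region source/sink
dispersal matrices, and classify each internal node as an intra- or
inter-island diversification event with a support fraction across maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .geoscape import Geography, TimeStrata
from .rangemodel import ModelSpec, Params, RangeModel
from .trees import DatedTree

CLADO_KINDS = ("clado_founder", "clado_sympatry", "clado_vicariance", "clado_subset")
ANA_KINDS = ("anagenetic_dispersal", "anagenetic_extirpation")


@dataclass(frozen=True)
class EventRecord:
    """One mapped event.

    Branch (anagenetic) events attach to the child-end node id of the host
    branch; cladogenetic events attach to the internal node where the
    split happens.  Ranges are frozensets of region indices.
    """

    kind: str
    node: int
    age: float
    range_before: frozenset[int]
    range_after: frozenset[int] | None = None  # anagenetic result
    region: int | None = None                  # gained / lost / jump region
    left_range: frozenset[int] | None = None   # cladogenetic daughters
    right_range: frozenset[int] | None = None


@dataclass
class StochasticMap:
    node_state: dict[int, frozenset[int]]        # pre-split state at each node
    daughter_state: dict[int, frozenset[int]]    # state at the top of each branch
    events: list[EventRecord]

    def clado_events(self):
        return [e for e in self.events if e.kind in CLADO_KINDS]

    def ana_events(self):
        return [e for e in self.events if e.kind in ANA_KINDS]


@dataclass
class StochasticMapSet:
    maps: list[StochasticMap]
    seed: int
    spec: ModelSpec
    params: Params
    tree: DatedTree

    @property
    def n_maps(self) -> int:
        return len(self.maps)


def classify_clado(
    parent: frozenset[int], left: frozenset[int], right: frozenset[int]
) -> str:
    """Event class of a daughter pair drawn for ``parent``."""
    for a, b in ((left, right), (right, left)):
        if a == parent and len(b) == 1 and not b <= parent:
            return "clado_founder"
    if left == right == parent:
        return "clado_sympatry"
    if len(parent) > 1:
        for a, b in ((left, right), (right, left)):
            if a == parent and len(b) == 1 and b <= parent:
                return "clado_subset"
        if (left | right) == parent and not (left & right):
            return "clado_vicariance"
    raise ValueError(f"unclassifiable event {parent} -> ({left}, {right})")


# ---------------------------------------------------------------------------
# endpoint-conditioned path sampling (uniformization)
# ---------------------------------------------------------------------------

def _sample_uniformized_path(rng, Q, P, dt, a, b, max_jumps=100000):
    """Jump chain of an endpoint-conditioned CTMC segment.

    Returns a list of (time_from_segment_top, from_state, to_state) for the
    *real* jumps, sampled exactly via uniformization (Poisson jump-count
    mixture + discrete bridge over powers of R = I + Q/mu).
    """
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0 or dt <= 0:
        if a != b:
            raise RuntimeError("state change with zero total rate")
        return []
    R = np.eye(Q.shape[0]) + Q / mu
    target = P[a, b]
    if target <= 0:
        raise RuntimeError("endpoint pair has zero probability")
    u = rng.random() * target
    lam = mu * dt
    log_pois = -lam
    powers = [np.eye(Q.shape[0])]
    acc = math.exp(log_pois) * powers[0][a, b]
    n = 0
    while acc < u and n < max_jumps:
        n += 1
        powers.append(powers[-1] @ R)
        log_pois += math.log(lam) - math.log(n)
        acc += math.exp(log_pois) * powers[n][a, b]
    # bridge over states at the n uniformized jumps
    times = np.sort(rng.random(n)) * dt
    states = [a]
    for k in range(1, n):
        w = R[states[-1], :] * powers[n - k][:, b]
        w = np.maximum(w, 0.0)
        s = w.sum()
        states.append(int(rng.choice(len(w), p=w / s)))
    if n > 0:
        states.append(b)
    jumps = []
    for k in range(n):
        if states[k] != states[k + 1]:
            jumps.append((float(times[k]), states[k], states[k + 1]))
    return jumps


# ---------------------------------------------------------------------------
# map sampling
# ---------------------------------------------------------------------------

class _BranchPlan:
    """Per-branch segment data reused across maps: generator, transition
    matrix and the below-data conditional at each segment's younger end,
    plus the fully propagated conditional at the branch top."""

    __slots__ = ("segments", "top")

    def __init__(self, model: RangeModel, tree, node, Qs, down_child):
        parent = tree.parent[node]
        segs = model.strata.segment_branch(tree.age[parent], tree.age[node])
        # young -> old pass to collect below-conditionals at segment bottoms
        v = down_child.copy()
        rev = []
        for i, (stratum, dt) in enumerate(reversed(segs)):
            if i > 0:
                v = v * model._valid[stratum]
            P = expm(Qs[stratum] * dt)
            rev.append((Qs[stratum], dt, P, v.copy()))
            v = np.maximum(P @ v, 0.0)
        self.segments = rev[::-1]  # old -> young
        self.top = v


def sample_stochastic_maps(
    tree: DatedTree,
    tip_ranges: dict[str, frozenset[int]],
    spec: ModelSpec,
    params: Params,
    geography: Geography,
    strata: TimeStrata | None = None,
    n_maps: int = 50,
    seed: int = 0,
) -> StochasticMapSet:
    """Draw ``n_maps`` independent histories consistent with the tip data."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    model = RangeModel(spec, geography, strata)
    lnL, partials = model.log_likelihood(
        tree, tip_ranges, params, return_partials=True
    )
    if partials is None or not np.isfinite(lnL):
        bad = _find_zero_tip(model, tree, tip_ranges, params)
        raise RuntimeError(
            "tip data have zero probability under the model"
            + (f" (offending tip: {bad})" if bad else "")
        )
    down = partials["down"]
    Qs = partials["generators"]
    clado = partials["clado"]
    space = model.space
    plans = {
        node: _BranchPlan(model, tree, node, Qs, down[node])
        for node in tree.postorder()
        if tree.parent[node] is not None
    }

    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_maps):
        maps.append(
            _sample_one(rng, model, tree, down, clado, plans, space)
        )
    return StochasticMapSet(maps=maps, seed=seed, spec=spec, params=params,
                            tree=tree)


def _find_zero_tip(model, tree, tip_ranges, params):
    for tip in tree.tips:
        try:
            model.tip_vector(frozenset(tip_ranges[tree.label[tip]]))
        except (ValueError, KeyError):
            return tree.label[tip]
    return None


def _draw(rng, weights) -> int:
    w = np.maximum(np.asarray(weights, dtype=float), 0.0)
    s = w.sum()
    if s <= 0:
        raise RuntimeError("no admissible state to sample")
    return int(rng.choice(len(w), p=w / s))


def _sample_one(rng, model, tree, down, clado, plans, space) -> StochasticMap:
    node_state: dict[int, frozenset[int]] = {}
    daughter_state: dict[int, frozenset[int]] = {}
    events: list[EventRecord] = []

    root = tree.root
    root_idx = _draw(rng, down[root])
    node_state[root] = space.states[root_idx]

    for node in tree.preorder():
        if not tree.children[node]:
            continue
        a = space.index_of(node_state[node])
        stratum = model.strata.stratum_at(tree.age[node])
        table = clado.table(stratum, a)
        l_node, r_node = tree.children[node]
        weights = [
            p * plans[l_node].top[il] * plans[r_node].top[ir]
            for il, ir, p in table
        ]
        il, ir, _ = table[_draw(rng, weights)]
        left, right = space.states[il], space.states[ir]
        parent_range = space.states[a]
        kind = classify_clado(parent_range, left, right)
        region = None
        if kind == "clado_founder":
            jumped = left if left != parent_range else right
            region = next(iter(jumped))
        events.append(
            EventRecord(
                kind=kind, node=node, age=tree.age[node],
                range_before=parent_range,
                left_range=left, right_range=right, region=region,
            )
        )
        daughter_state[l_node] = left
        daughter_state[r_node] = right
        for child, top in ((l_node, left), (r_node, right)):
            _sample_branch(
                rng, tree, plans[child], child, top, node_state, events, space,
            )
    return StochasticMap(node_state=node_state, daughter_state=daughter_state,
                         events=events)


def _sample_branch(rng, tree, plan, child, top_range, node_state,
                   events, space):
    parent_age = tree.age[tree.parent[child]]
    cur = space.index_of(top_range)
    age_top = parent_age
    for Q, dt, P, below in plan.segments:
        bot = _draw(rng, P[cur, :] * below)
        for t, s_from, s_to in _sample_uniformized_path(
            rng, Q, P, dt, cur, bot
        ):
            A, B = space.states[s_from], space.states[s_to]
            if len(B) > len(A):
                kind, region = "anagenetic_dispersal", next(iter(B - A))
            else:
                kind, region = "anagenetic_extirpation", next(iter(A - B))
            events.append(
                EventRecord(
                    kind=kind, node=child, age=age_top - t,
                    range_before=A, range_after=B, region=region,
                )
            )
        cur = bot
        age_top -= dt
    node_state[child] = space.states[cur]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _per_map_counts(m: StochasticMap) -> dict[str, float]:
    c = {k: 0.0 for k in CLADO_KINDS + ANA_KINDS}
    for e in m.events:
        c[e.kind] += 1.0
    return c


def summarize_events(mapset: StochasticMapSet) -> pd.DataFrame:
    """Mean +/- sd event counts per map, with percentages over the three
    counted classes (founder cladogenesis, sympatric cladogenesis,
    anagenetic dispersal)."""
    rows = [_per_map_counts(m) for m in mapset.maps]
    df = pd.DataFrame(rows)
    df["cladogenetic_total"] = df[list(CLADO_KINDS)].sum(axis=1)
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1).fillna(0.0)})
    counted = ["clado_founder", "clado_sympatry", "anagenetic_dispersal"]
    total = out.loc[counted, "mean"].sum()
    out["percent"] = np.nan
    if total > 0:
        out.loc[counted, "percent"] = 100.0 * out.loc[counted, "mean"] / total
    return out


def table4_layout(summary: pd.DataFrame) -> pd.DataFrame:
    """Reshape an event summary into the two-way cladogenesis/anagenesis by
    dispersal/sympatry layout."""
    f = summary.loc["clado_founder"]
    s = summary.loc["clado_sympatry"]
    a = summary.loc["anagenetic_dispersal"]

    def cell(mean, sd, pct):
        if sd != sd:  # sd undefined for derived margins
            return f"{mean:.2f}; {pct:.1f}%"
        return f"{mean:.2f} (± {sd:.2f}); {pct:.1f}%"

    total = f["mean"] + s["mean"] + a["mean"]
    clad_sum = f["mean"] + s["mean"]
    clad_sd = summary.loc["cladogenetic_total", "sd"]
    return pd.DataFrame(
        {
            "Dispersal": [
                cell(f["mean"], f["sd"], f["percent"]),
                cell(a["mean"], a["sd"], a["percent"]),
                cell(f["mean"] + a["mean"], np.nan, f["percent"] + a["percent"]),
            ],
            "Sympatry": [
                cell(s["mean"], s["sd"], s["percent"]), "–",
                cell(s["mean"], s["sd"], s["percent"]),
            ],
            "Sum": [
                cell(clad_sum, clad_sd, f["percent"] + s["percent"]),
                cell(a["mean"], a["sd"], a["percent"]),
                cell(total, np.nan, 100.0),
            ],
        },
        index=["Cladogenesis", "Anagenesis", "Sum"],
    )


@dataclass
class SourceSinkMatrix:
    mean: pd.DataFrame       # region x region mean dispersal counts
    sd: pd.DataFrame
    outgoing: pd.Series      # row sums (mean)
    incoming: pd.Series      # column sums (mean)
    outgoing_pct: pd.Series
    incoming_pct: pd.Series
    grand_total: float


def source_sink_matrix(
    mapset: StochasticMapSet, geography: Geography
) -> SourceSinkMatrix:
    """Region-by-region mean dispersal counts (rows = source, columns =
    target), counting founder events and anagenetic gains alike.

    A dispersal out of a multi-region range has an ambiguous single source;
    the count is split as 1/|range| over the occupied source regions, which
    preserves every marginal total.
    """
    n = geography.n_regions
    per_map = []
    for m in mapset.maps:
        M = np.zeros((n, n))
        for e in m.events:
            if e.kind == "clado_founder" or e.kind == "anagenetic_dispersal":
                src = e.range_before
                tgt = e.region
                for s in src:
                    M[s, tgt] += 1.0 / len(src)
        per_map.append(M)
    stack = np.stack(per_map)
    mean = pd.DataFrame(stack.mean(axis=0), index=geography.regions,
                        columns=geography.regions)
    sd = pd.DataFrame(stack.std(axis=0, ddof=1) if len(per_map) > 1
                      else np.zeros((n, n)),
                      index=geography.regions, columns=geography.regions)
    outgoing = mean.sum(axis=1)
    incoming = mean.sum(axis=0)
    total = float(mean.to_numpy().sum())
    pct_out = 100.0 * outgoing / total if total else outgoing * np.nan
    pct_in = 100.0 * incoming / total if total else incoming * np.nan
    return SourceSinkMatrix(mean=mean, sd=sd, outgoing=outgoing,
                            incoming=incoming, outgoing_pct=pct_out,
                            incoming_pct=pct_in, grand_total=total)


@dataclass(frozen=True)
class NodeClassification:
    node: int
    call: str                  # intra_island | inter_island | ambiguous
    support: float             # fraction of maps behind the call
    modal_island: str | None   # island (intra) or dispersal path (inter)
    n_maps: int


def _event_is_intra(e: EventRecord) -> bool:
    """Intra-island: sympatric cladogenesis whose daughters share exactly
    one region.  Founder, vicariant and subset events are inter-island, as
    is widespread sympatry (the daughters share more than one region)."""
    if e.kind != "clado_sympatry":
        return False
    shared = e.left_range & e.right_range
    return len(shared) == 1


def _event_place(e: EventRecord, geography: Geography) -> str:
    if _event_is_intra(e):
        return geography.regions[next(iter(e.left_range & e.right_range))]
    if e.kind == "clado_founder":
        src = "+".join(geography.regions[i] for i in sorted(e.range_before))
        return f"{src}→{geography.regions[e.region]}"
    lab = lambda r: "+".join(geography.regions[i] for i in sorted(r))
    return f"{lab(e.left_range)}|{lab(e.right_range)}"


def classify_nodes(
    mapset: StochasticMapSet, geography: Geography
) -> list[NodeClassification]:
    """Per internal node: majority intra- vs inter-island call with its
    support fraction across maps and the modal island (or island pair).
    An exact 50/50 split is reported as ambiguous."""
    tree = mapset.tree
    out = []
    for node in tree.internal_nodes:
        intra, places = 0, {}
        for m in mapset.maps:
            ev = next(e for e in m.clado_events() if e.node == node)
            if _event_is_intra(ev):
                intra += 1
            key = (_event_is_intra(ev), _event_place(ev, geography))
            places[key] = places.get(key, 0) + 1
        n = mapset.n_maps
        frac_intra = intra / n
        if frac_intra == 0.5:
            call, support = "ambiguous", 0.5
            modal = None
        else:
            is_intra = frac_intra > 0.5
            call = "intra_island" if is_intra else "inter_island"
            support = frac_intra if is_intra else 1.0 - frac_intra
            cand = {p: c for (flag, p), c in places.items() if flag == is_intra}
            modal = max(sorted(cand), key=lambda p: cand[p])
        out.append(NodeClassification(node=node, call=call, support=support,
                                      modal_island=modal, n_maps=n))
    return out


def per_island_sympatry_counts(
    mapset: StochasticMapSet, geography: Geography
) -> pd.DataFrame:
    """Mean +/- sd intra-island (sympatric) speciation count per region and
    its percentage of the sympatric total.  A widespread sympatric event is
    split evenly over the daughters' shared regions."""
    n = geography.n_regions
    per_map = np.zeros((mapset.n_maps, n))
    for i, m in enumerate(mapset.maps):
        for e in m.clado_events():
            if e.kind != "clado_sympatry":
                continue
            shared = e.left_range & e.right_range
            for r in shared:
                per_map[i, r] += 1.0 / len(shared)
    mean = per_map.mean(axis=0)
    sd = per_map.std(axis=0, ddof=1) if mapset.n_maps > 1 else np.zeros(n)
    total = mean.sum()
    pct = 100.0 * mean / total if total > 0 else np.full(n, np.nan)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "percent": pct}, index=geography.regions
    )


# ---------------------------------------------------------------------------
# replay (consistency check / export support)
# ---------------------------------------------------------------------------

def replay_map(m: StochasticMap, tree: DatedTree) -> dict[int, frozenset[int]]:
    """Re-derive every node state by replaying the event list from the
    sampled root state; used to verify history consistency."""
    states: dict[int, frozenset[int]] = {tree.root: m.node_state[tree.root]}
    by_branch: dict[int, list[EventRecord]] = {}
    clado_at: dict[int, EventRecord] = {}
    for e in m.events:
        if e.kind in CLADO_KINDS:
            clado_at[e.node] = e
        else:
            by_branch.setdefault(e.node, []).append(e)
    for node in tree.preorder():
        if not tree.children[node]:
            continue
        e = clado_at[node]
        if states[node] != e.range_before:
            raise AssertionError("cladogenetic parent range mismatch")
        for child, start in zip(tree.children[node],
                                (e.left_range, e.right_range)):
            cur = start
            for ev in sorted(by_branch.get(child, []), key=lambda x: -x.age):
                if ev.range_before != cur:
                    raise AssertionError("anagenetic chain mismatch")
                cur = ev.range_after
            states[child] = cur
    return states


def map_to_dataframe(m: StochasticMap, geography: Geography) -> pd.DataFrame:
    """Tidy per-event table (one row per event) for TSV export."""
    lab = lambda r: ("null" if r is not None and not r else
                     None if r is None else
                     "+".join(geography.regions[i] for i in sorted(r)))
    rows = []
    for e in sorted(m.events, key=lambda x: -x.age):
        rows.append(
            {
                "kind": e.kind,
                "node": e.node,
                "age_myr": e.age,
                "range_before": lab(e.range_before),
                "range_after": lab(e.range_after),
                "region": geography.regions[e.region]
                if e.region is not None else None,
                "left_range": lab(e.left_range),
                "right_range": lab(e.right_range),
            }
        )
    return pd.DataFrame(rows)
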