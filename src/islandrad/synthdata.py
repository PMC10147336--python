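"""Forward-time island-radiation simulator with known ground truth.

Generates every input the analysis stages consume — dated trees, tip
ranges, trait matrices, co-occurrence data — from an explicit birth
process on islands, together with a complete event log, so inference can
be checked against truth at desk scale.

The lineage process is a continuous-time birth–death-like process:

* founder speciation at rate ``f_sim`` /myr per lineage (one daughter
  jumps into an available region outside the parent range);
* within-island speciation at rate ``s_sim`` /myr per lineage (both
  daughters inherit the parent range);
* anagenetic region gain at rate ``d_sim`` per occupied region per
  available unoccupied region, and loss at ``e_sim`` per occupied region;
  a lineage whose range empties goes extinct.

Region availability follows the emergence schedule, so rates change
piecewise at emergence ages.  Note the deliberate mismatch with the
inference model: simulation speciation is a *rate* process while the
inference model weights cladogenetic events per node; recovery tests that
need model-consistent data use :func:`simulate_ranges_on_tree` instead,
which draws ranges on a fixed tree under the inference model itself.

Defaults are set to the study scale: ~50 tips over ~6 myr, 11 regions
with staggered emergence, anagenetic rates of order 0.02–0.05 /myr, and
equal founder / within-island speciation rates (the study inferred the
two cladogenetic modes in nearly equal numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cooccur import CooccurrenceData
from .divergence import CharacterSpec, TraitMatrix
from .geoscape import Geography, TimeStrata, build_geography, study_geography
from .rangemodel import ModelSpec, Params, cladogenetic_event_table
from .trees import DatedTree


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Radiation-simulator settings (rates are per lineage per myr)."""

    geography: Geography
    strata: TimeStrata
    d_sim: float = 0.021          # anagenetic gain, per occupied x target region
    e_sim: float = 0.044          # anagenetic loss, per occupied region
    f_sim: float = 0.35           # founder speciation
    s_sim: float = 0.35           # within-island speciation
    duration: float = 6.0         # myr from the first lineage to the present
    n_tips: int | None = None     # if set, cap the extant-lineage count:
                                  # once reached, only anagenesis continues
    min_tips: int = 10
    max_tips: int = 90
    max_range_size: int = 5
    start_region: str | None = None   # default: first always-available region
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self):
        for r in (self.d_sim, self.e_sim, self.f_sim, self.s_sim):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def study_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Simulator configured to the study conditions: 11 regions with the
    staggered emergence schedule, ~50 tips over ~6 myr, low anagenetic
    rates, equal founder and within-island speciation rates."""
    geo, strata = study_geography()
    cfg = SimConfig(geography=geo, strata=strata, n_tips=50, duration=8.0,
                    seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# forward lineage simulation
# ---------------------------------------------------------------------------

@dataclass
class SimEvent:
    """Ground-truth log entry (full, unpruned genealogy)."""

    kind: str              # founder | within_island | gain | loss | extinction
    lineage: int
    time: float            # forward time from process start
    range_before: frozenset[int]
    range_after: frozenset[int] | None = None
    region: int | None = None
    daughters: tuple[int, int] | None = None


@dataclass
class RadiationResult:
    tree: DatedTree
    tip_ranges: dict[str, frozenset[int]]
    events: list[SimEvent]                 # full log, forward time
    node_truth: dict[int, str]             # pruned node id -> event kind
    node_regions: dict[int, frozenset[int]]  # pruned node id -> parent range
    n_attempts: int
    config: SimConfig
    horizon: float = 0.0      # forward time of the present (tips sit here)

    def event_age(self, event: "SimEvent") -> float:
        """Age of a logged event in myr before present."""
        return self.horizon - event.time

    @property
    def true_founder_fraction(self) -> float:
        """Fraction of the pruned tree's cladogenetic events that were
        founder events (the quantity stochastic mapping estimates)."""
        kinds = list(self.node_truth.values())
        return sum(k == "founder" for k in kinds) / len(kinds)


class _Lineage:
    __slots__ = ("id", "parent", "birth", "death", "range", "children",
                 "range_history")

    def __init__(self, lid, parent, birth, rng_range):
        self.id = lid
        self.parent = parent
        self.birth = birth
        self.death = None
        self.range = rng_range
        self.children: list[int] = []
        self.range_history = [(birth, rng_range)]


def simulate_radiation(config: SimConfig) -> RadiationResult:
    """Run the forward process, prune to survivors, and emit ground truth.

    Retries (up to ``max_retries``) on total extinction or a tip count
    outside the accepted band; raises if no attempt succeeds.
    """
    rng = np.random.default_rng(config.seed)
    last_err = None
    for attempt in range(1, config.max_retries + 1):
        try:
            result = _simulate_once(config, rng)
            result.n_attempts = attempt
            return result
        except _RetrySimulation as err:
            last_err = err
    raise RuntimeError(
        f"simulation failed after {config.max_retries} attempts: {last_err}"
    )


class _RetrySimulation(Exception):
    pass


def _available(config: SimConfig, age: float) -> frozenset[int]:
    return config.geography.available_at(age)


def _simulate_once(config: SimConfig, rng) -> RadiationResult:
    geo = config.geography
    T = config.duration
    if config.start_region is None:
        always = [c for c in geo.regions if c not in geo.emergence_age]
        start = geo.index(always[0])
    else:
        start = geo.index(config.start_region)
    if geo.emergence_age.get(geo.regions[start], math.inf) < T:
        raise ValueError("start region not emerged at the process start")

    lineages: dict[int, _Lineage] = {0: _Lineage(0, None, 0.0, frozenset({start}))}
    alive: set[int] = {0}
    events: list[SimEvent] = []
    next_id = 1
    t = 0.0
    # emergence times in forward coordinates
    emergences = sorted(
        T - a for a in set(geo.emergence_age.values()) if a < T
    )

    speciation_on = True

    def rates(age):
        avail = _available(config, age)
        per = {}
        for lid in alive:
            A = lineages[lid].range
            gain_targets = len(avail - A) if len(A) < config.max_range_size else 0
            gain = config.d_sim * len(A) * gain_targets
            loss = config.e_sim * len(A)
            founder = (config.f_sim if (avail - A) else 0.0) \
                if speciation_on else 0.0
            within = config.s_sim if speciation_on else 0.0
            per[lid] = (gain, loss, founder, within)
        return avail, per

    reached_cap = False
    while t < T and alive:
        age = T - t
        avail, per = rates(age)
        total = sum(sum(v) for v in per.values())
        nxt_emerg = next((e for e in emergences if e > t), None)
        if total <= 0:
            t = nxt_emerg if nxt_emerg is not None else T
            continue
        dt = rng.exponential(1.0 / total)
        if nxt_emerg is not None and t + dt > nxt_emerg:
            t = nxt_emerg
            continue
        t += dt
        if t >= T:
            break
        # pick lineage and channel
        lids = sorted(per)
        weights = np.array([sum(per[l]) for l in lids])
        lid = lids[_draw_index(rng, weights)]
        gain, loss, founder, within = per[lid]
        channel = _draw_index(rng, np.array([gain, loss, founder, within]))
        lin = lineages[lid]
        A = lin.range
        age = T - t
        avail = _available(config, age)
        if channel == 0:   # anagenetic gain
            choices = sorted(avail - A)
            k = choices[int(rng.integers(len(choices)))]
            lin.range = A | {k}
            lin.range_history.append((t, lin.range))
            events.append(SimEvent("gain", lid, t, A, lin.range, k))
        elif channel == 1:  # anagenetic loss
            choices = sorted(A)
            k = choices[int(rng.integers(len(choices)))]
            lin.range = A - {k}
            lin.range_history.append((t, lin.range))
            events.append(SimEvent("loss", lid, t, A, lin.range, k))
            if not lin.range:
                lin.death = t
                alive.discard(lid)
                events.append(SimEvent("extinction", lid, t, frozenset()))
        else:               # speciation
            if channel == 2:
                choices = sorted(avail - A)
                k = choices[int(rng.integers(len(choices)))]
                ranges = (A, frozenset({k}))
                kind, region = "founder", k
            else:
                ranges = (A, A)
                kind, region = "within_island", None
            c1, c2 = next_id, next_id + 1
            next_id += 2
            for cid, crange in zip((c1, c2), ranges):
                lineages[cid] = _Lineage(cid, lid, t, crange)
            lin.children = [c1, c2]
            lin.death = t
            alive.discard(lid)
            alive.update((c1, c2))
            events.append(
                SimEvent(kind, lid, t, A, None, region, daughters=(c1, c2))
            )
            if config.n_tips is not None and len(alive) >= config.n_tips:
                # cap reached: from here only anagenesis runs, so the tree
                # keeps exactly this many tips while ages stay anchored to
                # the emergence schedule
                reached_cap = True
                speciation_on = False

    horizon = T
    if not alive:
        raise _RetrySimulation("total extinction")
    if config.n_tips is not None:
        if not reached_cap:
            raise _RetrySimulation(
                f"never reached {config.n_tips} lineages (got {len(alive)})"
            )
        if len(alive) != config.n_tips:
            raise _RetrySimulation("lineage lost after reaching the cap")
    else:
        n = len(alive)
        if n < config.min_tips or n > config.max_tips:
            raise _RetrySimulation(f"{n} surviving tips outside accepted band")

    return _assemble(config, lineages, alive, events, horizon)


def _draw_index(rng, weights) -> int:
    w = np.maximum(np.asarray(weights, float), 0.0)
    return int(rng.choice(len(w), p=w / w.sum()))


def _assemble(config, lineages, alive, events, horizon) -> RadiationResult:
    # keep lineages with >= 1 extant descendant
    surviving: set[int] = set()
    for lid in alive:
        cur = lid
        while cur is not None and cur not in surviving:
            surviving.add(cur)
            cur = lineages[cur].parent

    # pruned binary structure: a node is a speciation whose both daughters
    # have survivors; chains of single-survivor speciations are suppressed
    def surviving_children(lid):
        return [c for c in lineages[lid].children if c in surviving]

    parent: list[int | None] = []
    children: list[tuple[int, ...]] = []
    age_l: list[float] = []
    label: list[str | None] = []
    node_of: dict[int, int] = {}
    truth: dict[int, str] = {}
    regions_at: dict[int, frozenset[int]] = {}

    def build(lid) -> int:
        """Return the pruned-node id for the subtree seeded by lineage lid."""
        cur = lid
        while True:
            kids = surviving_children(cur)
            if not kids:            # extant tip (cur in alive)
                idx = len(parent)
                parent.append(None)
                children.append(())
                age_l.append(0.0)
                label.append(f"t{cur}")
                node_of[cur] = idx
                return idx
            if len(kids) == 1:
                cur = kids[0]
                continue
            left = build(kids[0])
            right = build(kids[1])
            idx = len(parent)
            parent.append(None)
            children.append((left, right))
            age_l.append(horizon - lineages[cur].death)
            label.append(None)
            parent[left] = idx
            parent[right] = idx
            ev = next(
                e for e in events
                if e.daughters == tuple(lineages[cur].children)
            )
            truth[idx] = ev.kind
            regions_at[idx] = ev.range_before
            node_of[cur] = idx
            return idx

    root_lineage = 0
    build(root_lineage)
    tree = DatedTree(parent=parent, children=children, age=age_l, label=label)
    tip_ranges = {
        f"t{lid}": lineages[lid].range for lid in alive
    }
    bad = [k for k, v in tip_ranges.items() if not v]
    if bad:
        raise _RetrySimulation("extant lineage with empty range")
    return RadiationResult(
        tree=tree, tip_ranges=tip_ranges, events=events,
        node_truth=truth, node_regions=regions_at,
        n_attempts=0, config=config, horizon=horizon,
    )


def replay_event_log(result: RadiationResult) -> dict[str, frozenset[int]]:
    """Re-derive extant tip ranges by replaying the full event log from the
    starting lineage; equality with ``result.tip_ranges`` is the
    consistency contract of the simulator."""
    cfg = result.config
    if cfg.start_region is None:
        always = [c for c in cfg.geography.regions
                  if c not in cfg.geography.emergence_age]
        start = cfg.geography.index(always[0])
    else:
        start = cfg.geography.index(cfg.start_region)
    ranges: dict[int, frozenset[int]] = {0: frozenset({start})}
    dead: set[int] = set()
    for e in sorted(result.events, key=lambda x: x.time):
        if e.kind in ("gain", "loss"):
            assert ranges[e.lineage] == e.range_before
            ranges[e.lineage] = e.range_after
        elif e.kind == "extinction":
            dead.add(e.lineage)
        elif e.kind in ("founder", "within_island"):
            c1, c2 = e.daughters
            if e.kind == "founder":
                ranges[c1] = e.range_before
                ranges[c2] = frozenset({e.region})
            else:
                ranges[c1] = ranges[c2] = e.range_before
            dead.add(e.lineage)
    return {
        f"t{lid}": r for lid, r in ranges.items()
        if lid not in dead and f"t{lid}" in result.tip_ranges
    }


# ---------------------------------------------------------------------------
# model-consistent range simulation on a fixed tree
# ---------------------------------------------------------------------------

def simulate_ranges_on_tree(
    tree: DatedTree,
    spec: ModelSpec,
    params: Params,
    geography: Geography,
    strata: TimeStrata | None = None,
    seed: int = 0,
    root_range: frozenset[int] | None = None,
    max_retries: int = 200,
):
    """Draw tip ranges on a fixed dated tree under the inference model
    itself (anagenetic CTMC along branches, cladogenetic table draws at
    nodes).  Used for parameter-recovery experiments where "simulate at
    (d, e, j)" must mean the model's own parameters.

    Returns ``(tip_ranges, node_events)`` where ``node_events`` maps each
    internal node to its true cladogenetic event class.  Because observed
    tips cannot have the null range, each branch walk is conditioned on
    not being absorbed into the null range (walks that hit it are
    redrawn); this is the survivorship conditioning implicit in any
    observed dataset.
    """
    if strata is None:
        _, strata = build_geography(geography.regions, geography.emergence_age)
    rng = np.random.default_rng(seed)
    from .stochmap import classify_clado  # local import to avoid cycle

    for _ in range(max_retries):
        try:
            return _simulate_on_tree_once(
                tree, spec, params, geography, strata, rng, root_range,
                classify_clado,
            )
        except _RetrySimulation:
            continue
    raise RuntimeError("range simulation kept hitting extinct tips")


def _simulate_on_tree_once(tree, spec, params, geography, strata, rng,
                           root_range, classify_clado):
    root_age = tree.root_age
    avail_root = strata.mask_at(root_age)
    if root_range is None:
        singles = sorted(avail_root)
        root_range = frozenset({singles[int(rng.integers(len(singles)))]})
    state: dict[int, frozenset[int]] = {tree.root: frozenset(root_range)}
    node_events: dict[int, str] = {}
    for node in tree.preorder():
        if not tree.children[node]:
            continue
        A = state[node]
        if not A:
            raise _RetrySimulation("extinct internal lineage")
        table = cladogenetic_event_table(
            spec, params, A, strata.mask_at(tree.age[node])
        )
        probs = np.array([p for _, _, p in table])
        il = int(rng.choice(len(table), p=probs / probs.sum()))
        left, right, _ = table[il]
        node_events[node] = classify_clado(A, left, right)
        for child, start in zip(tree.children[node], (left, right)):
            for _ in range(1000):
                end = _evolve_range(
                    start, tree.age[node], tree.age[child], spec, params,
                    geography, strata, rng,
                )
                if end:
                    break
            else:
                raise _RetrySimulation("branch absorbed into the null range")
            state[child] = end
    tips = {tree.label[tip]: state[tip] for tip in tree.tips}
    return tips, node_events


def _evolve_range(A, older, younger, spec, params, geography, strata, rng):
    """Gillespie walk of the anagenetic CTMC down one branch."""
    t = older
    while t > younger and A:
        avail = strata.mask_at(t)
        gain_targets = sorted(avail - A) if len(A) < spec.max_range_size else []
        gain = params.d * len(A) * len(gain_targets)
        loss = params.e * len(A)
        total = gain + loss
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        # rates change at stratum boundaries: cap the step there
        boundary = next((b for b in strata.boundaries if younger < b < t), None)
        if boundary is not None and t - dt < boundary:
            t = boundary - 1e-12
            continue
        t -= dt
        if t <= younger:
            break
        if rng.random() * total < gain:
            k = gain_targets[int(rng.integers(len(gain_targets)))]
            A = A | {k}
        else:
            drop = sorted(A)[int(rng.integers(len(A)))]
            A = A - {drop}
    return A


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def default_trait_specs() -> list[CharacterSpec]:
    """Eleven morphological and three habitat characters shaped like the
    study's matrix (growth form plus ten mostly binary morphological
    characters; elevation, thermotype, ombrotype)."""
    morph = [
        CharacterSpec("growth_form", "ordinal",
                      ("rosette", "chamaephyte", "nanophanerophyte")),
        CharacterSpec("branch_indumentum", "binary", ("absent", "present")),
        CharacterSpec("leaf_indumentum", "binary", ("absent", "present")),
        CharacterSpec("inflorescence_indumentum", "binary",
                      ("absent", "present")),
        CharacterSpec("leaf_scar_scales", "binary", ("absent", "present")),
        CharacterSpec("leaf_cilia", "binary", ("absent", "present")),
        CharacterSpec("tannic_stripes", "binary", ("absent", "present")),
        CharacterSpec("flower_merism", "ordinal", ("low", "medium", "high")),
        CharacterSpec("petal_colour", "categorical",
                      ("white", "yellow", "red")),
        CharacterSpec("carpel_appendages", "binary", ("absent", "present")),
        CharacterSpec("nectar_glands", "binary", ("absent", "present")),
    ]
    eco = [
        CharacterSpec("elevation", "quantitative-range", bounds=(0.0, 2500.0),
                      char_class="ecological"),
        CharacterSpec("thermotype", "ordinal",
                      ("infra", "thermo", "meso", "supra"),
                      char_class="ecological"),
        CharacterSpec("ombrotype", "ordinal",
                      ("arid", "semiarid", "dry", "humid"),
                      char_class="ecological"),
    ]
    return morph + eco


@dataclass(frozen=True)
class TraitConfig:
    """Trait-evolution settings.

    ``jump_rate`` is the per-character level-change rate (/myr) of discrete
    characters; ``bm_sigma`` the Brownian scale (per sqrt-myr, on the [0,1]
    coded axis) of quantitative characters; ``delta`` the extra divergence
    kick applied between the daughters of within-island nodes, expressed in
    per-character units and spread over the kicked characters so the extra
    RED is about ``delta``.
    """

    specs: tuple[CharacterSpec, ...] = field(
        default_factory=lambda: tuple(default_trait_specs())
    )
    # ~100 lineage-myr of tree at the study scale: 0.04 /myr gives each
    # discrete character a handful of state changes across the radiation,
    # matching the sparse variation of real identification characters
    jump_rate: float = 0.04
    bm_sigma: float = 0.08
    delta: float = 0.0
    kick_class: str = "morphological"
    seed: int = 0


def simulate_traits(
    tree: DatedTree,
    intra_nodes: set[int],
    config: TraitConfig,
) -> TraitMatrix:
    """Evolve the character set along the tree and code the tips.

    Discrete characters follow a jump process between their levels
    (ordinal: one level up/down; binary/categorical: any other level);
    quantitative characters follow reflected Brownian motion on [0, 1].
    At nodes in ``intra_nodes`` the daughters receive opposite divergence
    kicks totalling ``delta`` split across the kicked characters.
    """
    rng = np.random.default_rng(config.seed)
    specs = list(config.specs)
    kicked = [
        i for i, s in enumerate(specs)
        if config.kick_class in ("all", s.char_class)
    ]
    per_char_kick = (
        config.delta / math.sqrt(len(kicked)) if kicked and config.delta else 0.0
    )

    def n_levels(s: CharacterSpec) -> int:
        return len(s.levels) if s.levels else 0

    # state: coded value in [0,1] per character
    init = np.array([
        0.0 if s.kind != "quantitative-range" else 0.4 for s in specs
    ])
    values: dict[int, np.ndarray] = {tree.root: init}

    def evolve(v: np.ndarray, dt: float) -> np.ndarray:
        v = v.copy()
        for i, s in enumerate(specs):
            if s.kind == "quantitative-range":
                x = v[i] + rng.normal(0.0, config.bm_sigma * math.sqrt(dt))
                v[i] = _reflect01(x)
            else:
                L = n_levels(s)
                gap = 1.0 / (L - 1)
                n_jumps = rng.poisson(config.jump_rate * dt)
                level = round(v[i] / gap)
                for _ in range(n_jumps):
                    if s.kind == "ordinal":
                        step = -1 if level == L - 1 else (
                            1 if level == 0 else (1 if rng.random() < 0.5 else -1)
                        )
                        level += step
                    else:
                        others = [x for x in range(L) if x != level]
                        level = others[int(rng.integers(len(others)))]
                v[i] = level * gap
        return v

    def kick(v: np.ndarray, sign: int) -> np.ndarray:
        if not per_char_kick:
            return v
        v = v.copy()
        for i in kicked:
            s = specs[i]
            if s.kind == "quantitative-range":
                v[i] = _reflect01(v[i] + sign * per_char_kick / 2.0)
            else:
                L = n_levels(s)
                gap = 1.0 / (L - 1)
                p = min(1.0, per_char_kick)
                if rng.random() < p:
                    level = round(v[i] / gap)
                    step = sign if 0 <= level + sign < L else -sign
                    v[i] = (level + step) * gap
        return v

    for node in tree.preorder():
        if not tree.children[node]:
            continue
        v = values[node]
        signs = (1, -1) if rng.random() < 0.5 else (-1, 1)
        for child, sign in zip(tree.children[node], signs):
            start = kick(v, sign) if node in intra_nodes else v
            values[child] = evolve(start, tree.branch_length(child))

    rows = {tree.label[t]: values[t] for t in tree.tips}
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.name for s in specs]
    )
    return TraitMatrix(df, {s.name: s for s in specs})


def _reflect01(x: float) -> float:
    x = math.fmod(abs(x), 2.0)
    return 2.0 - x if x > 1.0 else x


# ---------------------------------------------------------------------------
# co-occurrence simulation
# ---------------------------------------------------------------------------

def simulate_cooccurrence(
    tip_ranges: dict[str, frozenset[int]],
    geography: Geography,
    co_prob: float = 0.6,
    hybrid_prob: float = 0.3,
    co_prob_by_island: dict[str, float] | None = None,
    seed: int = 0,
) -> CooccurrenceData:
    """Draw pairwise co-occurrence and nested hybrid pairs per island.

    For every island and taxon pair sharing it, the pair co-occurs there
    with probability ``co_prob`` (overridable per island, e.g. to encode a
    decline with habitation time); hybrids are drawn among co-occurring
    pairs only, with probability ``hybrid_prob``.
    """
    rng = np.random.default_rng(seed)
    occupancy = {
        t: {geography.regions[i] for i in r} for t, r in tip_ranges.items()
    }
    pairs: dict[tuple[str, str], set[str]] = {}
    hybrids: dict[tuple[str, str], set[str]] = {}
    taxa = sorted(occupancy)
    for ai, a in enumerate(taxa):
        for b in taxa[ai + 1:]:
            shared = occupancy[a] & occupancy[b]
            for island in sorted(shared):
                p = (co_prob_by_island or {}).get(island, co_prob)
                if rng.random() < p:
                    pairs.setdefault((a, b), set()).add(island)
                    if rng.random() < hybrid_prob:
                        hybrids.setdefault((a, b), set()).add(island)
    return CooccurrenceData(occupancy=occupancy, pairs=pairs, hybrids=hybrids)
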