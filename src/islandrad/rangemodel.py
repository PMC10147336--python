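"""Time-stratified ancestral-range models: DEC, DIVALIKE, BAYAREALIKE (+J).

The geographic range of a lineage evolves in two modes:

* **Anagenetically** (along branches) as a continuous-time Markov chain on
  the subset state space: a range ``A`` gains an available region ``k`` at
  rate ``d * |A|`` (one dispersal opportunity per occupied source region)
  and loses an occupied region at rate ``e`` per region.  The empty range
  is absorbing.

* **Cladogenetically** (at nodes) by drawing a daughter-range pair from a
  family-specific event table.  The three families differ in which splits
  they allow for a widespread parent range ``A``:

  - DEC: subset sympatry (one daughter keeps ``A``, the other one region
    of ``A``) and vicariance with a singleton daughter;
  - DIVALIKE: vicariance with a singleton daughter only;
  - BAYAREALIKE: widespread sympatry only (both daughters keep ``A``).

  A single-region parent always splits into two copies of itself.  The +J
  variants add founder-event (jump) speciation: one daughter keeps ``A``
  while the other jumps into a single available region outside ``A``.
  Each non-founder event carries per-event weight ``(3 - j) / 3``, each
  founder event carries weight ``j``, and weights are normalised per
  parent range, so ``j = 0`` recovers the base family and larger ``j``
  shifts cladogenetic mass onto jumps.

Island emergence enters twice: gains into not-yet-emerged regions carry
rate zero in older strata, and conditional likelihood mass on states that
contain a not-yet-emerged region is zeroed whenever a branch crosses a
stratum boundary rootward.

Likelihoods are computed by Felsenstein pruning over the range state
space, with per-branch matrix exponentials split at stratum boundaries and
cladogenetic mixing at internal nodes; the root likelihood is the plain
sum of root conditional likelihoods over states (no estimated root
frequencies), which is recorded in fit metadata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .geoscape import Geography, StateSpace, TimeStrata, build_geography
from .trees import DatedTree

FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")


@dataclass(frozen=True)
class ModelSpec:
    """Cladogenetic model family, jump flag, and range-size cap."""

    family: str
    jump: bool = False
    max_range_size: int = 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.max_range_size < 1:
            raise ValueError("max_range_size must be >= 1")

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.jump else "")

    @property
    def n_free_params(self) -> int:
        return 3 if self.jump else 2


@dataclass(frozen=True)
class Params:
    """Rates of the range-evolution process.

    d : per-occupied-region dispersal (range-gain) rate, /myr
    e : per-occupied-region extirpation (range-loss) rate, /myr
    j : founder-event weight (dimensionless, 0 when the model has no jump)
    """

    d: float
    e: float
    j: float = 0.0

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("negative rates")
        if not (0.0 <= self.j <= 3.0):
            raise ValueError("j must lie in [0, 3]")


@dataclass
class FitResult:
    spec: ModelSpec
    mle: Params
    lnL: float
    k: int
    converged: bool = True
    AICc: float | None = None
    akaike_weight: float | None = None
    root_handling: str = "sum over states, equal weights"


# ---------------------------------------------------------------------------
# anagenetic generator
# ---------------------------------------------------------------------------

def anagenetic_generator(
    space: StateSpace,
    params: Params,
    available: frozenset[int],
) -> np.ndarray:
    """Dense CTMC generator over the range state space for one stratum.

    Off-diagonal entries: ``Q[A, A+k] = d * |A|`` for each available region
    ``k`` outside ``A`` with ``|A|+1 <= max_range_size``; ``Q[A, A-k] = e``
    for each ``k`` in ``A``.  Rows sum to zero; the null range (if present)
    is absorbing.
    """
    states = space.states
    n = len(states)
    Q = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(states)}
    for i, A in enumerate(states):
        if not A:
            continue  # null range is absorbing
        if len(A) < space.max_range_size:
            for k in available - A:
                j = idx.get(A | {k})
                if j is not None:
                    Q[i, j] = params.d * len(A)
        for k in A:
            j = idx.get(A - {k})
            if j is not None:
                Q[i, j] = params.e
        Q[i, i] = -Q[i].sum()
    return Q


# ---------------------------------------------------------------------------
# cladogenetic event table
# ---------------------------------------------------------------------------

def cladogenetic_event_table(
    spec: ModelSpec,
    params: Params,
    parent_range: frozenset[int],
    available: frozenset[int],
) -> list[tuple[frozenset[int], frozenset[int], float]]:
    """Daughter-range pairs and probabilities for one parent range.

    Returns ordered ``(left, right, probability)`` entries summing to 1;
    asymmetric events are emitted in both orientations with half their
    normalised weight.  Raises if no event is allowed (cannot happen for a
    non-null parent).
    """
    A = parent_range
    if not A:
        raise ValueError("cladogenesis from the null range is undefined")
    j = params.j if spec.jump else 0.0
    w_nonj = (3.0 - j) / 3.0

    # unordered event classes: (left, right, weight, symmetric?)
    events: list[tuple[frozenset[int], frozenset[int], float]] = []
    if len(A) == 1:
        events.append((A, A, w_nonj))  # narrow sympatry (copy)
    else:
        if spec.family == "DEC":
            for k in sorted(A):
                events.append((A, frozenset({k}), w_nonj))       # subset sympatry
                events.append((frozenset({k}), A - {k}, w_nonj))  # vicariance
        elif spec.family == "DIVALIKE":
            for k in sorted(A):
                events.append((frozenset({k}), A - {k}, w_nonj))
        elif spec.family == "BAYAREALIKE":
            events.append((A, A, w_nonj))  # widespread sympatry
    if spec.jump:
        for k in sorted(available - A):
            events.append((A, frozenset({k}), j))

    total = sum(w for _, _, w in events if w > 0)
    if total <= 0:
        # all weights zero (e.g. j undefined); fall back to uniform over classes
        total = float(len(events))
        events = [(l, r, 1.0) for l, r, _ in events]
    out: list[tuple[frozenset[int], frozenset[int], float]] = []
    for left, right, w in events:
        if w <= 0:
            continue
        p = w / total
        if left == right:
            out.append((left, right, p))
        else:
            out.append((left, right, p / 2.0))
            out.append((right, left, p / 2.0))
    return out


class _CladoCache:
    """Per-stratum cladogenetic tables in index form."""

    def __init__(self, space: StateSpace, spec: ModelSpec, params: Params,
                 strata: TimeStrata):
        self.space = space
        self.spec = spec
        self.params = params
        self.strata = strata
        self._cache: dict[tuple[int, int], list[tuple[int, int, float]]] = {}

    def table(self, stratum: int, parent_index: int):
        key = (stratum, parent_index)
        if key not in self._cache:
            A = self.space.states[parent_index]
            rows = cladogenetic_event_table(
                self.spec, self.params, A, self.strata.masks[stratum]
            )
            self._cache[key] = [
                (self.space.index_of(l), self.space.index_of(r), p)
                for l, r, p in rows
            ]
        return self._cache[key]


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _valid_state_mask(space: StateSpace, available: frozenset[int]) -> np.ndarray:
    """1.0 for states whose regions were all emerged, else 0.0 (null valid)."""
    return np.array(
        [1.0 if s <= available else 0.0 for s in space.states]
    )


class RangeModel:
    """Bound model: spec + geography + strata + state space.

    Caches per-stratum generators and validity masks; the cladogenetic
    cache is per-parameter and rebuilt on each likelihood call.
    """

    def __init__(
        self,
        spec: ModelSpec,
        geography: Geography,
        strata: TimeStrata | None = None,
    ):
        if strata is None:
            _, strata = build_geography(geography.regions, geography.emergence_age)
        self.spec = spec
        self.geography = geography
        self.strata = strata
        self.space = StateSpace(geography, spec.max_range_size, include_null=True)
        self._valid = [
            _valid_state_mask(self.space, m) for m in strata.masks
        ]

    # -- tip data ----------------------------------------------------------

    def tip_vector(self, tip_range: frozenset[int]) -> np.ndarray:
        if not tip_range:
            raise ValueError("tips cannot have the null range")
        v = np.zeros(self.space.n_states)
        try:
            v[self.space.index_of(frozenset(tip_range))] = 1.0
        except KeyError:
            raise ValueError(
                f"tip range of size {len(tip_range)} exceeds the state space "
                f"(max_range_size={self.spec.max_range_size})"
            ) from None
        return v

    def encode_tip_ranges(
        self, tree: DatedTree, tip_ranges: dict[str, frozenset[int]]
    ) -> dict[int, np.ndarray]:
        missing = [t for t in tree.tip_labels() if t not in tip_ranges]
        if missing:
            raise ValueError(f"tip labels without range data: {missing}")
        out = {}
        for tip in tree.tips:
            rng = frozenset(tip_ranges[tree.label[tip]])
            avail0 = self.strata.masks[-1]
            if not rng <= avail0:
                raise ValueError(
                    f"tip {tree.label[tip]!r} occupies a region not emerged "
                    "at the present"
                )
            out[tip] = self.tip_vector(rng)
        return out

    # -- propagation -------------------------------------------------------

    def _generators(self, params: Params) -> list[np.ndarray]:
        return [
            anagenetic_generator(self.space, params, m) for m in self.strata.masks
        ]

    def _propagate_branch(
        self,
        v: np.ndarray,
        parent_age: float,
        child_age: float,
        Qs: list[np.ndarray],
    ) -> np.ndarray:
        """Carry a conditional-likelihood vector from a child node to the
        bottom of its parent node, masking emergence-invalid states at each
        rootward stratum crossing."""
        segments = self.strata.segment_branch(parent_age, child_age)
        for i, (stratum, dt) in enumerate(reversed(segments)):
            if i > 0:
                v = v * self._valid[stratum]
            if dt > 0:
                v = expm(Qs[stratum] * dt) @ v
                np.maximum(v, 0.0, out=v)
        return v

    # -- likelihood --------------------------------------------------------

    def log_likelihood(
        self,
        tree: DatedTree,
        tip_ranges: dict[str, frozenset[int]],
        params: Params,
        return_partials: bool = False,
    ):
        """Natural-log pruning likelihood of the tip ranges.

        With ``return_partials`` the per-node downpass vectors (after
        cladogenetic combination, before the parent branch) and the
        branch-top vectors are returned for use by stochastic mapping.
        """
        tips = self.encode_tip_ranges(tree, tip_ranges)
        Qs = self._generators(params)
        clado = _CladoCache(self.space, self.spec, params, self.strata)

        down: dict[int, np.ndarray] = {}       # at node, below-node data
        branch_top: dict[int, np.ndarray] = {}  # propagated to parent's age
        log_scale = 0.0
        for node in tree.postorder():
            if not tree.children[node]:
                v = tips[node].copy()
            else:
                l, r = tree.children[node]
                stratum = self.strata.stratum_at(tree.age[node])
                vl, vr = branch_top[l], branch_top[r]
                v = np.zeros(self.space.n_states)
                for a in range(self.space.n_states):
                    if not self.space.states[a]:
                        continue
                    acc = 0.0
                    for il, ir, p in clado.table(stratum, a):
                        acc += p * vl[il] * vr[ir]
                    v[a] = acc
                v *= self._valid[stratum]
            m = v.max()
            if m <= 0:
                return (-np.inf, None) if return_partials else -np.inf
            v = v / m
            log_scale += math.log(m)
            down[node] = v
            p = tree.parent[node]
            if p is not None:
                branch_top[node] = self._propagate_branch(
                    v, tree.age[p], tree.age[node], Qs
                )

        root = tree.root
        total = down[root].sum()
        lnL = math.log(total) + log_scale
        if return_partials:
            return lnL, {
                "down": down,
                "branch_top": branch_top,
                "generators": Qs,
                "clado": clado,
            }
        return lnL


def log_likelihood(
    tree: DatedTree,
    tip_ranges: dict[str, frozenset[int]],
    spec: ModelSpec,
    params: Params,
    geography: Geography,
    strata: TimeStrata | None = None,
) -> float:
    """Functional wrapper over :class:`RangeModel`."""
    return RangeModel(spec, geography, strata).log_likelihood(
        tree, tip_ranges, params
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

#: fixed multi-start grid (d, e, j-if-used); seedless and deterministic
_STARTS = (
    (0.01, 0.01, 0.01),
    (0.1, 0.1, 0.1),
    (0.5, 0.5, 0.5),
    (0.01, 0.1, 0.02),
    (0.1, 0.01, 0.2),
)

_RATE_BOUNDS = (1e-9, 5.0)
_J_BOUNDS = (0.0, 3.0)


def fit_model(
    tree: DatedTree,
    tip_ranges: dict[str, frozenset[int]],
    spec: ModelSpec,
    geography: Geography,
    strata: TimeStrata | None = None,
    starts=_STARTS,
    n_starts: int | None = None,
) -> FitResult:
    """Maximum-likelihood rates for one model on one dataset.

    Bounded quasi-Newton (L-BFGS-B) over ``log d``, ``log e`` (and ``j``
    for +J models) from a fixed multi-start grid; deterministic.
    """
    model = RangeModel(spec, geography, strata)
    lo, hi = math.log(_RATE_BOUNDS[0]), math.log(_RATE_BOUNDS[1])
    bounds = [(lo, hi), (lo, hi)]
    if spec.jump:
        bounds.append(_J_BOUNDS)

    def unpack(x) -> Params:
        j = float(x[2]) if spec.jump else 0.0
        return Params(d=math.exp(x[0]), e=math.exp(x[1]), j=min(max(j, 0.0), 3.0))

    def nll(x) -> float:
        val = model.log_likelihood(tree, tip_ranges, unpack(x))
        return 1e10 if not np.isfinite(val) else -val

    best = None
    use = starts if n_starts is None else starts[:n_starts]
    for s in use:
        x0 = [math.log(s[0]), math.log(s[1])]
        if spec.jump:
            x0.append(s[2])
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    return FitResult(
        spec=spec,
        mle=params,
        lnL=-best.fun,
        k=spec.n_free_params,
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalised relative likelihoods exp(-dAICc/2) of a compared set."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_selection_table(fits: list[FitResult], n_for_aicc: int) -> pd.DataFrame:
    """AICc model-comparison table (model, LnL, d, e, j, AICc, AICc_wt)."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    rows = []
    for f in fits:
        f.AICc = aicc(f.lnL, f.k, n_for_aicc)
        rows.append(
            {
                "model": f.spec.name,
                "LnL": f.lnL,
                "d": f.mle.d,
                "e": f.mle.e,
                "j": f.mle.j if f.spec.jump else 0.0,
                "k": f.k,
                "AICc": f.AICc,
            }
        )
    table = pd.DataFrame(rows)
    table["AICc_wt"] = akaike_weights(table["AICc"].to_numpy())
    for f, w in zip(fits, table["AICc_wt"]):
        f.akaike_weight = float(w)
    return table


def standard_model_set(max_range_size: int, families=FAMILIES) -> list[ModelSpec]:
    """The six-model comparison set: each family with and without +J."""
    specs = []
    for fam in families:
        specs.append(ModelSpec(fam, jump=False, max_range_size=max_range_size))
        specs.append(ModelSpec(fam, jump=True, max_range_size=max_range_size))
    return specs
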