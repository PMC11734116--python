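"""Discrete Bayesian networks: representation, validation, exact inference, sampling.

A network is a directed acyclic graph over named variables with ordered
discrete states.  Random variables carry a conditional probability table
(CPT); decision variables carry none and must either be fixed as evidence or
be given an explicit prior before inference.  Exact inference uses variable
elimination with a min-fill ordering (lexicographic tie-break), which is
deterministic and adequate at the treewidths of risk-assessment networks of
this kind.  A brute-force joint enumeration is provided as an independent
oracle for testing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

PROB_TOL = 1e-9          # vectors must sum to 1 within this
RENORM_TOL = 1e-6        # columns off by <= this are renormalized with a warning
ENUMERATION_LIMIT = 10**6

ROLES = ("decision", "random")
TIERS = ("operational", "pressure", "environment", "biota")
CONFIDENCE_LEVELS = ("low", "moderate", "high", "unrated")


class BNError(Exception):
    """Base class for network errors."""


class IncompleteAssignmentError(BNError):
    pass


class ZeroProbabilityEvidenceError(BNError):
    pass


class MissingDecisionError(BNError):
    """A decision variable was neither observed nor given a prior."""


class StateSpaceTooLargeError(BNError):
    pass


class DegenerateWeightsError(BNError):
    pass


@dataclass(frozen=True)
class Variable:
    """A named model quantity with ordered discrete states.

    ``role`` distinguishes random variables (which carry a CPT) from decision
    variables (controlled by the operator, set as evidence).  ``tier`` and
    ``confidence`` are metadata carried through to outputs.  State order is
    meaningful: unless ``nominal`` is set, states are read as an ordinal scale.
    """

    name: str
    states: tuple[str, ...]
    role: str = "random"
    tier: str = "operational"
    confidence: str = "unrated"
    nominal: bool = False

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate states")
        if self.role not in ROLES:
            raise ValueError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.tier not in TIERS:
            raise ValueError(f"variable {self.name!r}: unknown tier {self.tier!r}")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(
                f"variable {self.name!r}: unknown confidence {self.confidence!r}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"{state!r} is not a state of {self.name!r}") from None


@dataclass
class Cpt:
    """Conditional probability table P(child | parents).

    ``table`` has shape ``(prod of parent cardinalities, n_child_states)``,
    rows in row-major (itertools.product) order over the parents' state lists.
    Root nodes have a single row (the prior).
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2:
            raise ValueError(f"CPT for {self.child!r}: table must be 2-D")

    def column(self, parent_states: dict[str, str], net: "Network") -> np.ndarray:
        """Probability vector over child states for one parent configuration."""
        idx = 0
        for p in self.parents:
            v = net.variables[p]
            idx = idx * v.n_states + v.index_of(parent_states[p])
        return self.table[idx]


@dataclass
class Network:
    """A discrete Bayesian network.

    ``cpts`` maps each random variable to its CPT.  ``decision_priors`` may
    supply a prior over a decision variable (degenerate or otherwise) so it can
    participate in queries or sampling without being observed.
    """

    variables: dict[str, Variable]
    cpts: dict[str, Cpt]
    decision_priors: dict[str, np.ndarray] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        for cpt in self.cpts.values():
            out.extend((p, cpt.child) for p in cpt.parents)
        return out

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def parents(self, name: str) -> tuple[str, ...]:
        cpt = self.cpts.get(name)
        return cpt.parents if cpt is not None else ()

    def roots(self) -> list[str]:
        g = self.graph()
        return [v for v in self.variables if g.in_degree(v) == 0]

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    # -- factors -----------------------------------------------------------

    def _cpt_factor(self, cpt: Cpt) -> "Factor":
        scope = cpt.parents + (cpt.child,)
        shape = tuple(self.variables[v].n_states for v in scope)
        return Factor(scope, cpt.table.reshape(shape))

    def _all_factors(self, evidence: dict[str, str] | None) -> list["Factor"]:
        evidence = evidence or {}
        factors = [self._cpt_factor(c) for c in self.cpts.values()]
        for name, var in self.variables.items():
            if var.role != "decision":
                continue
            if name in evidence:
                continue
            prior = self.decision_priors.get(name)
            if prior is None:
                raise MissingDecisionError(
                    f"decision variable {name!r} must be observed or given a prior"
                )
            factors.append(Factor((name,), np.asarray(prior, dtype=float)))
        return factors


@dataclass
class Factor:
    """A nonnegative table over the joint states of an ordered variable scope."""

    scope: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.scope = tuple(self.scope)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.scope):
            raise ValueError("factor dimension mismatch")

    def restrict(self, var: str, index: int) -> "Factor":
        if var not in self.scope:
            return self
        axis = self.scope.index(var)
        vals = np.take(self.values, index, axis=axis)
        scope = tuple(v for v in self.scope if v != var)
        return Factor(scope, vals)

    def multiply(self, other: "Factor") -> "Factor":
        scope = self.scope + tuple(v for v in other.scope if v not in self.scope)
        a = _broadcast(self, scope)
        b = _broadcast(other, scope)
        return Factor(scope, a * b)

    def sum_out(self, var: str) -> "Factor":
        axis = self.scope.index(var)
        scope = tuple(v for v in self.scope if v != var)
        return Factor(scope, self.values.sum(axis=axis))

    def marginal(self, var: str) -> np.ndarray:
        axes = tuple(i for i, v in enumerate(self.scope) if v != var)
        return self.values.sum(axis=axes)


def _broadcast(f: Factor, scope: tuple[str, ...]) -> np.ndarray:
    """Expand a factor's value array to the axis order of ``scope``."""
    full = f.values
    axes = list(f.scope)
    for v in scope:
        if v not in axes:
            full = np.expand_dims(full, axis=full.ndim)
            axes.append(v)
    return np.transpose(full, [axes.index(v) for v in scope])


# ---------------------------------------------------------------------------
# validation


def validate_network(net: Network) -> list[str]:
    """Return a list of invariant violations (empty list means the net is valid).

    Checks: CPT coverage and normalization, parent declarations, edge/CPT
    consistency, role constraints, and acyclicity.  CPT columns off by no more
    than ``RENORM_TOL`` are renormalized in place with a logged warning rather
    than reported.
    """
    problems: list[str] = []

    for name, var in net.variables.items():
        if var.role == "decision" and name in net.cpts:
            problems.append(f"decision variable {name!r} carries a CPT")
    for name, var in net.variables.items():
        if var.role == "random" and name not in net.cpts:
            problems.append(f"random variable {name!r} has no CPT")

    for child, cpt in net.cpts.items():
        if child != cpt.child:
            problems.append(f"CPT keyed {child!r} declares child {cpt.child!r}")
            continue
        if child not in net.variables:
            problems.append(f"CPT child {child!r} is not a declared variable")
            continue
        missing = [p for p in cpt.parents if p not in net.variables]
        if missing:
            problems.append(f"CPT for {child!r}: unknown parents {missing}")
            continue
        n_rows = int(np.prod([net.variables[p].n_states for p in cpt.parents]))
        n_cols = net.variables[child].n_states
        if cpt.table.shape != (n_rows, n_cols):
            problems.append(
                f"CPT for {child!r}: shape {cpt.table.shape} != ({n_rows}, {n_cols})"
            )
            continue
        if np.any(cpt.table < 0):
            problems.append(f"CPT for {child!r}: negative probabilities")
            continue
        sums = cpt.table.sum(axis=1)
        bad = np.abs(sums - 1.0) > PROB_TOL
        if np.any(bad):
            fixable = np.abs(sums - 1.0) <= RENORM_TOL
            if np.all(~bad | fixable):
                logger.warning(
                    "CPT for %r: %d column(s) off by <=%.0e, renormalized",
                    child, int(np.sum(bad)), RENORM_TOL,
                )
                cpt.table = cpt.table / sums[:, None]
            else:
                worst = float(np.max(np.abs(sums - 1.0)))
                problems.append(
                    f"CPT for {child!r}: columns do not sum to 1 (worst off by {worst:.3g})"
                )

    g = net.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        problems.append(f"network contains a cycle: {cycle}")

    return problems


# ---------------------------------------------------------------------------
# joint probability and enumeration oracle


def joint_probability(net: Network, assignment: dict[str, str]) -> float:
    """Probability of a full assignment: product of CPT entries.

    Decision variables are treated as conditioned constants (they contribute
    no factor but must be present in the assignment).
    """
    missing = set(net.variables) - set(assignment)
    if missing:
        raise IncompleteAssignmentError(
            f"assignment missing variables: {sorted(missing)}"
        )
    p = 1.0
    for name, cpt in net.cpts.items():
        col = cpt.column(assignment, net)
        p *= float(col[net.variables[name].index_of(assignment[name])])
    return p


def enumerate_joint(net: Network, order: list[str] | None = None) -> Factor:
    """Full joint table over all variables; brute-force test oracle.

    Decision variables require a prior in ``net.decision_priors``.  Guarded:
    refuses joint state spaces larger than ``ENUMERATION_LIMIT``.
    """
    order = order or sorted(net.variables)
    size = int(np.prod([net.variables[v].n_states for v in order]))
    if size > ENUMERATION_LIMIT:
        raise StateSpaceTooLargeError(
            f"joint state space has {size} cells (> {ENUMERATION_LIMIT})"
        )
    shape = tuple(net.variables[v].n_states for v in order)
    priors = {
        name: np.asarray(p, dtype=float) for name, p in net.decision_priors.items()
    }
    for name, var in net.variables.items():
        if var.role == "decision" and name not in priors:
            raise MissingDecisionError(
                f"decision variable {name!r} needs a prior for enumeration"
            )
    # full tensor product of all CPTs (and decision priors), one broadcastable
    # term at a time -- deliberately not the elimination machinery
    values = np.ones(shape)
    terms = [
        (cpt.parents + (cpt.child,), cpt.table) for cpt in net.cpts.values()
    ] + [((name,), p) for name, p in priors.items()]
    for scope, table in terms:
        t = np.asarray(table).reshape([net.variables[v].n_states for v in scope])
        expanded_scope = list(scope)
        for v in order:
            if v not in expanded_scope:
                t = np.expand_dims(t, axis=t.ndim)
                expanded_scope.append(v)
        values = values * np.transpose(t, [expanded_scope.index(v) for v in order])
    return Factor(tuple(order), values)


# ---------------------------------------------------------------------------
# variable elimination


def _min_fill_order(
    net: Network, factors: list[Factor], eliminate: set[str]
) -> list[str]:
    """Min-fill elimination order with lexicographic tie-break."""
    # adjacency over the interaction graph of current factor scopes
    adj: dict[str, set[str]] = {}
    for f in factors:
        s = set(f.scope)
        for v in s:
            adj.setdefault(v, set()).update(s - {v})
    order = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = sorted(adj.get(v, ()))
            fill = sum(
                1 for a, b in itertools.combinations(nbrs, 2)
                if b not in adj.get(a, set())
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        nbrs = list(adj.get(best, ()))
        for a, b in itertools.combinations(nbrs, 2):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for u in nbrs:
            adj[u].discard(best)
        adj.pop(best, None)
        order.append(best)
        remaining.discard(best)
    return order


def _check_evidence(net: Network, evidence: dict[str, str]) -> None:
    for name, state in evidence.items():
        if name not in net.variables:
            raise KeyError(f"evidence names unknown variable {name!r}")
        net.variables[name].index_of(state)  # raises on bad state


def query(
    net: Network,
    targets: list[str],
    evidence: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Exact conditional marginals P(target | evidence) for each target.

    Variable elimination with min-fill ordering; normalization is applied once
    at the end.  Raises :class:`ZeroProbabilityEvidenceError` if the evidence
    has probability zero under the model.
    """
    evidence = dict(evidence or {})
    _check_evidence(net, evidence)
    overlap = set(targets) & set(evidence)
    if overlap:
        raise ValueError(f"targets overlap evidence: {sorted(overlap)}")

    factors = net._all_factors(evidence)
    for name, state in evidence.items():
        idx = net.variables[name].index_of(state)
        factors = [f.restrict(name, idx) for f in factors]
        factors = [f for f in factors if f.scope or f.values.size]

    keep = set(targets)
    eliminate = {
        v for f in factors for v in f.scope if v not in keep
    }
    order = _min_fill_order(net, factors, eliminate)
    for v in order:
        involved = [f for f in factors if v in f.scope]
        rest = [f for f in factors if v not in f.scope]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(v)]

    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    total = float(result.values.sum())
    if total <= 0.0:
        raise ZeroProbabilityEvidenceError(
            f"evidence {evidence} has probability 0 under the model"
        )
    posterior = {}
    for t in targets:
        if t in result.scope:
            marg = result.marginal(t)
        else:  # target disconnected from all factors (cannot normally happen)
            marg = np.ones(net.variables[t].n_states)
        posterior[t] = marg / marg.sum()
    return posterior


def posterior_all(
    net: Network, evidence: dict[str, str] | None = None
) -> dict[str, np.ndarray]:
    """Posterior marginals of every non-evidence variable given the evidence."""
    evidence = dict(evidence or {})
    _check_evidence(net, evidence)
    targets = [v for v in net.variables if v not in evidence]
    out: dict[str, np.ndarray] = {}
    for t in targets:
        out.update(query(net, [t], evidence))
    return out


# ---------------------------------------------------------------------------
# forward (ancestral) sampling


def forward_sample(
    net: Network,
    n: int,
    seed: int,
    evidence: dict[str, str] | None = None,
) -> "pd.DataFrame":
    """Draw ``n`` full assignments by ancestral sampling in topological order.

    Evidence variables are clamped (the mutilated network is sampled); with
    evidence only on root/decision variables this is exact conditional
    sampling.  Decision variables must be clamped or have a degenerate prior.
    """
    import pandas as pd

    evidence = dict(evidence or {})
    _check_evidence(net, evidence)
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    n = int(n)
    cols: dict[str, np.ndarray] = {}
    idx: dict[str, np.ndarray] = {}
    for name in order:
        var = net.variables[name]
        if name in evidence:
            k = var.index_of(evidence[name])
            idx[name] = np.full(n, k, dtype=int)
        elif var.role == "decision" or name not in net.cpts:
            prior = net.decision_priors.get(name)
            if prior is None:
                raise MissingDecisionError(
                    f"decision variable {name!r} must be fixed by evidence "
                    "or have a prior for sampling"
                )
            prior = np.asarray(prior, dtype=float)
            idx[name] = rng.choice(var.n_states, size=n, p=prior / prior.sum())
        else:
            cpt = net.cpts[name]
            if not cpt.parents:
                idx[name] = rng.choice(var.n_states, size=n, p=cpt.table[0])
            else:
                row = np.zeros(n, dtype=int)
                for p in cpt.parents:
                    row = row * net.variables[p].n_states + idx[p]
                u = rng.random(n)
                cdf = np.cumsum(cpt.table, axis=1)
                idx[name] = (u[:, None] > cdf[row]).sum(axis=1)
        cols[name] = np.asarray(var.states, dtype=object)[idx[name]] if n else np.array([], dtype=object)
    return pd.DataFrame(cols, columns=list(net.variables))
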