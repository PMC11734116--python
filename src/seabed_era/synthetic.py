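"""Synthetic inputs with the statistical structure the analysis assumes.

Two families of generators:

* random small networks (random DAG + Dirichlet CPTs) used to exercise the
  exact-inference machinery against the brute-force enumeration oracle;
* before/after benthic abundance surveys — overdispersed (negative-binomial)
  core counts for control and impacted sites with a group-specific true
  relative decrease — from which bootstrap samples of the relative decrease
  are drawn and an empirical "best case" beta distribution is fitted.

All generators are deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn import Cpt, Network, Variable

logger = logging.getLogger(__name__)


def random_dag(n_nodes: int, max_parents: int, seed: int) -> list[tuple[str, str]]:
    """Random DAG over nodes v0..v{n-1}; acyclic by construction.

    Nodes are placed in a random order and each node draws up to
    ``max_parents`` parents uniformly from its predecessors in that order.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    edges: list[tuple[str, str]] = []
    for pos, child in enumerate(order):
        if pos == 0 or max_parents == 0:
            continue
        k = int(rng.integers(0, min(max_parents, pos) + 1))
        if k:
            parents = rng.choice(order[:pos], size=k, replace=False)
            edges.extend((str(p), child) for p in parents)
    return edges


def random_cpts(
    dag: list[tuple[str, str]],
    n_states: int,
    concentration: float,
    seed: int,
    n_nodes: int | None = None,
) -> Network:
    """Network over a DAG with CPT columns drawn from a symmetric Dirichlet."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    nodes = sorted({v for e in dag for v in e})
    if n_nodes is not None:
        nodes = sorted(set(nodes) | {f"v{i}" for i in range(n_nodes)})
    parents: dict[str, list[str]] = {v: [] for v in nodes}
    for p, c in dag:
        parents[c].append(p)
    states = tuple(f"s{i}" for i in range(n_states))
    variables = {v: Variable(v, states, role="random", tier="operational") for v in nodes}
    cpts = {}
    for v in nodes:
        ps = tuple(sorted(parents[v]))
        n_rows = n_states ** len(ps)
        table = rng.dirichlet([concentration] * n_states, size=n_rows)
        cpts[v] = Cpt(child=v, parents=ps, table=table)
    return Network(variables=variables, cpts=cpts)


@dataclass(frozen=True)
class SurveySpec:
    """Design of a synthetic before/after multicore abundance survey.

    ``mean_density`` is individuals per core in the undisturbed (control)
    arm per functional group; ``dispersion`` is the negative-binomial size
    parameter (smaller = patchier); ``true_decrease`` is the relative
    reduction of mean density at impacted sites.
    """

    n_cores_control: int
    n_cores_impact: int
    mean_density: dict[str, float]
    dispersion: float
    true_decrease: dict[str, float]
    seed: int = 0

    def __post_init__(self):
        if self.n_cores_control < 3 or self.n_cores_impact < 3:
            raise ValueError("need at least 3 cores per arm")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for g, d in self.true_decrease.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"true_decrease[{g!r}] must be in [0, 1]")
        if set(self.mean_density) != set(self.true_decrease):
            raise ValueError("mean_density and true_decrease must cover the same groups")


def _nb_draw(rng, mean: float, size_param: float, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_survey(spec: SurveySpec) -> pd.DataFrame:
    """Per-core counts per group for the control and impact arms.

    Counts are negative binomial with the spec's mean (scaled by
    1 - true_decrease in the impact arm) and dispersion; deterministic per
    seed.  Columns: group, arm, core, count.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in sorted(spec.mean_density):
        mu = spec.mean_density[group]
        dec = spec.true_decrease[group]
        control = _nb_draw(rng, mu, spec.dispersion, spec.n_cores_control)
        impact = _nb_draw(rng, mu * (1.0 - dec), spec.dispersion, spec.n_cores_impact)
        rows.extend(
            dict(group=group, arm="control", core=i, count=int(c))
            for i, c in enumerate(control)
        )
        rows.extend(
            dict(group=group, arm="impact", core=i, count=int(c))
            for i, c in enumerate(impact)
        )
    return pd.DataFrame(rows)


def decrease_samples(
    survey: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> dict[str, np.ndarray]:
    """Bootstrap samples of the relative decrease in abundance per group.

    Cores are resampled with replacement within each arm; each replicate's
    decrease is clip(1 - mean_impact / mean_control, 0, 1).  Replicates whose
    control resample has zero mean are dropped (and logged).
    """
    out: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for group, sub in survey.groupby("group", sort=True):
        control = sub.loc[sub["arm"] == "control", "count"].to_numpy()
        impact = sub.loc[sub["arm"] == "impact", "count"].to_numpy()
        if len(control) < 3 or len(impact) < 3:
            raise ValueError(f"group {group!r}: need >=3 cores per arm")
        ci = rng.integers(0, len(control), size=(n_boot, len(control)))
        ii = rng.integers(0, len(impact), size=(n_boot, len(impact)))
        mc = control[ci].mean(axis=1)
        mi = impact[ii].mean(axis=1)
        ok = mc > 0
        dropped = int(np.sum(~ok))
        if dropped:
            logger.info(
                "decrease_samples: dropped %d replicate(s) with zero control mean "
                "for group %r", dropped, group,
            )
        out[str(group)] = np.clip(1.0 - mi[ok] / mc[ok], 0.0, 1.0)
    return out
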