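"""Synthetic gene-regulatory networks and expression data.

Generates (i) known directed acyclic regulatory topologies, (ii) expression
matrices simulated from them with a structural-equation model, and (iii)
bivariate fixtures with prescribed functional shapes for measure unit
tests.  This is a deliberately simple, seed-reproducible stand-in for
community-benchmark generators (which integrate ODE kinetics): an acyclic
SEM with configurable link functions and Gaussian noise is sufficient to
rank association measures against a known edge set.

Presets ``dream10`` / ``dream50`` / ``dream100`` mirror the three benchmark
network sizes (10, 50, 100 genes with 4, 23 and 46 replicate datasets
respectively) at matched graph density: every size uses the 10-node
preset's edge probability 10/C(10,2), so a 10-gene network expects 10
edges (within the 10-25 edge range of the 10-node benchmark gold
standards) and larger networks are proportionally harder to infer, with
100 samples, linear links and noise standard deviation 0.3 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .errors import AssocnetError, ParameterError
from .evaluation import GoldStandard
from .netinfer import ExpressionMatrix

__all__ = [
    "NetworkSpec",
    "SimulationParams",
    "PRESETS",
    "generate_topology",
    "simulate_expression",
    "bivariate_fixture",
]

_LINKS = {
    "linear": lambda u: u,
    "sigmoid": np.tanh,
    "quadratic": lambda u: u**2,
}


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for a random directed acyclic regulatory topology."""

    n_genes: int
    topology: str = "erdos_renyi"  # or "scale_free"
    expected_edges: float | None = None  # default n_genes (avg total degree 2)
    attachment: int = 2  # parents per new node (scale_free)
    seed: int = 0


@dataclass(frozen=True)
class SimulationParams:
    """Structural-equation simulation settings."""

    n_samples: int = 100
    link: str = "linear"
    weight_range: tuple[float, float] = (0.5, 1.5)  # |weight| bounds
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        lo, hi = self.weight_range
        if not 0 < lo <= hi:
            raise ParameterError("weight magnitudes must be bounded away from 0")
        if self.link not in _LINKS:
            raise ParameterError(
                f"unknown link {self.link!r}; known: {', '.join(_LINKS)}"
            )


@dataclass(frozen=True)
class Preset:
    """A benchmark scenario: topology spec, simulation params, replicates."""

    spec: NetworkSpec
    params: SimulationParams
    replicates: int


# the three benchmark sizes share the 10-node preset's graph density
# (edge probability 10 / C(10,2)), so inference difficulty grows with size
_PRESET_EDGE_PROB = 10 / 45


def _preset(n_genes: int, replicates: int) -> Preset:
    expected = _PRESET_EDGE_PROB * n_genes * (n_genes - 1) / 2
    return Preset(
        spec=NetworkSpec(n_genes=n_genes, expected_edges=expected),
        params=SimulationParams(),
        replicates=replicates,
    )


PRESETS: dict[str, Preset] = {
    "dream10": _preset(10, 4),
    "dream50": _preset(50, 23),
    "dream100": _preset(100, 46),
}


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_topology(spec: NetworkSpec) -> GoldStandard:
    """Draw a random DAG of regulations; reproducible under a fixed seed.

    ``erdos_renyi``: a uniformly random topological order, each forward pair
    wired independently with probability expected_edges / C(n, 2).
    ``scale_free``: genes arrive in random order; each new gene picks
    `attachment` regulators among earlier genes with probability
    proportional to (out-degree + 1), producing hub regulators.  Both
    constructions only add edges from earlier to later genes, so the graph
    is acyclic with no self-loops.
    """
    n = spec.n_genes
    if n < 2:
        raise ParameterError("need at least 2 genes")
    rng = np.random.default_rng(spec.seed)
    ids = _gene_ids(n)
    order = rng.permutation(n)
    edges: set[tuple[str, str]] = set()
    if spec.topology == "erdos_renyi":
        expected = float(n) if spec.expected_edges is None else spec.expected_edges
        p = expected / (n * (n - 1) / 2)
        if not 0 < p <= 1:
            raise ParameterError(f"expected_edges {expected} gives edge prob {p}")
        for a in range(n):
            for b in range(a + 1, n):
                if rng.random() < p:
                    edges.add((ids[order[a]], ids[order[b]]))
    elif spec.topology == "scale_free":
        out_deg = np.zeros(n)
        for b in range(1, n):
            k = min(spec.attachment, b)
            weights = out_deg[order[:b]] + 1.0
            parents = rng.choice(b, size=k, replace=False, p=weights / weights.sum())
            for a in parents:
                edges.add((ids[order[a]], ids[order[b]]))
                out_deg[order[a]] += 1
    else:
        raise ParameterError(f"unknown topology {spec.topology!r}")
    if not edges:
        raise AssocnetError(
            "generated topology has no edges; increase expected_edges"
        )
    return GoldStandard(universe=frozenset(ids), positives=frozenset(edges))


def simulate_expression(
    gold: GoldStandard, params: SimulationParams
) -> ExpressionMatrix:
    """Simulate expression from a regulatory DAG by a structural equation model.

    Genes are evaluated in topological order: source genes are standard
    normal; a regulated gene is link(sum_k w_k * parent_k), with the
    regulator sum standardised to unit sample scale before the link so that
    noise_sd is comparable across in-degrees, plus Gaussian noise of
    standard deviation noise_sd.  Weights have magnitude uniform in
    weight_range with random sign.  Reproducible under a fixed seed.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(gold.universe)
    graph.add_edges_from(gold.positives)
    if not nx.is_directed_acyclic_graph(graph):
        raise AssocnetError("regulatory graph contains a cycle")
    rng = np.random.default_rng(params.seed)
    link = _LINKS[params.link]
    lo, hi = params.weight_range
    n = params.n_samples
    values: dict[str, np.ndarray] = {}
    for gene in nx.lexicographical_topological_sort(graph):
        parents = sorted(graph.predecessors(gene))
        if not parents:
            values[gene] = rng.standard_normal(n)
            continue
        w = rng.uniform(lo, hi, size=len(parents)) * rng.choice([-1.0, 1.0],
                                                                size=len(parents))
        u = np.sum([wk * values[p] for wk, p in zip(w, parents)], axis=0)
        scale = u.std()
        if scale > 0:
            u = u / scale
        values[gene] = link(u) + params.noise_sd * rng.standard_normal(n)
    ids = sorted(gold.universe)
    mat = np.vstack([values[g] for g in ids])
    samples = tuple(f"S{j + 1}" for j in range(n))
    return ExpressionMatrix(gene_ids=tuple(ids), sample_ids=samples, values=mat)


_PATTERNS = {
    "linear": lambda x: x,
    "monotone_exp": np.exp,
    "quadratic": lambda x: x**2,
    "sinusoidal": lambda x: np.sin(2.0 * np.pi * x),
}


def bivariate_fixture(
    pattern: str, n: int = 500, noise_sd: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A single (x, y) pair with a prescribed functional shape.

    x ~ Uniform(-1, 1); y = pattern(x) + noise_sd * N(0, 1), or independent
    uniform noise for ``pattern="independent"``.  These fixtures ground the
    linear / monotone / non-linear claims of the measure catalogue: e.g. a
    noiseless quadratic has Pearson ~ 0 but high dCor / MI.
    """
    if n < 5:
        raise ParameterError("need n >= 5")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=n)
    if pattern == "independent":
        y = rng.uniform(-1.0, 1.0, size=n)
    else:
        try:
            f = _PATTERNS[pattern]
        except KeyError:
            raise ParameterError(
                f"unknown pattern {pattern!r}; known: "
                + ", ".join([*_PATTERNS, "independent"])
            ) from None
        y = f(x)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    return x, y


def replicate_params(params: SimulationParams, base_seed: int, index: int
                     ) -> SimulationParams:
    """Derive the simulation params of replicate `index` from a base seed."""
    child = int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
                % (2**31))
    return replace(params, seed=child)
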