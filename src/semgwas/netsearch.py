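"""Phenotypic causal-network discovery.

The structure among traits is learned from the posterior of the *residual*
covariance matrix of the multi-trait mixed model: conditioning on the
polygenic effects removes genetic confounding, so residual partial
correlations carry the trait-to-trait dependence signal.  For every trait
pair and conditioning set, the partial correlation is evaluated on each
stored Gibbs draw of Sigma_e; the pair is declared conditionally dependent
when the highest-posterior-density interval at the chosen coverage excludes
zero.  Those decisions drive the inductive-causation (IC) algorithm:
skeleton by conditional-independence queries over exhaustive conditioning
subsets, v-structure orientation, then the standard propagation rules.
Edges the IC output leaves undirected can be completed to a DAG with an
explicit causal order.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mtm import PosteriorDraws

logger = logging.getLogger(__name__)


class InconsistentOrientationError(RuntimeError):
    pass


@dataclass
class HPDInterval:
    lower: float
    upper: float
    coverage: float

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass
class CausalStructure:
    """Trait graph: undirected skeleton plus (partially) directed edges."""

    nodes: list[str]
    undirected: set[frozenset] = field(default_factory=set)
    directed: set[tuple] = field(default_factory=set)
    sepsets: dict = field(default_factory=dict)
    status: str = "pdag"
    lam: np.ndarray | None = None  # structural coefficients, filled by the SEM fit

    def skeleton(self) -> set[frozenset]:
        return self.undirected | {frozenset(e) for e in self.directed}

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.skeleton()

    def v_structures(self) -> set[tuple]:
        """Ordered triples (a, c, b), a < b, with a -> c <- b and a,b non-adjacent."""
        out = set()
        for (a, c1) in self.directed:
            for (b, c2) in self.directed:
                if c1 == c2 and a < b and not self.adjacent(a, b):
                    out.add((a, c1, b))
        return out

    def parents(self, node: str) -> list[str]:
        return sorted(a for (a, b) in self.directed if b == node)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_digraph())

    def edge_table(self) -> list[tuple]:
        rows = [(a, b, "directed") for (a, b) in sorted(self.directed)]
        rows += [tuple(sorted(e)) + ("undirected",) for e in sorted(
            self.undirected, key=sorted)]
        return rows

    def write(self, path, sidecar: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("from\tto\tstatus\n")
            for a, b, s in self.edge_table():
                fh.write(f"{a}\t{b}\t{s}\n")
        if sidecar is not None:
            meta = dict(sidecar)
            meta["sepsets"] = {f"{a}|{b}": sorted(h)
                               for (a, b), h in self.sepsets.items()}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# partial correlations and HPD decisions
# ---------------------------------------------------------------------------

def residual_partial_correlation(sigma: np.ndarray, pair: tuple[int, int],
                                 conditioning: tuple[int, ...] = ()) -> float:
    """Partial correlation of a trait pair given a conditioning set,
    computed from the precision of the covariance submatrix over
    {pair} + conditioning."""
    a, b = pair
    if a in conditioning or b in conditioning:
        raise ValueError("conditioning set must exclude the pair")
    idx = [a, b, *conditioning]
    sub = np.asarray(sigma, float)[np.ix_(idx, idx)]
    try:
        theta = np.linalg.inv(sub)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular covariance submatrix for traits {idx}") from err
    return float(-theta[0, 1] / math.sqrt(theta[0, 0] * theta[1, 1]))


def hpd_interval(samples, coverage: float) -> HPDInterval:
    """Shortest contiguous window of the sorted draws holding
    ceil(coverage * S) of them; ties resolved to the lowest start index."""
    x = np.sort(np.asarray(samples, float))
    s = len(x)
    if s < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    m = math.ceil(coverage * s)
    widths = x[m - 1:] - x[: s - m + 1]
    i = int(np.argmin(widths))
    return HPDInterval(float(x[i]), float(x[i + m - 1]), coverage)


def dependence_decision(samples, coverage: float) -> bool:
    """True (dependent) when zero lies outside the HPD interval."""
    return not hpd_interval(samples, coverage).contains(0.0)


def partial_correlation_draws(draws: PosteriorDraws, pair, conditioning=()):
    return np.array([residual_partial_correlation(s, pair, tuple(conditioning))
                     for s in draws.sigma_e])


# ---------------------------------------------------------------------------
# IC algorithm
# ---------------------------------------------------------------------------

def ic_algorithm(nodes: list[str], oracle) -> CausalStructure:
    """Inductive causation from a conditional-dependence oracle.

    ``oracle(a, b, cond)`` returns True when traits a and b are dependent
    given the conditioning tuple.  Stage 1 removes an edge as soon as some
    subset of the remaining nodes renders the pair independent (recording
    the separating set); stage 2 orients a -> c <- b for every non-adjacent
    pair whose separating set excludes c; stage 3 applies the three standard
    orientation-propagation rules to closure.  The output is a PDAG.
    """
    if len(nodes) > 10:
        raise ValueError("exhaustive subset search limited to <= 10 traits")
    struct = CausalStructure(list(nodes))
    struct.undirected = {frozenset(p) for p in itertools.combinations(nodes, 2)}

    for a, b in itertools.combinations(nodes, 2):
        others = [x for x in nodes if x not in (a, b)]
        for size in range(len(others) + 1):
            found = False
            for h in itertools.combinations(others, size):
                if not oracle(a, b, h):
                    struct.undirected.discard(frozenset((a, b)))
                    struct.sepsets[(a, b)] = set(h)
                    struct.sepsets[(b, a)] = set(h)
                    found = True
                    break
            if found:
                break

    _orient_v_structures(struct)
    _propagate_orientations(struct)
    struct.status = "pdag"
    return struct


def _force_direction(struct: CausalStructure, a: str, b: str, why: str) -> None:
    if (b, a) in struct.directed:
        raise InconsistentOrientationError(
            f"contradictory orientation {a}->{b} vs {b}->{a} ({why})")
    struct.undirected.discard(frozenset((a, b)))
    struct.directed.add((a, b))


def _orient_v_structures(struct: CausalStructure) -> None:
    for a, b in itertools.combinations(struct.nodes, 2):
        if struct.adjacent(a, b) or (a, b) not in struct.sepsets:
            continue
        for c in struct.nodes:
            if c in (a, b) or c in struct.sepsets[(a, b)]:
                continue
            if struct.adjacent(a, c) and struct.adjacent(b, c):
                _force_direction(struct, a, c, f"v-structure {a}->{c}<-{b}")
                _force_direction(struct, b, c, f"v-structure {a}->{c}<-{b}")


def _propagate_orientations(struct: CausalStructure) -> None:
    """Meek's closure rules: orient undirected edges whose reversal would
    either create a new v-structure or a directed cycle."""
    changed = True
    while changed:
        changed = False
        for e in list(struct.undirected):
            b, c = tuple(e)
            for x, y in ((b, c), (c, b)):
                # R1: a -> x, x - y, a and y non-adjacent  =>  x -> y
                if any((a, x) in struct.directed and not struct.adjacent(a, y)
                       and a != y for a in struct.nodes):
                    _force_direction(struct, x, y, "rule R1")
                    changed = True
                    break
                # R2: x -> z -> y and x - y  =>  x -> y (avoid a cycle)
                if any((x, z) in struct.directed and (z, y) in struct.directed
                       for z in struct.nodes):
                    _force_direction(struct, x, y, "rule R2")
                    changed = True
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1 and z2 non-adjacent => x -> y
                half = [z for z in struct.nodes
                        if frozenset((x, z)) in struct.undirected
                        and (z, y) in struct.directed]
                if any(not struct.adjacent(z1, z2)
                       for z1, z2 in itertools.combinations(half, 2)):
                    _force_direction(struct, x, y, "rule R3")
                    changed = True
                    break
            if changed:
                break


def orient_with_order(pdag: CausalStructure, order: list[str]) -> CausalStructure:
    """Complete a PDAG to a DAG with a causal order: every undirected edge
    a - b becomes a -> b when a precedes b.  Existing directed edges must
    agree with the order."""
    if sorted(order) != sorted(pdag.nodes):
        raise ValueError("order must be a permutation of the trait nodes")
    rank = {x: i for i, x in enumerate(order)}
    for a, b in pdag.directed:
        if rank[a] > rank[b]:
            raise InconsistentOrientationError(
                f"directed edge {a}->{b} contradicts the causal order")
    out = CausalStructure(list(pdag.nodes), set(), set(pdag.directed),
                          dict(pdag.sepsets), status="dag", lam=pdag.lam)
    for e in pdag.undirected:
        a, b = sorted(e, key=rank.get)
        out.directed.add((a, b))
    if not out.is_acyclic():
        raise InconsistentOrientationError("completion produced a cycle")
    return out


# ---------------------------------------------------------------------------
# end-to-end: posterior draws -> structure
# ---------------------------------------------------------------------------

def infer_structure(draws: PosteriorDraws, coverage: float,
                    order: list[str] | None = None,
                    decisions_log: dict | None = None) -> CausalStructure:
    """IC algorithm on HPD dependence decisions over residual partial
    correlation draws.  With ``order`` the PDAG is completed to a DAG."""
    traits = list(draws.traits)
    index = {t: i for i, t in enumerate(traits)}
    cache: dict = {}

    def oracle(a: str, b: str, h: tuple) -> bool:
        key = (frozenset((a, b)), frozenset(h))
        if key not in cache:
            rho = partial_correlation_draws(
                draws, (index[a], index[b]), tuple(index[x] for x in h))
            cache[key] = dependence_decision(rho, coverage)
            if decisions_log is not None:
                decisions_log[f"{a}|{b}|{','.join(sorted(h))}"] = bool(cache[key])
        return cache[key]

    struct = ic_algorithm(traits, oracle)
    if order is not None:
        struct = orient_with_order(struct, order)
    logger.info("network at HPD %.2f: %d directed, %d undirected edges",
                coverage, len(struct.directed), len(struct.undirected))
    return struct
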