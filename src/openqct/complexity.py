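"""Scalar complexity C = f(S o E), its bounds, profiles and maps.

Complexity condenses a window's dependency structure (adjacency matrix S)
and disorder (entropy matrix E, bits) into one scalar: the spectral norm
(largest singular value) of the Hadamard product S o E.  For the symmetric
matrices produced here this equals the largest absolute eigenvalue.  C is
measured in bits, like entropy.

C is bounded.  C_min is the complexity the current interdependency
topology would have if every connected pair were perfectly dependent
(joint entropy at its information-theoretic floor, max of the marginals):
dynamics dominated by structure.  C_critical is the complexity of the same
topology at maximal disorder (joint entropy at the independence ceiling,
sum of the marginals): dynamics dominated by entropy.  The observed C
always lies between the two; its position in the band {C_min, C,
C_critical} characterizes how close the system runs to the
entropy-dominated "critical" regime.

The complexity profile attributes percentages of C to individual
variables by leave-one-out norm reduction; the complexity map is the graph
of structured pairs, weighted by joint entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dependency import MatrixPair
from .exceptions import InvalidMatrixError

PROFILE_METHODS = ("leave_one_out", "eigenvector")


def _spectral_norm(a: np.ndarray) -> float:
    """Largest singular value; for symmetric a, the largest |eigenvalue|."""
    if a.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvalsh(a))))


def _checked(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(np.isnan(a)):
        raise InvalidMatrixError("matrix contains NaN")
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise InvalidMatrixError("matrix must be square and symmetric")
    return a


def complexity(mp: MatrixPair) -> float:
    """C = spectral norm of S o E, in bits."""
    return _spectral_norm(_checked(mp.hadamard()))


def complexity_bounds(mp: MatrixPair, b: int | None = None) -> tuple[float, float]:
    """Lower and upper complexity bounds (C_min, C_critical) for the
    current adjacency topology S.

    With ``b`` given, the textbook rank-binning extremes are used: every
    connected entry of E_min at log2(b) (perfect dependence) and E_max
    with diagonal log2(b), connected off-diagonals 2*log2(b)
    (independence).  Without ``b`` (the default in the pipeline), the
    extremes come from the measured marginal entropies of each pair's own
    sample subset — E_min_ij = max(h_i, h_j), E_max_ij = h_i + h_j — which
    bracket the joint entropy exactly, so C_min <= C <= C_critical is
    guaranteed even on gappy windows where pairs see different sample
    counts.
    """
    S = _checked(mp.S)
    if b is not None:
        h = float(np.log2(b))
        e_min = np.full_like(S, h)
        e_max = np.full((mp.n, mp.n), 2.0 * h)
        np.fill_diagonal(e_max, h)
    elif mp.e_lo is not None and mp.e_hi is not None:
        e_min, e_max = mp.e_lo, mp.e_hi
    else:
        h = np.diag(mp.E)
        e_min = np.maximum.outer(h, h)
        e_max = np.add.outer(h, h)
        np.fill_diagonal(e_max, h)
    c_min = _spectral_norm(S * e_min)
    c_critical = _spectral_norm(S * e_max)
    return c_min, c_critical


def complexity_profile(mp: MatrixPair, method: str = "leave_one_out") -> np.ndarray:
    """Percentage contribution of each variable to total complexity.

    ``leave_one_out`` (default): the raw contribution of variable k is the
    drop in C when its row and column are removed, clipped at zero;
    percentages are the normalized raw contributions.  ``eigenvector``:
    squared loadings of the leading eigenvector (sensitivity-analysis
    alternative).  A window with no complexity at all (or where no
    variable's removal changes C) is attributed uniformly.
    """
    n = mp.n
    if n == 1:
        return np.array([100.0])
    a = _checked(mp.hadamard())
    if method == "leave_one_out":
        c_full = _spectral_norm(a)
        raw = np.empty(n)
        idx = np.arange(n)
        for k in range(n):
            keep = idx != k
            raw[k] = max(0.0, c_full - _spectral_norm(a[np.ix_(keep, keep)]))
    elif method == "eigenvector":
        w, v = np.linalg.eigh(a)
        raw = v[:, np.argmax(np.abs(w))] ** 2
    else:
        raise ValueError(f"unknown profile method {method!r}")
    total = raw.sum()
    if total <= 0:
        return np.full(n, 100.0 / n)
    return raw / total * 100.0


def complexity_map(mp: MatrixPair) -> nx.Graph:
    """Graph of structured interdependencies: one node per variable, one
    undirected edge per structured pair, weighted by joint entropy."""
    g = nx.Graph()
    for k, name in enumerate(mp.variable_names):
        g.add_node(name, marginal_entropy=float(mp.E[k, k]))
    for i in range(mp.n):
        for j in range(i + 1, mp.n):
            if mp.S[i, j] == 1:
                g.add_edge(mp.variable_names[i], mp.variable_names[j],
                           joint_entropy=float(mp.E[i, j]),
                           mi=float(mp.mi[i, j]) if mp.mi is not None else None)
    return g


def map_to_dict(g: nx.Graph) -> dict:
    """JSON-serializable node/edge list of a complexity map."""
    return {
        "nodes": [{"name": n, **d} for n, d in g.nodes(data=True)],
        "edges": [{"source": u, "target": v, **d} for u, v, d in g.edges(data=True)],
    }


@dataclass
class ComplexityState:
    """Complexity triple, matrices and profile for one analysis window."""

    C: float
    C_min: float
    C_critical: float
    matrices: MatrixPair
    profile: np.ndarray  # percent per variable, sums to 100
    window_index: int = 0
    window_end_time: float = 0.0


def evaluate_window(
    mp: MatrixPair,
    window_index: int = 0,
    window_end_time: float = 0.0,
    profile_method: str = "leave_one_out",
) -> ComplexityState:
    """Compute the full complexity state {C_min, C, C_critical} + profile."""
    c = complexity(mp)
    c_min, c_crit = complexity_bounds(mp)
    prof = complexity_profile(mp, method=profile_method)
    return ComplexityState(C=c, C_min=c_min, C_critical=c_crit, matrices=mp,
                           profile=prof, window_index=window_index,
                           window_end_time=window_end_time)
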