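"""Generalized-correlation detection via rank-pixelated scatter images.

The dependency between two beat-to-beat variables is judged from the
*image* of their scatter plot rather than from a linear statistic.  The
scatter area is discretized into a b x b pixel mesh with b = floor(sqrt(M))
pixels per side (M samples -> for M = 100 a 10 x 10 mesh); each pixel's
density is m/M, the fraction of samples falling into it.  Shannon entropy
H = -sum p_i log2 p_i of the pixel densities, in bits, measures the
disorder of the image: a structured image (correlated variables) has low
joint entropy, a chaotic one approaches the 2*log2(b) bits of an
independent pair.

Axes are partitioned into *equal-frequency rank bins* (a copula grid), not
equal-width value bins.  This makes the image invariant under any strictly
monotone rescaling of either variable and immune to outliers, and pins the
marginal entropies at ~log2(b) bits so that all dependence information sits
in the joint term.

The structured/chaotic verdict is a permutation-surrogate test on mutual
information MI = H_x + H_y - H_xy: the pairing of y with x is destroyed by
random row permutation n_surrogates times, and the pair is declared
structured when the observed MI exceeds the (1 - alpha) order statistic of
the surrogate MIs (exact-level permutation threshold).  All randomness is
seeded; the surrogate seed of a pair inside a window derives from
(global seed, window index, pair index), so runs are reproducible and
pair_dependency(x, y) == pair_dependency(y, x) bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateVariableError,
    InsufficientSamplesError,
    InvalidInputError,
    InvalidMatrixError,
)

DEFAULT_ALPHA = 0.05
DEFAULT_N_SURROGATES = 200
#: Minimum pairwise-complete samples for a 2 x 2 mesh.
MIN_SAMPLES = 4


def mesh_side(m: int) -> int:
    """Pixels per side of the scatter mesh for M samples: floor(sqrt(M)).

    M = 100 gives the canonical 10 x 10 mesh.  M < 4 cannot support the
    smallest (2 x 2) mesh and raises :class:`InsufficientSamplesError`.
    """
    if m < MIN_SAMPLES:
        raise InsufficientSamplesError(f"need at least {MIN_SAMPLES} samples, got {m}")
    return int(np.sqrt(m))


def shannon_entropy(p) -> float:
    """Shannon entropy H = -sum p_i log2(p_i) in bits; zero cells contribute 0."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0):
        raise InvalidInputError("probabilities must be non-negative")
    if p.sum() > 1.0 + 1e-9:
        raise InvalidInputError("probabilities must sum to at most 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def rank_bins(values: np.ndarray, b: int) -> np.ndarray:
    """Assign each value to one of b equal-frequency rank bins (0..b-1).

    Ties are broken by stable input order, so bin populations differ by at
    most one.  A constant input has no rank structure and raises
    :class:`DegenerateVariableError`.
    """
    values = np.asarray(values, dtype=float)
    m = values.size
    if np.all(values == values[0]):
        raise DegenerateVariableError("variable is constant over the window")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(m)
    return ranks * b // m


@dataclass(frozen=True)
class PixelImage:
    """b x b density image of a two-variable rank scatter plot."""

    b: int
    counts: np.ndarray  # (b, b) int, pixel occupancies m
    M: int

    @property
    def density(self) -> np.ndarray:
        """Pixel densities m/M; non-negative and summing to 1."""
        return self.counts / self.M

    def joint_entropy(self) -> float:
        return shannon_entropy(self.density)

    def marginal_entropies(self) -> tuple[float, float]:
        d = self.density
        return shannon_entropy(d.sum(axis=1)), shannon_entropy(d.sum(axis=0))


def rank_pixelate(x, y) -> PixelImage:
    """Pixelate the (x, y) scatter plot on a b x b equal-frequency rank mesh.

    Inputs must be equal-length, gap-free (pairwise-complete) and have
    M >= 4 samples.  Perfectly dependent inputs (y a monotone function of
    x) put all mass on the b diagonal pixels; independent inputs spread it
    over the full mesh.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D sequences")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise InvalidInputError("rank_pixelate expects pairwise-complete samples")
    m = x.size
    b = mesh_side(m)
    bx = rank_bins(x, b)
    by = rank_bins(y, b)
    counts = np.bincount(bx * b + by, minlength=b * b).reshape(b, b)
    return PixelImage(b=b, counts=counts, M=m)


@dataclass(frozen=True)
class DependencyResult:
    """Outcome of the generalized-correlation test for one variable pair."""

    h_i: float
    h_j: float
    h_ij: float
    mi: float
    null_quantile: float
    structured: bool
    n_valid: int
    b: int


def _surrogate_mis(bx: np.ndarray, by: np.ndarray, b: int,
                   n_surrogates: int, rng: np.random.Generator) -> np.ndarray:
    """MI of n row-permuted surrogates, vectorized over surrogates."""
    m = bx.size
    perms = np.argsort(rng.random((n_surrogates, m)), axis=1)
    # joint histograms of all surrogates in one bincount
    flat = bx[perms] * b + by[np.newaxis, :]
    flat += (np.arange(n_surrogates) * b * b)[:, np.newaxis]
    counts = np.bincount(flat.ravel(), minlength=n_surrogates * b * b)
    dens = counts.reshape(n_surrogates, b * b) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        h_joint = -np.nansum(np.where(dens > 0, dens * np.log2(dens), 0.0), axis=1)
    # marginals are permutation-invariant
    hx = shannon_entropy(np.bincount(bx, minlength=b) / m)
    hy = shannon_entropy(np.bincount(by, minlength=b) / m)
    return hx + hy - h_joint


def null_threshold(null_mis: np.ndarray, alpha: float) -> float:
    """Exact-level permutation threshold: the k-th largest surrogate MI.

    k = floor(alpha * (n + 1)); declaring dependence when the observed MI
    strictly exceeds this order statistic gives a type-I rate of
    floor(alpha*(n+1)) / (n+1) <= alpha under exchangeability.
    """
    n = null_mis.size
    k = int(np.floor(alpha * (n + 1)))
    if k < 1:
        raise InvalidInputError(
            f"n_surrogates={n} too small for alpha={alpha}: needs n >= 1/alpha - 1"
        )
    return float(np.sort(null_mis)[n - k])


def pair_dependency(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    rng_seed: int | np.random.SeedSequence = 0,
) -> DependencyResult:
    """Test two gap-free sample vectors for generalized correlation.

    Returns marginal/joint entropies (bits), mutual information, the
    surrogate null threshold and the structured verdict.  A constant
    variable is reported unstructured with zero entropy on its axis.
    Symmetric: swapping x and y gives a bit-identical result (the
    permuted axis is chosen canonically, and MI is axis-symmetric).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    m = x.size
    b = mesh_side(m)

    x_const = bool(np.all(x == x[0]))
    y_const = bool(np.all(y == y[0]))
    if x_const or y_const:
        hx = 0.0 if x_const else shannon_entropy(np.bincount(rank_bins(x, b), minlength=b) / m)
        hy = 0.0 if y_const else shannon_entropy(np.bincount(rank_bins(y, b), minlength=b) / m)
        return DependencyResult(h_i=hx, h_j=hy, h_ij=max(hx, hy), mi=0.0,
                                null_quantile=np.inf, structured=False, n_valid=m, b=b)

    bx = rank_bins(x, b)
    by = rank_bins(y, b)
    swap = bx.tobytes() > by.tobytes()  # canonical orientation for surrogates
    ax, ay = (by, bx) if swap else (bx, by)

    counts = np.bincount(ax * b + ay, minlength=b * b).reshape(b, b)
    dens = counts / m
    h_ij = shannon_entropy(dens)
    h_ax = shannon_entropy(dens.sum(axis=1))
    h_ay = shannon_entropy(dens.sum(axis=0))
    mi = h_ax + h_ay - h_ij

    rng = np.random.default_rng(rng_seed)
    nulls = _surrogate_mis(ax, ay, b, n_surrogates, rng)
    q = null_threshold(nulls, alpha)
    h_i, h_j = (h_ay, h_ax) if swap else (h_ax, h_ay)
    return DependencyResult(h_i=h_i, h_j=h_j, h_ij=h_ij, mi=mi,
                            null_quantile=q, structured=bool(mi > q),
                            n_valid=m, b=b)


@dataclass
class MatrixPair:
    """Adjacency matrix S and entropy matrix E for one window of data.

    S is symmetric 0/1 with unit diagonal; S_ij = 1 marks a structured
    (generalized-correlated) pair.  E is symmetric, in bits: E_ii is the
    marginal entropy of variable i, E_ij the joint entropy of pair (i, j).
    The complexity operator consumes the Hadamard product S o E, so
    unstructured pairs contribute nothing.

    ``e_lo``/``e_hi`` carry the information-theoretic extremes of each
    entry given the measured marginals of the pair's own sample subset
    (max(h_i, h_j) and h_i + h_j); the bound operators use them so that
    C_min <= C <= C_critical holds exactly even when gap handling gives
    different pairs different sample counts.
    """

    S: np.ndarray
    E: np.ndarray
    variable_names: tuple[str, ...]
    e_lo: np.ndarray | None = None
    e_hi: np.ndarray | None = None
    mi: np.ndarray | None = None
    b: np.ndarray | None = None  # per-entry mesh side
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.variable_names = tuple(self.variable_names)
        n = len(self.variable_names)
        self.S = np.asarray(self.S, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.S.shape != (n, n) or self.E.shape != (n, n):
            raise InvalidMatrixError("S and E must be N x N for N variable names")
        if np.any(np.isnan(self.S)) or np.any(np.isnan(self.E)):
            raise InvalidMatrixError("S and E may not contain NaN")
        if not np.array_equal(self.S, self.S.T) or not np.allclose(self.E, self.E.T):
            raise InvalidMatrixError("S and E must be symmetric")
        if not np.all(np.isin(self.S, (0.0, 1.0))):
            raise InvalidMatrixError("S entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.variable_names)

    def hadamard(self) -> np.ndarray:
        """The masked entropy matrix S o E entering the complexity norm."""
        return self.S * self.E

    def to_dict(self) -> dict:
        """JSON-serializable diagnostic dump of the window's matrices."""
        return {
            "variable_names": list(self.variable_names),
            "S": self.S.astype(int).tolist(),
            "E": self.E.tolist(),
            "mi": None if self.mi is None else self.mi.tolist(),
            "dropped": list(self.dropped),
        }


def pair_seed(global_seed: int, window_index: int, i: int, j: int) -> np.random.SeedSequence:
    """Deterministic surrogate seed for pair (i, j) of a window."""
    lo, hi = (i, j) if i <= j else (j, i)
    return np.random.SeedSequence(entropy=int(global_seed) & 0x7FFFFFFF,
                                  spawn_key=(int(window_index), lo, hi))


def build_matrices(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    variable_names: tuple[str, ...] | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    min_valid_fraction: float = 0.5,
    seed: int = 0,
    window_index: int = 0,
) -> MatrixPair:
    """Run the pairwise dependency test over an M x N window of data.

    Each unordered pair is tested on its pairwise-complete rows.  A
    variable (or pair) with fewer than ``max(MIN_SAMPLES,
    min_valid_fraction * M)`` valid rows is isolated (forced unstructured)
    for this window; fully degenerate variables get zero marginal entropy.

    Returns the :class:`MatrixPair` with S, E, per-pair MI and the
    entrywise entropy extremes used by the bound operators.
    """
    data = np.asarray(data, dtype=float)
    m_rows, n = data.shape
    if n < 2:
        raise InvalidInputError("need at least two variables")
    if mask is None:
        mask = np.isnan(data)
    names = tuple(variable_names) if variable_names else tuple(f"x{k}" for k in range(n))
    min_rows = max(MIN_SAMPLES, int(np.ceil(min_valid_fraction * m_rows)))

    S = np.eye(n)
    E = np.zeros((n, n))
    MI = np.zeros((n, n))
    B = np.zeros((n, n))
    e_lo = np.zeros((n, n))
    e_hi = np.zeros((n, n))
    dropped: list[str] = []

    valid = ~mask
    # diagonal: marginal entropy of each variable on its own valid rows
    h_diag = np.zeros(n)
    usable = np.ones(n, dtype=bool)
    for k in range(n):
        col = data[valid[:, k], k]
        if col.size < min_rows:
            usable[k] = False
            dropped.append(names[k])
            continue
        bk = mesh_side(col.size)
        try:
            h_diag[k] = shannon_entropy(np.bincount(rank_bins(col, bk), minlength=bk) / col.size)
        except DegenerateVariableError:
            h_diag[k] = 0.0
            usable[k] = False
        B[k, k] = bk
    E[np.diag_indices(n)] = h_diag
    e_lo[np.diag_indices(n)] = h_diag
    e_hi[np.diag_indices(n)] = h_diag

    for i in range(n):
        for j in range(i + 1, n):
            if not (usable[i] and usable[j]):
                continue
            rows = valid[:, i] & valid[:, j]
            if rows.sum() < min_rows:
                continue
            res = pair_dependency(
                data[rows, i], data[rows, j],
                alpha=alpha, n_surrogates=n_surrogates,
                rng_seed=pair_seed(seed, window_index, i, j),
            )
            MI[i, j] = MI[j, i] = res.mi
            E[i, j] = E[j, i] = res.h_ij
            B[i, j] = B[j, i] = res.b
            e_lo[i, j] = e_lo[j, i] = max(res.h_i, res.h_j)
            e_hi[i, j] = e_hi[j, i] = res.h_i + res.h_j
            if res.structured:
                S[i, j] = S[j, i] = 1.0

    return MatrixPair(S=S, E=E, variable_names=names, e_lo=e_lo, e_hi=e_hi,
                      mi=MI, b=B, dropped=tuple(dropped))
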