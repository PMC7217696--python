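"""Spatial network construction on an open grid.

Neurons live on a ``side x side`` square lattice with open (non-periodic)
boundaries. A fixed fraction is excitatory; the inhibitory minority is spread
evenly over the grid with Mitchell's best-candidate algorithm so that chance
clusters of one type are avoided. Each neuron connects to neighbours within a
local circular range, with a connection probability that decays exponentially
with Euclidean distance,

    P(r) = min(alpha * exp(-r), 1),

where ``alpha`` is solved per presynaptic neuron so that the expected
connected fraction of its neighbourhood equals the connectivity percentage
(CE for excitatory, CI for inhibitory presynaptic neurons). Border neurons
have smaller neighbourhoods and get their own ``alpha``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "GridSpec",
    "ConnectivityParams",
    "GridNetwork",
    "place_inhibitory",
    "solve_alpha",
    "build_connections",
    "save_network",
    "load_network",
]

DEFAULT_SIDE = 50
DEFAULT_FRAC_EXCITATORY = 0.75
DEFAULT_LOCAL_RADIUS = 4.0
#: candidates per placement in Mitchell's best-candidate algorithm
DEFAULT_MITCHELL_K = 10

EXCITATORY = 0
INHIBITORY = 1


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the neuron grid.

    Parameters
    ----------
    side_length : int
        Number of neurons along one side of the square grid.
    frac_excitatory : float
        Fraction of neurons that are excitatory (the rest are inhibitory).
    local_radius : float
        Radius (in grid units, Euclidean) of the local connection range.
    seed : int
        Seed for inhibitory placement and connection sampling.
    mitchell_k : int
        Number of random candidates per point in Mitchell's algorithm.
    """

    side_length: int = DEFAULT_SIDE
    frac_excitatory: float = DEFAULT_FRAC_EXCITATORY
    local_radius: float = DEFAULT_LOCAL_RADIUS
    seed: int = 0
    mitchell_k: int = DEFAULT_MITCHELL_K

    def __post_init__(self) -> None:
        if self.side_length < 2:
            raise ValueError("side_length must be >= 2")
        if not 0.0 < self.frac_excitatory < 1.0:
            raise ValueError("frac_excitatory must be in (0, 1)")
        if self.local_radius <= 0:
            raise ValueError("local_radius must be > 0")
        if self.mitchell_k < 1:
            raise ValueError("mitchell_k must be >= 1")

    @property
    def n_neurons(self) -> int:
        return self.side_length**2

    @property
    def n_excitatory(self) -> int:
        return round(self.frac_excitatory * self.n_neurons)

    @property
    def n_inhibitory(self) -> int:
        return self.n_neurons - self.n_excitatory


@dataclass(frozen=True)
class ConnectivityParams:
    """Local connectivity percentages for excitatory (CE) and inhibitory (CI)
    presynaptic neurons, in percent of the local neighbourhood."""

    CE: float
    CI: float

    def __post_init__(self) -> None:
        for name, v in (("CE", self.CE), ("CI", self.CI)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be within [0, 100], got {v}")


@dataclass
class GridNetwork:
    """A constructed network: positions, types and the weighted synapse table.

    Attributes
    ----------
    spec, params : construction inputs.
    positions : (N, 2) int array of 0-based (row, col) coordinates,
        neuron ids enumerate the grid row-major.
    neuron_type : (N,) int array, 0 = excitatory, 1 = inhibitory.
    pre, post : (E,) int arrays, directed edges pre -> post.
    weight : (E,) float array, synaptic weight of each edge.
    alpha_per_neuron : (N,) float array, solved scale factor of the
        connection-probability law for each presynaptic neuron.
    alpha_residual : (N,) float array, |expected - target| residual of the
        alpha solve (non-zero when no exact root exists, e.g. saturated
        border neighbourhoods).
    """

    spec: GridSpec
    params: ConnectivityParams
    positions: np.ndarray
    neuron_type: np.ndarray
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    alpha_per_neuron: np.ndarray
    alpha_residual: np.ndarray
    weights_by_type: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_type)

    @property
    def excitatory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.neuron_type == EXCITATORY)

    @property
    def inhibitory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.neuron_type == INHIBITORY)

    def connection_matrix(self):
        """Weight matrix W with W[post, pre] = weight, as CSR sparse."""
        from scipy.sparse import coo_matrix

        n = self.n_neurons
        return coo_matrix(
            (self.weight, (self.post, self.pre)), shape=(n, n)
        ).tocsr()


def place_inhibitory(
    spec: GridSpec,
    rng: np.random.Generator | None = None,
    n_points: int | None = None,
) -> set[tuple[int, int]]:
    """Place the inhibitory neurons on the grid with Mitchell's
    best-candidate algorithm.

    Each new point is chosen among ``spec.mitchell_k`` uniform random empty
    cells as the one farthest from all previously placed points, yielding a
    more even (blue-noise) spatial distribution than uniform sampling.

    Returns the set of occupied (row, col) cells; remaining cells are
    excitatory.
    """
    n_inh = spec.n_inhibitory if n_points is None else n_points
    n_cells = spec.n_neurons
    if n_inh > n_cells:
        raise ValueError("grid too small for requested inhibitory count")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    side = spec.side_length
    free = np.ones(n_cells, dtype=bool)
    placed = np.empty((n_inh, 2), dtype=float)

    # first point: uniform
    first = rng.integers(n_cells)
    free[first] = False
    placed[0] = divmod(first, side)

    for i in range(1, n_inh):
        free_ids = np.flatnonzero(free)
        k = min(spec.mitchell_k, len(free_ids))
        cand_ids = rng.choice(free_ids, size=k, replace=False)
        cand_xy = np.column_stack(divmod(cand_ids, side)).astype(float)
        # farthest-from-existing candidate wins
        d = cdist(cand_xy, placed[:i]).min(axis=1)
        best = cand_ids[int(np.argmax(d))]
        free[best] = False
        placed[i] = divmod(best, side)

    return {(int(r), int(c)) for r, c in placed}


def _expected_connections(alpha: float, distances: np.ndarray) -> float:
    return float(np.minimum(alpha * np.exp(-distances), 1.0).sum())


def solve_alpha(target_fraction: float, neighbor_distances, tol: float = 1e-6) -> float:
    """Solve for the scale factor ``alpha`` of the connection-probability law.

    Finds alpha >= 0 minimizing
    ``f(alpha) = | sum_j min(alpha e^{-r_j}, 1) - target * |J| |``
    by Nelder-Mead from the initial guess ``target*|J| / sum_j e^{-r_j}``
    (the exact root when no per-neighbour probability saturates).

    Parameters
    ----------
    target_fraction : float in (0, 1]
        Desired expected connected fraction of the neighbourhood.
    neighbor_distances : array-like of positive floats
        Euclidean distances to each neighbour in the local range.
    """
    r = np.asarray(neighbor_distances, dtype=float)
    if r.size == 0:
        raise ValueError("empty neighbor list")
    if np.any(r <= 0):
        raise ValueError("all neighbor distances must be > 0")
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")

    target = target_fraction * r.size
    er = np.exp(-r)

    def f(a):
        a = float(a[0]) if np.ndim(a) else float(a)
        if a < 0:
            return target + abs(a)  # steer back to alpha >= 0
        return abs(np.minimum(a * er, 1.0).sum() - target)

    a0 = target / er.sum()
    res = minimize(f, x0=[a0], method="Nelder-Mead",
                   options={"xatol": tol, "fatol": tol, "maxiter": 500})
    alpha = max(float(res.x[0]), 0.0)
    # f is piecewise linear; polish with the exact root of the active piece
    unsat = alpha * er < 1.0
    n_sat = int((~unsat).sum())
    denom = er[unsat].sum()
    if denom > 0:
        exact = (target - n_sat) / denom
        if exact >= 0 and f([exact]) <= f([alpha]):
            alpha = float(exact)
    return alpha


def _neighbor_offsets(radius: float) -> np.ndarray:
    """Integer (dr, dc) offsets with 0 < Euclidean norm <= radius."""
    m = int(np.floor(radius))
    dr, dc = np.mgrid[-m : m + 1, -m : m + 1]
    d2 = dr**2 + dc**2
    keep = (d2 > 0) & (d2 <= radius**2)
    return np.column_stack([dr[keep], dc[keep]])


def build_connections(
    spec: GridSpec,
    params: ConnectivityParams,
    weights,
    seed: int | None = None,
) -> GridNetwork:
    """Construct the full network for one seed.

    Inhibitory positions come from :func:`place_inhibitory`; then, for each
    presynaptic neuron, every neighbour within ``local_radius`` is connected
    independently with probability ``min(alpha e^{-r}, 1)``, alpha solved so
    the expected connected fraction equals CE (excitatory pre) or CI
    (inhibitory pre). Edge weights depend only on (pre type, post type).

    Parameters
    ----------
    weights : :class:`crosnet.dynamics.SynapticWeights`
        Supplies W_EE, W_IE, W_EI, W_II.
    seed : overrides ``spec.seed`` when given.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    side = spec.side_length
    n = spec.n_neurons

    inhib_cells = place_inhibitory(spec, rng)
    neuron_type = np.full(n, EXCITATORY, dtype=np.int8)
    for r, c in inhib_cells:
        neuron_type[r * side + c] = INHIBITORY
    rows, cols = np.divmod(np.arange(n), side)
    positions = np.column_stack([rows, cols]).astype(np.int64)

    offsets = _neighbor_offsets(spec.local_radius)
    off_dist = np.hypot(offsets[:, 0], offsets[:, 1]).astype(float)

    # weight lookup by (pre_type, post_type)
    wmap = {
        (EXCITATORY, EXCITATORY): weights.W_EE,
        (EXCITATORY, INHIBITORY): weights.W_IE,
        (INHIBITORY, EXCITATORY): weights.W_EI,
        (INHIBITORY, INHIBITORY): weights.W_II,
    }

    alpha_cache: dict[tuple, float] = {}
    alphas = np.zeros(n)
    residuals = np.zeros(n)
    pre_list, post_list, w_list = [], [], []

    for i in range(n):
        r0, c0 = rows[i], cols[i]
        nr = r0 + offsets[:, 0]
        nc = c0 + offsets[:, 1]
        inside = (nr >= 0) & (nr < side) & (nc >= 0) & (nc < side)
        if not inside.any():
            continue
        dist = off_dist[inside]
        target_pct = params.CE if neuron_type[i] == EXCITATORY else params.CI
        if target_pct <= 0:
            continue
        target = target_pct / 100.0

        key = (round(target, 9), tuple(np.sort(dist).round(9)))
        if key in alpha_cache:
            alpha = alpha_cache[key]
        else:
            alpha = solve_alpha(target, dist)
            alpha_cache[key] = alpha
        alphas[i] = alpha
        residuals[i] = abs(
            _expected_connections(alpha, dist) - target * dist.size
        )

        p = np.minimum(alpha * np.exp(-dist), 1.0)
        connect = rng.random(dist.size) < p
        if not connect.any():
            continue
        tgt_ids = (nr[inside][connect] * side + nc[inside][connect]).astype(np.int64)
        w = np.fromiter(
            (wmap[(int(neuron_type[i]), int(neuron_type[j]))] for j in tgt_ids),
            dtype=float,
            count=len(tgt_ids),
        )
        pre_list.append(np.full(len(tgt_ids), i, dtype=np.int64))
        post_list.append(tgt_ids)
        w_list.append(w)

    if pre_list:
        pre = np.concatenate(pre_list)
        post = np.concatenate(post_list)
        weight = np.concatenate(w_list)
    else:
        pre = np.empty(0, dtype=np.int64)
        post = np.empty(0, dtype=np.int64)
        weight = np.empty(0)

    net = GridNetwork(
        spec=spec,
        params=params,
        positions=positions,
        neuron_type=neuron_type,
        pre=pre,
        post=post,
        weight=weight,
        alpha_per_neuron=alphas,
        alpha_residual=residuals,
        weights_by_type={
            "W_EE": weights.W_EE,
            "W_IE": weights.W_IE,
            "W_EI": weights.W_EI,
            "W_II": weights.W_II,
        },
    )
    _validate_network(net)
    return net


def _validate_network(net: GridNetwork) -> None:
    spec = net.spec
    n_exc = int((net.neuron_type == EXCITATORY).sum())
    assert n_exc == spec.n_excitatory, "excitatory count mismatch"
    assert not np.any(net.pre == net.post), "self-edges present"
    if len(net.pre):
        d = np.linalg.norm(
            net.positions[net.pre] - net.positions[net.post], axis=1
        )
        assert np.all(d <= spec.local_radius + 1e-12), "edge beyond local range"
        edges = set(zip(net.pre.tolist(), net.post.tolist()))
        assert len(edges) == len(net.pre), "duplicate edges"


# ---------------------------------------------------------------------------
# serialization: text header + columnar edge table; lossless round-trip

def save_network(net: GridNetwork, path: str) -> None:
    """Write a network to ``path``.

    ``.npz`` extension: binary container. Anything else: a text format with
    a ``#``-prefixed header (grid spec, params, seed, weights) followed by a
    TSV edge table (pre_id, post_id, weight) and the neuron-type vector.
    """
    if str(path).endswith(".npz"):
        np.savez_compressed(
            path,
            side_length=net.spec.side_length,
            frac_excitatory=net.spec.frac_excitatory,
            local_radius=net.spec.local_radius,
            seed=net.spec.seed,
            mitchell_k=net.spec.mitchell_k,
            CE=net.params.CE,
            CI=net.params.CI,
            neuron_type=net.neuron_type,
            pre=net.pre,
            post=net.post,
            weight=net.weight,
            alpha=net.alpha_per_neuron,
            alpha_residual=net.alpha_residual,
            **{k: v for k, v in net.weights_by_type.items()},
        )
        return
    buf = io.StringIO()
    s = net.spec
    buf.write(
        f"# side_length={s.side_length} frac_excitatory={s.frac_excitatory!r} "
        f"local_radius={s.local_radius!r} seed={s.seed} mitchell_k={s.mitchell_k}\n"
    )
    buf.write(f"# CE={net.params.CE!r} CI={net.params.CI!r}\n")
    wbt = net.weights_by_type
    buf.write(
        "# W_EE={W_EE!r} W_IE={W_IE!r} W_EI={W_EI!r} W_II={W_II!r}\n".format(**wbt)
    )
    buf.write("# neuron_type=" + "".join(map(str, net.neuron_type.tolist())) + "\n")
    buf.write("pre_id\tpost_id\tweight\n")
    for p, q, w in zip(net.pre, net.post, net.weight):
        buf.write(f"{int(p)}\t{int(q)}\t{float(w)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_network(path: str) -> GridNetwork:
    """Inverse of :func:`save_network` (both formats)."""
    if str(path).endswith(".npz"):
        z = np.load(path)
        spec = GridSpec(
            side_length=int(z["side_length"]),
            frac_excitatory=float(z["frac_excitatory"]),
            local_radius=float(z["local_radius"]),
            seed=int(z["seed"]),
            mitchell_k=int(z["mitchell_k"]),
        )
        params = ConnectivityParams(CE=float(z["CE"]), CI=float(z["CI"]))
        neuron_type = z["neuron_type"].astype(np.int8)
        side = spec.side_length
        rows, cols = np.divmod(np.arange(spec.n_neurons), side)
        return GridNetwork(
            spec=spec,
            params=params,
            positions=np.column_stack([rows, cols]).astype(np.int64),
            neuron_type=neuron_type,
            pre=z["pre"].astype(np.int64),
            post=z["post"].astype(np.int64),
            weight=z["weight"].astype(float),
            alpha_per_neuron=z["alpha"].astype(float),
            alpha_residual=z["alpha_residual"].astype(float),
            weights_by_type={
                k: float(z[k]) for k in ("W_EE", "W_IE", "W_EI", "W_II")
            },
        )
    header: dict[str, str] = {}
    pre, post, weight = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].strip().split():
                    k, _, v = tok.partition("=")
                    header[k] = v
            elif line and not line.startswith("pre_id"):
                p, q, w = line.split("\t")
                pre.append(int(p))
                post.append(int(q))
                weight.append(float(w))
    spec = GridSpec(
        side_length=int(header["side_length"]),
        frac_excitatory=float(header["frac_excitatory"]),
        local_radius=float(header["local_radius"]),
        seed=int(header["seed"]),
        mitchell_k=int(header["mitchell_k"]),
    )
    params = ConnectivityParams(CE=float(header["CE"]), CI=float(header["CI"]))
    neuron_type = np.array([int(ch) for ch in header["neuron_type"]], dtype=np.int8)
    side = spec.side_length
    rows, cols = np.divmod(np.arange(spec.n_neurons), side)
    n = spec.n_neurons
    return GridNetwork(
        spec=spec,
        params=params,
        positions=np.column_stack([rows, cols]).astype(np.int64),
        neuron_type=neuron_type,
        pre=np.asarray(pre, dtype=np.int64),
        post=np.asarray(post, dtype=np.int64),
        weight=np.asarray(weight, dtype=float),
        alpha_per_neuron=np.zeros(n),
        alpha_residual=np.zeros(n),
        weights_by_type={
            k: float(header[k]) for k in ("W_EE", "W_IE", "W_EI", "W_II")
        },
    )
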