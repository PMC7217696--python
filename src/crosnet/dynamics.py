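"""Probabilistic integrate-and-fire dynamics with 1 ms time steps.

Each step, every neuron i updates its synaptic input with the spikes its
presynaptic partners fired on the previous step, under exponential decay
(time constant tau_I); the input then drives the activation A (time constant
tau_P, baseline A0); the neuron fires with probability A clamped to [0, 1];
and firing resets A to the reset value A_r. Excitatory and inhibitory
neurons differ in tau_P, A0 and A_r. Stimulation injects the input weight
w_input into a fixed random subset of excitatory neurons for exactly one
step, at intervals drawn uniformly from an inter-stimulus range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

from .topology import EXCITATORY, GridNetwork

__all__ = [
    "NeuronParams",
    "SynapticWeights",
    "SimState",
    "StimulusProtocol",
    "SpikeRaster",
    "step",
    "apply_stimulus",
    "run_simulation",
    "save_raster",
    "load_raster",
    "STIMULUS_SIZES",
]

DT_MS = 1.0

#: stimulus sizes used in the stimulation sweeps (log-ish spaced, 1..1800)
STIMULUS_SIZES = (1, 2, 3, 5, 9, 15, 25, 43, 74, 126, 216, 369, 632, 1081, 1800)


@dataclass(frozen=True)
class NeuronParams:
    """Integrate-and-fire constants, per neuron type.

    tau_I is shared; tau_P, A0 (baseline activation) and A_reset are
    (excitatory, inhibitory) pairs.
    """

    tau_I: float = 9.0
    tau_P_exc: float = 6.0
    tau_P_inh: float = 12.0
    A0_exc: float = 0.000001
    A0_inh: float = 0.0
    A_reset_exc: float = -2.0
    A_reset_inh: float = -20.0

    def __post_init__(self) -> None:
        if self.tau_I <= 0 or self.tau_P_exc <= 0 or self.tau_P_inh <= 0:
            raise ValueError("time constants must be > 0")
        if self.A_reset_exc > 0 or self.A_reset_inh > 0:
            raise ValueError("reset activations must be <= 0")


@dataclass(frozen=True)
class SynapticWeights:
    """Fixed synaptic weights by (pre, post) type and the stimulus weight."""

    W_EE: float = 0.0085
    W_IE: float = 0.0085   # excitatory pre -> inhibitory post
    W_EI: float = -0.569   # inhibitory pre -> excitatory post
    W_II: float = -2.0
    w_input: float | None = None  # defaults to W_EE
    input_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.W_EE <= 0 or self.W_IE <= 0:
            raise ValueError("excitatory weights must be > 0")
        if self.W_EI >= 0 or self.W_II >= 0:
            raise ValueError("inhibitory weights must be < 0")
        if self.w_input is None:
            object.__setattr__(self, "w_input", self.W_EE)

    @property
    def effective_input(self) -> float:
        return self.w_input * self.input_multiplier


@dataclass
class SimState:
    """Per-neuron state at one time step."""

    I: np.ndarray  # synaptic input
    A: np.ndarray  # activation
    S: np.ndarray  # binary spike flags of the previous step
    t: float = 0.0  # ms

    @classmethod
    def zeros(cls, n: int) -> "SimState":
        return cls(I=np.zeros(n), A=np.zeros(n), S=np.zeros(n, dtype=bool))


@dataclass(frozen=True)
class StimulusProtocol:
    """One-step stimulation of a fixed random excitatory subset.

    Stimuli recur at intervals drawn uniformly (integer ms) from
    ``isi_range``; the targeted subset is drawn once per run and held fixed.
    """

    n_stimulated: int
    isi_range: tuple[int, int] = (500, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimulated < 0:
            raise ValueError("n_stimulated must be >= 0")
        if self.isi_range[0] < 1 or self.isi_range[1] < self.isi_range[0]:
            raise ValueError("invalid isi_range")

    def draw_targets(self, network: GridNetwork, rng: np.random.Generator) -> np.ndarray:
        exc = network.excitatory_ids
        if self.n_stimulated > len(exc):
            raise ValueError(
                f"protocol requests {self.n_stimulated} targets but network "
                f"has {len(exc)} excitatory neurons"
            )
        return rng.choice(exc, size=self.n_stimulated, replace=False)

    def draw_stim_times(self, n_steps: int, rng: np.random.Generator) -> np.ndarray:
        """Stimulus onset times (ms) within [0, n_steps)."""
        lo, hi = self.isi_range
        times = []
        t = int(rng.integers(lo, hi + 1))
        while t < n_steps:
            times.append(t)
            t += int(rng.integers(lo, hi + 1))
        return np.asarray(times, dtype=np.int64)


@dataclass
class SpikeRaster:
    """Spikes of one run: sparse binary (timestep x neuron) matrix plus
    per-type per-step counts and the stimulus event times."""

    spikes: csr_matrix | None
    counts_exc: np.ndarray
    counts_inh: np.ndarray
    stim_times: np.ndarray
    stim_targets: np.ndarray
    n_steps: int
    n_neurons: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def counts_total(self) -> np.ndarray:
        return self.counts_exc + self.counts_inh

    def to_dense(self) -> np.ndarray:
        if self.spikes is None:
            raise ValueError("run recorded counts only; spikes unavailable")
        return self.spikes.toarray().astype(bool)

    def to_events(self) -> np.ndarray:
        """(n_events, 2) array of (t, neuron_id), time-ordered."""
        if self.spikes is None:
            raise ValueError("run recorded counts only; spikes unavailable")
        coo = self.spikes.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]]).astype(np.int64)


def _per_type_vectors(network: GridNetwork, params: NeuronParams):
    exc = network.neuron_type == EXCITATORY
    tau_P = np.where(exc, params.tau_P_exc, params.tau_P_inh)
    A0 = np.where(exc, params.A0_exc, params.A0_inh)
    A_reset = np.where(exc, params.A_reset_exc, params.A_reset_inh)
    return exc, tau_P, A0, A_reset


def apply_stimulus(state: SimState, targets: np.ndarray, w_input: float,
                   network: GridNetwork | None = None) -> SimState:
    """Inject ``w_input`` into the synaptic input of each target neuron.

    The increment is added before the step's input decay (it enters the
    update like a presynaptic spike). Targets must be excitatory.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if network is not None and len(targets):
        if np.any(network.neuron_type[targets] != EXCITATORY):
            raise ValueError("stimulus targets must be excitatory neurons")
    state.I[targets] += w_input
    return state


def step(
    state: SimState,
    W: csr_matrix,
    params: NeuronParams,
    rng: np.random.Generator,
    tau_P: np.ndarray,
    A0: np.ndarray,
    A_reset: np.ndarray,
    stim_increment: np.ndarray | None = None,
) -> SimState:
    """Advance the network by one 1 ms step (in place).

    Order: input integration (with decay) -> activation update -> spike draw
    with probability clamp(A, 0, 1) -> reset of spikers. Spikes take effect
    on their targets at the next step. ``W[post, pre]`` is the weight matrix;
    ``tau_P``/``A0``/``A_reset`` are the per-neuron constant vectors from
    :func:`_per_type_vectors` (passed in to avoid rebuilding each step).
    """
    drive = W @ state.S.astype(float)
    if stim_increment is not None:
        drive += stim_increment
    state.I = (state.I + drive) * (1.0 - DT_MS / params.tau_I)
    state.A = (state.A + state.I) * (1.0 - DT_MS / tau_P) + A0 * DT_MS / tau_P
    if np.any(np.isnan(state.A)) or np.any(np.isnan(state.I)):
        raise FloatingPointError(f"NaN in state at t={state.t} ms")
    p = np.clip(state.A, 0.0, 1.0)
    spiked = rng.random(len(p)) < p
    state.A[spiked] = A_reset[spiked]
    state.S = spiked
    state.t += DT_MS
    return state


def run_simulation(
    network: GridNetwork,
    params: NeuronParams | None = None,
    protocol: StimulusProtocol | None = None,
    n_steps: int = 10_000,
    seed: int = 0,
    weights: SynapticWeights | None = None,
    record_spikes: bool = True,
) -> SpikeRaster:
    """Simulate a network for ``n_steps`` ms.

    Deterministic given (network, protocol, seed): the dynamics noise and the
    stimulus bookkeeping (target subset, inter-stimulus intervals) use two
    independent child streams of ``seed``, so stimulus placement is
    reproducible independently of the dynamics draws.

    Returns a :class:`SpikeRaster`; per-type spike counts are always
    recorded, the full sparse spike matrix only when ``record_spikes``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if params is None:
        params = NeuronParams()
    if weights is None:
        weights = SynapticWeights(**network.weights_by_type)

    ss = np.random.SeedSequence(seed)
    child_dyn, child_stim = ss.spawn(2)
    rng_dyn = np.random.default_rng(child_dyn)
    rng_stim = np.random.default_rng(child_stim)

    n = network.n_neurons
    W = network.connection_matrix()
    exc_mask, tau_P, A0, A_reset = _per_type_vectors(network, params)

    if protocol is not None and protocol.n_stimulated > 0:
        targets = protocol.draw_targets(network, rng_stim)
        stim_times = protocol.draw_stim_times(n_steps, rng_stim)
        stim_vec = np.zeros(n)
        stim_vec[targets] = weights.effective_input
        stim_set = set(stim_times.tolist())
    else:
        targets = np.empty(0, dtype=np.int64)
        stim_times = np.empty(0, dtype=np.int64)
        stim_vec = None
        stim_set = set()

    state = SimState.zeros(n)
    counts_exc = np.zeros(n_steps, dtype=np.int64)
    counts_inh = np.zeros(n_steps, dtype=np.int64)
    ev_t: list[np.ndarray] = []
    ev_id: list[np.ndarray] = []

    for t in range(n_steps):
        inc = stim_vec if t in stim_set else None
        step(state, W, params, rng_dyn, tau_P, A0, A_reset, stim_increment=inc)
        spiked = state.S
        counts_exc[t] = int(np.count_nonzero(spiked & exc_mask))
        counts_inh[t] = int(np.count_nonzero(spiked & ~exc_mask))
        if record_spikes and counts_exc[t] + counts_inh[t]:
            ids = np.flatnonzero(spiked)
            ev_t.append(np.full(len(ids), t, dtype=np.int32))
            ev_id.append(ids.astype(np.int32))

    if record_spikes:
        if ev_t:
            rows = np.concatenate(ev_t)
            cols = np.concatenate(ev_id)
            data = np.ones(len(rows), dtype=np.int8)
        else:
            rows = cols = np.empty(0, dtype=np.int32)
            data = np.empty(0, dtype=np.int8)
        spikes = csr_matrix((data, (rows, cols)), shape=(n_steps, n))
    else:
        spikes = None

    config = {
        "CE": network.params.CE,
        "CI": network.params.CI,
        "n_steps": n_steps,
        "seed": seed,
        "n_stimulated": int(protocol.n_stimulated) if protocol else 0,
        "input_multiplier": weights.input_multiplier,
    }
    return SpikeRaster(
        spikes=spikes,
        counts_exc=counts_exc,
        counts_inh=counts_inh,
        stim_times=stim_times,
        stim_targets=targets,
        n_steps=n_steps,
        n_neurons=n,
        seed=seed,
        config=config,
    )


def save_raster(raster: SpikeRaster, path: str) -> None:
    """Store a raster.

    ``.npz``: compressed binary container (counts, stim bookkeeping, sparse
    events, config). Anything else: sparse text event list — a ``#`` JSON
    config header then TSV (t_ms, neuron_id) rows.
    """
    if str(path).endswith(".npz"):
        if raster.spikes is not None:
            ev = raster.to_events()
        else:
            ev = np.empty((0, 2), dtype=np.int64)
        np.savez_compressed(
            path,
            counts_exc=raster.counts_exc,
            counts_inh=raster.counts_inh,
            stim_times=raster.stim_times,
            stim_targets=raster.stim_targets,
            events=ev,
            has_spikes=np.array(raster.spikes is not None),
            n_steps=raster.n_steps,
            n_neurons=raster.n_neurons,
            seed=raster.seed,
            config=json.dumps(raster.config),
        )
        return
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(
            {**raster.config, "n_neurons": raster.n_neurons,
             "stim_times": raster.stim_times.tolist()}) + "\n")
        fh.write("t_ms\tneuron_id\n")
        for t, i in raster.to_events():
            fh.write(f"{t}\t{i}\n")


def load_raster(path: str) -> SpikeRaster:
    """Load a ``.npz`` raster written by :func:`save_raster`."""
    z = np.load(path, allow_pickle=False)
    n_steps = int(z["n_steps"])
    n_neurons = int(z["n_neurons"])
    if bool(z["has_spikes"]):
        ev = z["events"]
        spikes = csr_matrix(
            (np.ones(len(ev), dtype=np.int8), (ev[:, 0], ev[:, 1])),
            shape=(n_steps, n_neurons),
        )
    else:
        spikes = None
    return SpikeRaster(
        spikes=spikes,
        counts_exc=z["counts_exc"],
        counts_inh=z["counts_inh"],
        stim_times=z["stim_times"],
        stim_targets=z["stim_targets"],
        n_steps=n_steps,
        n_neurons=n_neurons,
        seed=int(z["seed"]),
        config=json.loads(str(z["config"])),
    )
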