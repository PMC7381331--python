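"""Network graph of neural buffers and associative memories, plus the
simulation engine.

Components
----------
``StateBuffer``
    An array of scalar LIF ensembles jointly encoding one vector; recurrent
    buffers feed their decoded value back to themselves through a slow
    synapse and act as working memories.
``AssociativeMemory``
    A bank of thresholded channels between two buffers.  Channel *i* computes
    the dot product of the input vector with input prototype *i*, rectifies
    it above a threshold, and emits output prototype *i* scaled by the
    rectified value.  With ``winner_take_all`` the channels mutually inhibit
    each other, which turns the memory into a cleanup: only the best-matching
    prototype survives.

Backends
--------
``spiking``
    Full leaky integrate-and-fire dynamics at the configured ``dt``.
``direct``
    The same graph, synaptic filters, thresholds and ablation masks, but
    neurons emit their static rate curves instead of spikes.  This backend is
    deterministic and fast and is used for oracles and large experiment
    grids; ablating a neuron zeroes its decoder contribution identically in
    both backends.

For speed the engine compiles the whole graph into flat arrays: one global
signal vector (the concatenated decoded outputs of all components), one
global neuron population, and a few sparse connection matrices grouped by
synapse time constant and gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .nef import EnsembleArray, LIFParams, lif_rate

__all__ = [
    "StateBuffer",
    "AssociativeMemory",
    "Connection",
    "InputEvent",
    "AblationSpec",
    "SimilarityTrace",
    "Network",
    "Simulator",
    "apply_ablation",
    "run_network",
]

PROBE_TAU = 0.01


@dataclass
class StateBuffer:
    name: str
    dims: int
    n_per: int = 50
    recurrent: bool = False
    radius: float = 1.0
    feedback: float = 0.95
    tau_feedback: float = 0.1

    @property
    def signal_dims(self) -> int:
        return self.dims

    @property
    def n_neurons(self) -> int:
        return self.dims * self.n_per


@dataclass
class AssociativeMemory:
    name: str
    in_vectors: np.ndarray  # (N, D_in) input prototypes
    out_vectors: np.ndarray  # (N, D_out) output prototypes
    threshold: float = 0.3
    winner_take_all: bool = False
    n_per: int = 50
    inhibit: float = 2.0
    ramp: "float | None" = None  # rise width of the channel rectifier
    radius: float = 2.0  # channel representation range
    fmax: float = 2.0  # rectifier output ceiling

    def __post_init__(self) -> None:
        if self.ramp is None:
            self.ramp = 1.0 - self.threshold
        self.in_vectors = np.atleast_2d(np.asarray(self.in_vectors, dtype=float))
        self.out_vectors = np.atleast_2d(np.asarray(self.out_vectors, dtype=float))
        if len(self.in_vectors) != len(self.out_vectors):
            raise ValueError(
                f"associative memory {self.name!r}: {len(self.in_vectors)} input "
                f"vs {len(self.out_vectors)} output prototypes"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("activation threshold must lie in (0, 1)")

    @property
    def n_channels(self) -> int:
        return len(self.in_vectors)

    @property
    def signal_dims(self) -> int:
        return self.n_channels

    @property
    def n_neurons(self) -> int:
        return self.n_channels * self.n_per


@dataclass(frozen=True)
class Connection:
    source: str
    target: str
    transform: "np.ndarray | float" = 1.0  # acts in vector space
    synapse: float = 0.01
    gate: "str | None" = None


@dataclass(frozen=True)
class InputEvent:
    """Piecewise-constant external input: ``vector`` driven into ``target``
    during ``[t_start, t_end)``."""

    target: str
    vector: np.ndarray
    t_start: float
    t_end: float


@dataclass(frozen=True)
class AblationSpec:
    """Silence ``floor(fraction * n_neurons)`` seeded-random neurons of one
    component for an entire run."""

    target: str
    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("ablation fraction must lie in [0, 1]")


@dataclass
class SimilarityTrace:
    """Per-label dot products of a buffer's decoded content over time."""

    buffer: str
    time: np.ndarray
    labels: list[str]
    values: np.ndarray  # (T, L)

    def label_series(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self):
        import pandas as pd

        rows = {
            "time": np.repeat(self.time, len(self.labels)),
            "buffer": self.buffer,
            "label": np.tile(self.labels, len(self.time)),
            "similarity": self.values.ravel(),
        }
        return pd.DataFrame(rows)


class Network:
    """A named collection of components and decoded connections."""

    def __init__(self, params: "LIFParams | None" = None, seed: int = 0):
        self.params = params or LIFParams()
        self.seed = seed
        self.components: dict[str, StateBuffer | AssociativeMemory] = {}
        self.connections: list[Connection] = []

    # -- construction ---------------------------------------------------

    def add_buffer(
        self,
        name: str,
        dims: int,
        n_per: int = 50,
        recurrent: bool = False,
        radius: float = 1.0,
        feedback: float = 0.95,
        tau_feedback: float = 0.1,
    ) -> StateBuffer:
        if dims < 1:
            raise ValueError(f"buffer {name!r}: dims must be >= 1")
        if name in self.components:
            raise ValueError(f"duplicate component name: {name!r}")
        buf = StateBuffer(name, dims, n_per, recurrent, radius, feedback, tau_feedback)
        self.components[name] = buf
        if recurrent:
            self.connections.append(
                Connection(name, name, transform=feedback, synapse=tau_feedback)
            )
        return buf

    def add_assoc_memory(
        self,
        name: str,
        in_vectors: np.ndarray,
        out_vectors: np.ndarray,
        threshold: float = 0.3,
        winner_take_all: bool = False,
        n_per: int = 50,
        inhibit: float = 2.0,
        ramp: "float | None" = None,
        radius: float = 2.0,
        fmax: float = 2.0,
        lateral_synapse: float = 0.01,
    ) -> AssociativeMemory:
        if name in self.components:
            raise ValueError(f"duplicate component name: {name!r}")
        am = AssociativeMemory(
            name, in_vectors, out_vectors, threshold, winner_take_all, n_per,
            inhibit, ramp, radius, fmax,
        )
        self.components[name] = am
        if inhibit > 0.0:
            n = am.n_channels
            lateral = -am.inhibit * (np.ones((n, n)) - np.eye(n))
            self.connections.append(
                Connection(name, name, transform=lateral, synapse=lateral_synapse)
            )
        return am

    def connect(
        self,
        source: str,
        target: str,
        transform: "np.ndarray | float" = 1.0,
        synapse: float = 0.01,
        gate: "str | None" = None,
    ) -> Connection:
        for nm in (source, target):
            if nm not in self.components:
                raise KeyError(
                    f"unknown component {nm!r}; valid: {sorted(self.components)}"
                )
        conn = Connection(source, target, transform, synapse, gate)
        self.connections.append(conn)
        return conn

    @property
    def gates(self) -> list[str]:
        return sorted({c.gate for c in self.connections if c.gate is not None})

    def summary(self) -> dict:
        """Component census: names, kinds, and neuron counts."""
        comps = {}
        for name, comp in self.components.items():
            kind = (
                "buffer"
                if isinstance(comp, StateBuffer)
                else ("cleanup" if comp.winner_take_all else "assoc_memory")
            )
            comps[name] = {"kind": kind, "n_neurons": comp.n_neurons}
        return {
            "components": comps,
            "n_connections": len(self.connections),
            "n_neurons": sum(c.n_neurons for c in self.components.values()),
        }


def _vector_space_maps(comp) -> tuple["np.ndarray | None", "np.ndarray | None"]:
    """(input map, output map) between vector space and the component's
    internal signal space; ``None`` stands for identity."""
    if isinstance(comp, AssociativeMemory):
        return comp.in_vectors, comp.out_vectors.T
    return None, None


class Simulator:
    """Compiled state of a :class:`Network` that can be reset, ablated, and
    stepped under either backend."""

    def __init__(
        self,
        network: Network,
        dt: "float | None" = None,
        backend: str = "spiking",
        seed: "int | None" = None,
    ):
        if backend not in ("spiking", "direct"):
            raise ValueError(f"unknown backend: {backend!r}")
        self.network = network
        self.params = network.params
        self.dt = float(dt if dt is not None else self.params.dt)
        self.backend = backend
        self.seed = network.seed if seed is None else seed
        self._build()

    # -- compilation ----------------------------------------------------

    def _build(self) -> None:
        net = self.network
        self.names = list(net.components)
        self.slices: dict[str, slice] = {}
        self.ensembles: dict[str, EnsembleArray] = {}
        offset = 0
        master = np.random.SeedSequence(self.seed)
        children = master.spawn(len(self.names))
        for name, ss in zip(self.names, children):
            comp = net.components[name]
            self.slices[name] = slice(offset, offset + comp.signal_dims)
            offset += comp.signal_dims
            rng = np.random.default_rng(ss)
            if isinstance(comp, StateBuffer):
                ea = EnsembleArray(
                    comp.dims, comp.n_per, self.params, rng, radius=comp.radius
                )
            else:
                theta, ramp, fmax = comp.threshold, comp.ramp, comp.fmax

                def thresh(x, theta=theta, ramp=ramp, fmax=fmax):
                    return np.clip((x - theta) / ramp, 0.0, fmax)

                ea = EnsembleArray(
                    comp.n_channels,
                    comp.n_per,
                    self.params,
                    rng,
                    radius=comp.radius,
                    intercept_range=(theta / comp.radius, 0.9),
                    encoders="positive",
                    target_fn=thresh,
                )
            self.ensembles[name] = ea
        self.n_signals = offset

        # global neuron arrays
        w_enc, bias, dim_idx, dec_rows, dec_cols, dec_vals = [], [], [], [], [], []
        self.neuron_slices: dict[str, slice] = {}
        n_off = 0
        for name in self.names:
            ea = self.ensembles[name]
            sl = self.slices[name]
            n = ea.n_neurons
            self.neuron_slices[name] = slice(n_off, n_off + n)
            w_enc.append((ea.gain * ea.enc / ea.radius).ravel())
            bias.append(ea.bias.ravel())
            dim_idx.append(np.repeat(np.arange(sl.start, sl.stop), ea.n_per))
            dec_rows.append(np.repeat(np.arange(sl.start, sl.stop), ea.n_per))
            dec_cols.append(np.arange(n_off, n_off + n))
            dec_vals.append(ea.decoders.ravel())
            n_off += n
        self.n_neurons = n_off
        self.w_enc = np.concatenate(w_enc)
        self.bias = np.concatenate(bias)
        self.dim_idx = np.concatenate(dim_idx)
        self.decode_matrix = sp.csr_matrix(
            (
                np.concatenate(dec_vals),
                (np.concatenate(dec_rows), np.concatenate(dec_cols)),
            ),
            shape=(self.n_signals, self.n_neurons),
        )
        self.mask = np.ones(self.n_neurons)

        # connection groups keyed by (synapse, gate)
        groups: dict[tuple[float, "str | None"], list] = {}
        for conn in net.connections:
            src, tgt = net.components[conn.source], net.components[conn.target]
            _, out_map = _vector_space_maps(src)
            in_map, _ = _vector_space_maps(tgt)
            T = conn.transform
            if np.isscalar(T):
                if conn.source == conn.target and isinstance(src, AssociativeMemory):
                    # channel-space self connection
                    eff = float(T) * np.eye(src.n_channels)
                    out_map = in_map = None
                else:
                    d_src = (
                        out_map.shape[0] if out_map is not None else src.signal_dims
                    )
                    eff = float(T) * np.eye(d_src)
            else:
                eff = np.asarray(T, dtype=float)
                if conn.source == conn.target and eff.shape == (
                    src.signal_dims,
                    src.signal_dims,
                ):
                    out_map = in_map = None  # lateral, already in signal space
            if out_map is not None:
                eff = eff @ out_map
            if in_map is not None:
                eff = in_map @ eff
            key = (float(conn.synapse), conn.gate)
            groups.setdefault(key, []).append((conn, eff))

        self.groups = []
        for (tau, gate), items in groups.items():
            rows, cols, vals = [], [], []
            for conn, eff in items:
                r0 = self.slices[conn.target].start
                c0 = self.slices[conn.source].start
                rr, cc = np.nonzero(eff)
                rows.append(rr + r0)
                cols.append(cc + c0)
                vals.append(eff[rr, cc])
            W = sp.csr_matrix(
                (
                    np.concatenate(vals) if vals else [],
                    (
                        np.concatenate(rows) if rows else [],
                        np.concatenate(cols) if cols else [],
                    ),
                ),
                shape=(self.n_signals, self.n_signals),
            )
            self.groups.append((tau, gate, W))

        self.taus = sorted({g[0] for g in self.groups} | {PROBE_TAU})

        # direct-backend function tables: buffers clip per dimension at
        # their radius; associative-memory channels apply the thresholded
        # rectifier.  Ablated components fall back to masked rate decoding.
        self._clip = np.empty(self.n_signals)
        self._is_am = np.zeros(self.n_signals, dtype=bool)
        self._theta = np.zeros(self.n_signals)
        self._inv_ramp = np.ones(self.n_signals)
        self._fmax = np.zeros(self.n_signals)
        for name in self.names:
            comp = self.network.components[name]
            sl = self.slices[name]
            if isinstance(comp, StateBuffer):
                self._clip[sl] = comp.radius
            else:
                self._clip[sl] = comp.radius
                self._is_am[sl] = True
                self._theta[sl] = comp.threshold
                self._inv_ramp[sl] = 1.0 / comp.ramp
                self._fmax[sl] = comp.fmax
        self.reset()

    # -- state ----------------------------------------------------------

    def reset(self) -> None:
        self.voltage = np.zeros(self.n_neurons)
        self.refractory = np.zeros(self.n_neurons)
        self.filters = {tau: np.zeros(self.n_signals) for tau in self.taus}
        self.time = 0.0
        if not hasattr(self, "_ablated_comps"):
            self._ablated_comps = set()

    def clear_ablations(self) -> None:
        self.mask[:] = 1.0
        self._ablated_comps: set[str] = set()

    def ablate(self, spec: AblationSpec) -> None:
        """Apply an ablation on top of the current mask."""
        if spec.target not in self.neuron_slices:
            raise KeyError(
                f"unknown ablation target {spec.target!r}; "
                f"valid targets: {sorted(self.neuron_slices)}"
            )
        sl = self.neuron_slices[spec.target]
        n = sl.stop - sl.start
        k = int(np.floor(spec.fraction * n))
        rng = np.random.default_rng(spec.seed)
        idx = rng.choice(n, size=k, replace=False)
        self.mask[sl.start + idx] = 0.0
        if k:
            if not hasattr(self, "_ablated_comps"):
                self._ablated_comps = set()
            self._ablated_comps.add(spec.target)

    # -- running --------------------------------------------------------

    def run(
        self,
        duration: float,
        events: "list[InputEvent] | None" = None,
        controller=None,
        probes: "list[str] | None" = None,
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Advance the simulation, returning probed decoded signals.

        Returns a mapping ``component -> (times, values)`` where ``values``
        has one row per step and one column per signal dimension (the decoded
        vector for buffers, channel activations for associative memories).
        """
        dt = self.dt
        if duration < dt:
            raise ValueError("duration must be at least one time step")
        n_steps = int(round(duration / dt))
        events = events or []
        probes = probes or []
        for ev in events:
            if ev.target not in self.slices:
                raise KeyError(f"unknown input target {ev.target!r}")

        # compile piecewise-constant external input
        bounds = sorted(
            {0.0, duration}
            | {min(max(ev.t_start - self.time, 0.0), duration) for ev in events}
            | {min(max(ev.t_end - self.time, 0.0), duration) for ev in events}
        )
        seg_vectors = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            u = np.zeros(self.n_signals)
            mid = self.time + 0.5 * (lo + hi)
            for ev in events:
                if ev.t_start <= mid < ev.t_end:
                    comp = self.network.components[ev.target]
                    in_map, _ = _vector_space_maps(comp)
                    vec = np.asarray(ev.vector, dtype=float)
                    if in_map is not None:
                        vec = in_map @ vec
                    u[self.slices[ev.target]] += vec
            seg_vectors.append(u)
        seg_edges = np.array(bounds[1:])

        alphas = {tau: 1.0 - np.exp(-dt / tau) for tau in self.taus}
        gate_values: dict[str, float] = {g: 0.0 for g in self.network.gates}

        probe_out = {
            name: np.empty(
                (n_steps, self.slices[name].stop - self.slices[name].start)
            )
            for name in probes
        }
        times = self.time + dt * (np.arange(n_steps) + 1)

        spiking = self.backend == "spiking"
        seg = 0
        filters = self.filters
        for k in range(n_steps):
            t_local = (k + 0.5) * dt
            while t_local > seg_edges[seg]:
                seg += 1
            u = seg_vectors[seg].copy()
            for tau, gate, W in self.groups:
                if gate is None:
                    u += W @ filters[tau]
                else:
                    gv = gate_values.get(gate, 0.0)
                    if gv:
                        u += gv * (W @ filters[tau])

            if controller is not None:
                state = {
                    name: filters[PROBE_TAU][self.slices[name]]
                    for name in controller.watch
                }
                gates_new, inputs = controller(self.time + t_local, state)
                gate_values.update(gates_new)
                for name, vec in inputs.items():
                    comp = self.network.components[name]
                    in_map, _ = _vector_space_maps(comp)
                    v = in_map @ vec if in_map is not None else vec
                    u[self.slices[name]] += v

            if spiking:
                J = self.w_enc * u[self.dim_idx] + self.bias
                # exact integration of the membrane equation over the step,
                # with sub-step refractory and spike-time handling
                self.refractory -= dt
                delta = np.clip(dt - self.refractory, 0.0, dt)
                v = self.voltage
                v -= (J - v) * np.expm1(-delta / self.params.tau_m)
                np.maximum(v, 0.0, out=v)
                spiked = v > 1.0
                t_spike = dt + self.params.tau_m * np.log1p(
                    -(v[spiked] - 1.0) / (J[spiked] - 1.0)
                )
                self.refractory[spiked] = self.params.tau_ref + t_spike
                v[spiked] = 0.0
                activity = (spiked * self.mask) / dt
                y = self.decode_matrix @ activity
            else:
                y = np.clip(u, -self._clip, self._clip)
                am = self._is_am
                y[am] = np.clip(
                    (u[am] - self._theta[am]) * self._inv_ramp[am],
                    0.0,
                    self._fmax[am],
                )
                for name in self._ablated_comps:
                    sl = self.slices[name]
                    ea = self.ensembles[name]
                    m = self.mask[self.neuron_slices[name]].reshape(
                        ea.dims, ea.n_per
                    )
                    y[sl] = np.einsum(
                        "dn,dn->d", ea.decoders, ea.rates(u[sl]) * m
                    )

            for tau in self.taus:
                f = filters[tau]
                f += alphas[tau] * (y - f)

            for name in probes:
                probe_out[name][k] = filters[PROBE_TAU][self.slices[name]]

        self.time += n_steps * dt
        return {name: (times, probe_out[name]) for name in probes}

    def similarity_trace(
        self,
        name: str,
        times: np.ndarray,
        values: np.ndarray,
        vocab,
        labels: "list[str] | None" = None,
    ) -> SimilarityTrace:
        """Project a probed buffer signal onto vocabulary pointers."""
        labels = vocab.labels if labels is None else labels
        M = vocab.matrix(labels)
        return SimilarityTrace(name, times, labels, values @ M.T)


def apply_ablation(sim: Simulator, spec: AblationSpec) -> Simulator:
    """Permanently silence a seeded random fraction of one component's
    neurons (cumulative with previously applied ablations)."""
    sim.ablate(spec)
    return sim


def run_network(
    network: Network,
    events: list[InputEvent],
    duration: float,
    dt: "float | None" = None,
    backend: str = "spiking",
    seed: "int | None" = None,
    probes: "list[str] | None" = None,
    controller=None,
    ablations: "list[AblationSpec] | None" = None,
) -> tuple[Simulator, dict]:
    """One-shot convenience wrapper: compile, ablate, run, return probes."""
    sim = Simulator(network, dt=dt, backend=backend, seed=seed)
    for spec in ablations or []:
        sim.ablate(spec)
    out = sim.run(duration, events=events, controller=controller, probes=probes)
    return sim, out
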