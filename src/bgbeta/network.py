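"""Network assembly and simulation: random connectivity, delayed spike
delivery, Poisson external drive, and the main fixed-step RK4 loop.

A :class:`Network` is an ordered set of neuron populations (contiguous
blocks of a flat neuron index), a list of realized random connections and
the per-neuron external Poisson drives.  `run_simulation` integrates it
with the numba kernel in :mod:`bgbeta._engine` and returns a
:class:`SpikeRaster` with the warm-up interval removed.

Randomness is split into two independent concerns, each seeded from the
master seed through `numpy.random.SeedSequence`: the *structure* stream
(connectivity realization, external-weight jitter, observer subsamples,
drawn once at build time) and the *dynamics* stream (initial conditions
and Poisson arrivals, drawn per run).  Identical seeds reproduce rasters
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _engine
from .neurons import NeuronParams, NumericalDivergenceError, ConfigurationError

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "PoissonDrive",
    "SpikeRaster",
    "Network",
    "build_connections",
    "sample_poisson_drive",
    "run_simulation",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One neuron population: name, size and shared parameters."""

    name: str
    size: int
    params: NeuronParams
    is_auxiliary: bool = False

    def __post_init__(self):
        if self.size < 1:
            raise ConfigurationError(f"population {self.name}: size must be >= 1")


@dataclass(frozen=True)
class ConnectionSpec:
    """One random-connectivity rule between two populations.

    Each ordered (source, target) neuron pair is connected with
    independent probability ``p``; every realized synapse carries the same
    delay, sign and weight.  Autapses are excluded when source == target.
    """

    source: str
    target: str
    p: float
    delay: float        # ms
    sign: str           # "E" | "I"
    weight: float       # nS

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(f"{self.source}->{self.target}: p outside [0,1]")
        if self.delay < 0:
            raise ConfigurationError(f"{self.source}->{self.target}: negative delay")
        if self.weight < 0:
            raise ConfigurationError(f"{self.source}->{self.target}: negative weight")
        if self.sign not in ("E", "I"):
            raise ConfigurationError(f"{self.source}->{self.target}: sign must be E or I")


@dataclass
class PoissonDrive:
    """Per-neuron independent Poisson input for one population.

    ``rate`` is the mean event rate in kHz (events per ms).  The synaptic
    weight of each neuron's drive is drawn once at build time, uniformly
    on [weight - dev, weight + dev] (floored at 0).
    """

    population: str
    rate: float
    weight: float
    dev: float = 0.0

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError(f"drive {self.population}: negative rate")


class SpikeRaster:
    """Spike times (ms, warm-up removed) with population bookkeeping."""

    def __init__(self, times, ids, pop_slices, duration, warmup):
        self.times = np.asarray(times, dtype=float)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.pop_slices = dict(pop_slices)   # name -> (start, stop)
        self.duration = float(duration)
        self.warmup = float(warmup)

    def __len__(self):
        return self.times.size

    def population(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, ids) of one population's spikes."""
        lo, hi = self.pop_slices[name]
        m = (self.ids >= lo) & (self.ids < hi)
        return self.times[m], self.ids[m]

    def mean_rate(self, name: str) -> float:
        """Population mean firing rate in Hz over the retained window."""
        lo, hi = self.pop_slices[name]
        n_spk = int(np.count_nonzero((self.ids >= lo) & (self.ids < hi)))
        return 1000.0 * n_spk / ((hi - lo) * self.duration)

    def to_tsv(self, path) -> None:
        """Write a 3-column TSV: time_ms, population, neuron_id."""
        names = sorted(self.pop_slices, key=lambda k: self.pop_slices[k][0])
        starts = np.array([self.pop_slices[k][0] for k in names])
        idx = np.searchsorted(starts, self.ids, side="right") - 1
        with open(path, "w") as fh:
            fh.write("time_ms\tpopulation\tneuron_id\n")
            for t, i, j in zip(self.times, self.ids, idx):
                fh.write(f"{t:.1f}\t{names[j]}\t{i}\n")


def build_connections(
    spec: ConnectionSpec,
    n_source: int,
    n_target: int,
    rng: np.random.Generator,
    self_connection: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Realize one connection as CSR (indptr over sources, flat targets).

    One Bernoulli(p) trial per ordered pair; for a self-connected
    population (``self_connection``) the diagonal is excluded, so a neuron
    never contacts itself.  Expected edge count is p * n_source * n_target
    (minus the diagonal for self connections).
    """
    n_avail = n_target - 1 if self_connection else n_target
    if spec.p == 0.0 or n_avail <= 0:
        return np.zeros(n_source + 1, dtype=np.int64), np.empty(0, dtype=np.int32)
    ks = rng.binomial(n_avail, spec.p, size=n_source)
    indptr = np.zeros(n_source + 1, dtype=np.int64)
    np.cumsum(ks, out=indptr[1:])
    sub_seed = int(rng.integers(2**31))
    targets = _engine.sample_subsets(ks.astype(np.int64), n_avail, sub_seed)
    if self_connection:
        # diagonal excluded: targets were drawn from n-1 slots, shift the
        # slots at or above each source index up by one
        src_per_edge = np.repeat(np.arange(n_source), ks)
        targets = np.where(targets >= src_per_edge, targets + 1, targets)
    return indptr, targets.astype(np.int32)


def sample_poisson_drive(
    drive: PoissonDrive, h: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Independent Poisson(rate*h) event counts for one step of length h."""
    return rng.poisson(drive.rate * h, size=size)


class Network:
    """A fully built network, ready to simulate.

    Parameters
    ----------
    populations : ordered sequence of PopulationSpec
    connections : ConnectionSpecs between the populations
    drives : per-population PoissonDrive (at most one each)
    seed : master seed for the structure stream
    observer_sizes : optional dict name -> number of neurons observed for
        rate/PSD analysis (defaults to the whole population); the
        subsample is drawn once here, so it is fixed across runs.
    """

    def __init__(
        self,
        populations: Sequence[PopulationSpec],
        connections: Iterable[ConnectionSpec],
        drives: Iterable[PoissonDrive],
        seed: int = 0,
        observer_sizes: Optional[dict] = None,
    ):
        self.populations = list(populations)
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("population names must be unique")
        self.connections = list(connections)
        self.drives = list(drives)
        self.seed = int(seed)

        starts = np.cumsum([0] + [p.size for p in self.populations])
        self.pop_start = starts.astype(np.int64)
        self.pop_slices = {
            p.name: (int(starts[i]), int(starts[i + 1]))
            for i, p in enumerate(self.populations)
        }
        self.n_neurons = int(starts[-1])

        for c in self.connections:
            for nm in (c.source, c.target):
                if nm not in self.pop_slices:
                    raise ConfigurationError(f"unknown population {nm!r}")
        for d in self.drives:
            if d.population not in self.pop_slices:
                raise ConfigurationError(f"unknown population {d.population!r}")

        ss = np.random.SeedSequence(self.seed)
        key_conn, key_drive, key_obs = ss.spawn(3)
        self._realize_connections(key_conn)
        self._realize_drives(key_drive)
        self._draw_observers(key_obs, observer_sizes or {})

    # -- structure -----------------------------------------------------

    def _realize_connections(self, key) -> None:
        conn_rngs = [np.random.default_rng(s) for s in key.spawn(max(1, len(self.connections)))]
        self.conn_edges = []       # per connection: (indptr, targets) global ids
        outdeg = np.zeros(self.n_neurons, dtype=np.int64)
        for c, rng in zip(self.connections, conn_rngs):
            s_lo, s_hi = self.pop_slices[c.source]
            t_lo, t_hi = self.pop_slices[c.target]
            indptr, tgt = build_connections(
                c, s_hi - s_lo, t_hi - t_lo, rng,
                self_connection=(c.source == c.target),
            )
            tgt = tgt.astype(np.int32) + np.int32(t_lo)
            self.conn_edges.append((indptr, tgt))
            outdeg[s_lo:s_hi] += np.diff(indptr)

        self.out_indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
        np.cumsum(outdeg, out=self.out_indptr[1:])
        n_edges = int(self.out_indptr[-1])
        self.out_tgt = np.empty(n_edges, dtype=np.int32)
        self.out_conn = np.empty(n_edges, dtype=np.int32)
        fill = self.out_indptr[:-1].copy()
        for ci, (c, (indptr, tgt)) in enumerate(zip(self.connections, self.conn_edges)):
            s_lo, s_hi = self.pop_slices[c.source]
            ks = np.diff(indptr)
            if tgt.size == 0:
                continue
            src_per_edge = np.repeat(np.arange(s_lo, s_hi, dtype=np.int64), ks)
            local = np.arange(tgt.size, dtype=np.int64) - np.repeat(indptr[:-1], ks)
            pos = fill[src_per_edge] + local
            self.out_tgt[pos] = tgt
            self.out_conn[pos] = ci
            fill[s_lo:s_hi] += ks

    def _realize_drives(self, key) -> None:
        rng = np.random.default_rng(key)
        self.ext_rate = np.zeros(self.n_neurons)      # events per ms (kHz)
        self.ext_weight = np.zeros(self.n_neurons)
        for d in self.drives:
            lo, hi = self.pop_slices[d.population]
            self.ext_rate[lo:hi] = d.rate
            self.ext_weight[lo:hi] = np.clip(
                rng.uniform(d.weight - d.dev, d.weight + d.dev, size=hi - lo),
                0.0, None,
            )

    def _draw_observers(self, key, observer_sizes: dict) -> None:
        rng = np.random.default_rng(key)
        self.observers = {}
        for p in self.populations:
            lo, hi = self.pop_slices[p.name]
            n_obs = int(observer_sizes.get(p.name, p.size))
            if n_obs >= p.size:
                self.observers[p.name] = np.arange(lo, hi, dtype=np.int64)
            else:
                self.observers[p.name] = np.sort(
                    rng.choice(np.arange(lo, hi), size=n_obs, replace=False)
                ).astype(np.int64)

    # -- convenience ---------------------------------------------------

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def expected_in_degree(self, conn: ConnectionSpec) -> float:
        src = self.population(conn.source)
        n = src.size - 1 if conn.source == conn.target else src.size
        return conn.p * n

    def total_edges(self) -> int:
        return int(self.out_indptr[-1])


def _param_matrix(populations, h):
    P = len(populations)
    par = np.zeros((P, len(_engine.PAR_COLS)))
    C = _engine.COL
    for i, pop in enumerate(populations):
        q = pop.params
        par[i, C["variant"]] = {"aeif": 0, "aqif": 1, "aqif2": 2}[q.model_variant]
        par[i, C["C_inv"]] = 1.0 / q.C_m
        par[i, C["E_L"]] = q.E_L
        par[i, C["E_ex"]] = q.E_ex
        par[i, C["E_in"]] = q.E_in
        par[i, C["V_th"]] = q.V_th
        par[i, C["I_e"]] = q.I_e
        par[i, C["a"]] = q.a
        par[i, C["inv_tau_w"]] = 1.0 / q.tau_w
        par[i, C["g_L"]] = q.g_L or 0.0
        par[i, C["Delta_T"]] = q.Delta_T or 1.0
        par[i, C["inv_Delta_T"]] = 1.0 / (q.Delta_T or 1.0)
        par[i, C["k"]] = q.k or 0.0
        par[i, C["V_b"]] = q.V_b if q.V_b is not None else 0.0
        par[i, C["V_reset"]] = q.V_reset
        par[i, C["V_peak"]] = q.V_peak
        par[i, C["b"]] = q.b
        par[i, C["t_ref"]] = q.t_ref
        par[i, C["c2e"]:C["cne"] + 1] = _engine.stage_coefficients(q.tau_ex, h)
        par[i, C["c2i"]:C["cni"] + 1] = _engine.stage_coefficients(q.tau_in, h)
    return par


def run_simulation(
    network: Network,
    duration: float = 10000.0,
    warmup: float = 500.0,
    h: float = 0.1,
    seed: int = 0,
    record: Optional[Sequence[int]] = None,
):
    """Simulate the network and return its spike raster.

    Integrates ``warmup + duration`` ms at fixed step ``h`` and discards
    the warm-up from the returned raster (spike times are shifted so the
    retained window is [0, duration]).  ``seed`` controls the dynamics
    stream only; the network structure is fixed at build time.

    If ``record`` lists global neuron indices, the per-step traces of
    V, g_ex, g_in and w for those neurons are returned alongside the
    raster as a dict of (n_rec, n_steps) arrays.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    n_steps = int(round((duration + warmup) / h))
    par = _param_matrix(network.populations, h)

    # connection metadata; delays rounded to the step grid
    C = max(1, len(network.connections))
    conn_delay = np.zeros(C, dtype=np.int64)
    conn_weight = np.zeros(C)
    conn_is_ex = np.zeros(C, dtype=np.int8)
    for i, c in enumerate(network.connections):
        conn_delay[i] = int(round(c.delay / h))
        conn_weight[i] = c.weight
        conn_is_ex[i] = 1 if c.sign == "E" else 0
    ring_len = int(conn_delay.max()) + 2

    ss = np.random.SeedSequence([network.seed, int(seed), 0x5D])
    init_key, kernel_key = ss.spawn(2)
    rng = np.random.default_rng(init_key)
    kernel_seed = int(kernel_key.generate_state(1, dtype=np.uint32)[0] % (2**31))

    V = np.empty(network.n_neurons)
    for pop in network.populations:
        lo, hi = network.pop_slices[pop.name]
        V[lo:hi] = pop.params.E_L + rng.uniform(-5.0, 5.0, size=hi - lo)
    w = np.zeros(network.n_neurons)
    g_ex = np.zeros(network.n_neurons)
    g_in = np.zeros(network.n_neurons)

    rec_ids = np.asarray(record if record is not None else [], dtype=np.int64)
    rec = {
        name: np.zeros((rec_ids.size, n_steps), dtype=np.float32)
        for name in ("V", "g_ex", "g_in", "w")
    }

    cap = max(1_000_000, int(network.n_neurons * (duration + warmup) * 0.012))
    while True:
        spike_step = np.empty(cap, dtype=np.int32)
        spike_id = np.empty(cap, dtype=np.int32)
        Vr, wr, ger, gir = V.copy(), w.copy(), g_ex.copy(), g_in.copy()
        nspk, status = _engine.run_kernel(
            network.pop_start, par,
            network.ext_rate * h, network.ext_weight,
            Vr, wr, ger, gir,
            network.out_indptr, network.out_tgt, network.out_conn,
            conn_delay, conn_weight, conn_is_ex,
            ring_len, n_steps, h, kernel_seed,
            spike_step, spike_id,
            rec_ids, rec["V"], rec["g_ex"], rec["g_in"], rec["w"],
        )
        if status == 2:
            i = int(spike_id[0])
            pop = next(
                nm for nm, (lo, hi) in network.pop_slices.items() if lo <= i < hi
            )
            raise NumericalDivergenceError(
                f"non-finite state in population {pop!r}, neuron {i}, "
                f"step {int(spike_step[0])}"
            )
        if status == 1:
            cap *= 2
            continue
        break

    times = spike_step[:nspk].astype(np.float64) * h - warmup
    ids = spike_id[:nspk].astype(np.int64)
    keep = times >= 0.0
    raster = SpikeRaster(
        times[keep], ids[keep], network.pop_slices, duration, warmup
    )
    if record is not None:
        return raster, rec
    return raster
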