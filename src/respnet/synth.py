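"""Synthetic calcium-imaging recordings with known network ground truth.

The generator emulates what the analysis pipeline assumes about respiratory
slice recordings: a minority of autonomously rhythmic pacemaker cells
(default 31% of cells, the fraction that stays rhythmic when synaptic
transmission is blocked), quasi-periodic Ca²⁺ transients at tens of mHz,
single-hop propagation of each pacemaker event to graph neighbours, and
imaging artefacts (shot noise, slow drift, finite frame interval).

Propagation is deliberately single-hop — a received event is not re-emitted —
so that correlated activity stays localized to the edges of the ground-truth
graph and edge recovery is well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .traces import TraceSet

TOPOLOGIES = ("ring_lattice", "small_world", "random", "planted_clusters", "empty")
PERTURBATION_MODES = ("decouple_all", "delete_edge_fraction", "scale_rate",
                      "add_tonic_rate")


@dataclass
class NetworkSpec:
    """Ground-truth coupling topology.

    ``k`` is the mean degree.  ``hub_fraction`` applies to planted clusters:
    inter-cluster bridges attach only to that leading fraction of each
    cluster's nodes, emulating clusters interconnected via a few hub cells.
    """

    n_cells: int = 100
    topology: str = "small_world"
    k: int = 6
    rewire_p: float = 0.1
    n_clusters: int = 2
    inter_cluster_edges: int = 2
    hub_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be at least 2")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 <= self.rewire_p <= 1:
            raise ValueError("rewire_p must be in [0, 1]")
        if self.topology != "empty" and self.k >= self.n_cells:
            raise ValueError("mean degree k must be below n_cells")
        if self.topology in ("ring_lattice", "small_world") and self.k % 2:
            raise ValueError("ring-lattice topologies need an even k")
        if not 0 <= self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in [0, 1]")


@dataclass
class DynamicsSpec:
    """Event dynamics and imaging model.

    Rates are in mHz (events per 1000 s); all times in seconds; amplitudes
    in raw-intensity units.  ``rate_jitter_cv`` is the coefficient of
    variation of pacemaker inter-event intervals (gamma-distributed).
    """

    pacemaker_fraction: float = 0.31
    pacemaker_rate: float = 25.0          # mHz; network cell rates sit at tens of mHz
    rate_jitter_cv: float = 0.2
    transmission_prob: float = 0.8
    transmission_delay: float = 0.3       # s, mean
    delay_jitter: float = 0.1             # s, SD
    propagated_amplitude_scale: float = 0.5  # evoked vs intrinsic transient peak
    kernel_rise: float = 0.3              # s
    kernel_decay: float = 2.0             # s
    amplitude: float = 60.0               # intensity units at unit kernel peak
    baseline: float = 100.0
    noise_sd: float = 2.0
    drift_amplitude: float = 2.0
    frame_interval: float = 0.5           # s, must be in [0.1, 2]
    duration: float = 300.0               # s

    def validate(self) -> None:
        for name in ("pacemaker_rate", "transmission_delay", "kernel_rise",
                     "kernel_decay", "frame_interval", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_rise >= self.kernel_decay:
            raise ValueError("kernel_rise must be shorter than kernel_decay")
        if not 0 <= self.pacemaker_fraction <= 1:
            raise ValueError("pacemaker_fraction must be in [0, 1]")
        if not 0 <= self.transmission_prob <= 1:
            raise ValueError("transmission_prob must be in [0, 1]")
        if not self.propagated_amplitude_scale > 0:
            raise ValueError("propagated_amplitude_scale must be positive")
        if not 0.1 <= self.frame_interval <= 2.0:
            raise ValueError("frame_interval must lie in [0.1, 2] s")
        if self.duration / self.frame_interval < 2:
            raise ValueError("recording must span at least 2 frames")


@dataclass
class PerturbationSpec:
    """A pharmacology-style intervention applied from ``onset`` onward.

    Modes: ``decouple_all`` (block all transmission, TTX-like),
    ``delete_edge_fraction`` (remove that fraction of edges, gap-junction
    block-like), ``scale_rate`` (multiply pacemaker rates, opioid/K⁺-like),
    ``add_tonic_rate`` (additional Poisson events at ``magnitude`` Hz in
    every cell, tonic depolarization).
    """

    mode: str
    magnitude: float = 0.0
    onset: float = 0.0

    def validate(self, duration: float) -> None:
        if self.mode not in PERTURBATION_MODES:
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if not 0 <= self.onset <= duration:
            raise ValueError("perturbation onset outside the recording")
        if self.mode == "delete_edge_fraction" and not 0 <= self.magnitude <= 1:
            raise ValueError("edge deletion fraction must be in [0, 1]")
        if self.mode in ("scale_rate", "add_tonic_rate") and self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")


@dataclass
class SimulatedRecording:
    """A synthetic TraceSet bundled with its ground truth."""

    traces: TraceSet
    truth_graph: nx.Graph
    pacemaker_mask: np.ndarray
    truth_events: list[np.ndarray]
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.traces.n_cells

    def save_truth_json(self, path) -> None:
        payload = {
            "edges": sorted([int(u), int(v)] for u, v in self.truth_graph.edges()),
            "pacemaker_mask": [bool(b) for b in self.pacemaker_mask],
            "event_times_s": [list(map(float, t)) for t in self.truth_events],
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def generate_network(spec: NetworkSpec) -> nx.Graph:
    """Build the ground-truth coupling graph for a NetworkSpec.

    Undirected simple graph without self-loops; reproducible per seed.
    """
    spec.validate()
    n, seed = spec.n_cells, spec.seed
    if spec.topology == "empty":
        g = nx.empty_graph(n)
    elif spec.topology == "ring_lattice":
        g = nx.watts_strogatz_graph(n, spec.k, 0.0, seed=seed)
    elif spec.topology == "small_world":
        g = nx.watts_strogatz_graph(n, spec.k, spec.rewire_p, seed=seed)
    elif spec.topology == "random":
        g = nx.gnm_random_graph(n, round(n * spec.k / 2), seed=seed)
    else:  # planted_clusters
        rng = np.random.default_rng(seed)
        g = nx.empty_graph(n)
        bounds = np.linspace(0, n, spec.n_clusters + 1).astype(int)
        clusters = [list(range(bounds[i], bounds[i + 1]))
                    for i in range(spec.n_clusters)]
        for ci, nodes in enumerate(clusters):
            m = round(len(nodes) * spec.k / 2)
            sub = nx.gnm_random_graph(len(nodes), m,
                                      seed=int(rng.integers(2**31)))
            g.add_edges_from((nodes[a], nodes[b]) for a, b in sub.edges())
            for v in nodes:
                g.nodes[v]["cluster"] = ci
        # bridges attach to the designated hub nodes of each cluster
        n_hub = max(1, round(spec.hub_fraction * len(clusters[0])))
        hubs = [nodes[:n_hub] for nodes in clusters]
        candidates = [(u, v) for a in range(spec.n_clusters)
                      for b in range(a + 1, spec.n_clusters)
                      for u in hubs[a] for v in hubs[b]]
        if spec.inter_cluster_edges > len(candidates):
            raise ValueError(
                f"cannot place {spec.inter_cluster_edges} bridges between "
                f"{len(candidates)} available hub pairs; raise hub_fraction")
        for i in rng.choice(len(candidates), size=spec.inter_cluster_edges,
                            replace=False):
            g.add_edge(*candidates[i])
        for nodes in hubs:
            for v in nodes:
                g.nodes[v]["hub"] = True
    g.graph["spec"] = asdict(spec)
    return g


def _calcium_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak."""
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    tp = np.maximum(t, 0.0)
    out = np.exp(-tp / decay) - np.exp(-tp / rise)
    return np.where(t >= 0, out / peak, 0.0)


def _pacemaker_events(rng: np.random.Generator, dyn: DynamicsSpec,
                      scale_onset: float, scale_mag: float) -> np.ndarray:
    """Quasi-periodic event train; first event at a random phase in one period."""
    period = 1000.0 / dyn.pacemaker_rate
    cv = dyn.rate_jitter_cv
    t = float(rng.uniform(0, period))
    out = []
    while t < dyn.duration:
        out.append(t)
        p = period / scale_mag if (scale_mag != 1.0 and t >= scale_onset) else period
        if cv > 0:
            shape = 1.0 / cv**2
            t += rng.gamma(shape, p / shape)
        else:
            t += p
    return np.asarray(out)


def simulate_recording(net: nx.Graph, dyn: DynamicsSpec,
                       perturbations: list[PerturbationSpec] | tuple = (),
                       seed: int = 0) -> SimulatedRecording:
    """Simulate Ca²⁺ traces on a ground-truth graph.

    Pacemaker cells emit quasi-periodic events; each autonomous event
    propagates once to each neighbour with probability ``transmission_prob``
    after a jittered delay.  Traces are baseline + amplitude-scaled transient
    kernels + sinusoidal drift + Gaussian noise sampled at the frame interval.
    """
    dyn.validate()
    for p in perturbations:
        p.validate(dyn.duration)

    n = net.number_of_nodes()
    nodes = sorted(net.nodes())
    if nodes != list(range(n)):
        raise ValueError("graph nodes must be 0..n_cells-1")

    # dedicated streams so pacemaker identity and cell dynamics are invariant
    # to which perturbations are applied (paired perturbed/control runs)
    ss = np.random.SeedSequence(seed)
    pace_seed, perturb_seed, prop_seed = ss.spawn(3)
    pace_rng = np.random.default_rng(pace_seed)
    perturb_rng = np.random.default_rng(perturb_seed)
    prop_rng = np.random.default_rng(prop_seed)
    cell_rngs = [np.random.default_rng(s) for s in ss.spawn(n)]

    # pacemaker selection
    n_pace = int(round(dyn.pacemaker_fraction * n))
    if dyn.pacemaker_fraction > 0:
        n_pace = max(1, n_pace)
    pace_idx = pace_rng.choice(n, size=n_pace, replace=False) if n_pace else np.array([], int)
    pacemaker = np.zeros(n, dtype=bool)
    pacemaker[pace_idx] = True

    # perturbation bookkeeping
    decouple_onset = np.inf
    scale_onset, scale_mag = np.inf, 1.0
    tonic_onset, tonic_rate = np.inf, 0.0
    deleted: set[tuple[int, int]] = set()
    delete_onset = np.inf
    for p in perturbations:
        if p.mode == "decouple_all":
            decouple_onset = min(decouple_onset, p.onset)
        elif p.mode == "scale_rate":
            scale_onset, scale_mag = p.onset, p.magnitude
        elif p.mode == "add_tonic_rate":
            tonic_onset, tonic_rate = p.onset, p.magnitude
        elif p.mode == "delete_edge_fraction":
            edges = sorted(tuple(sorted(e)) for e in net.edges())
            n_del = round(p.magnitude * len(edges))
            idx = perturb_rng.choice(len(edges), size=n_del, replace=False)
            deleted = {edges[i] for i in idx}
            delete_onset = p.onset

    # autonomous events (pacemaker rhythm + optional tonic Poisson drive)
    autonomous: list[np.ndarray] = []
    for i in range(n):
        ev = (_pacemaker_events(cell_rngs[i], dyn, scale_onset, scale_mag)
              if pacemaker[i] else np.array([]))
        if tonic_rate > 0 and tonic_onset < dyn.duration:
            span = dyn.duration - tonic_onset
            n_extra = cell_rngs[i].poisson(tonic_rate * span)
            extra = tonic_onset + cell_rngs[i].uniform(0, span, size=n_extra)
            ev = np.concatenate([ev, extra])
        autonomous.append(np.sort(ev))

    # single-hop propagation of autonomous events across surviving edges;
    # intrinsically bursting (pacemaker) targets occlude evoked transients,
    # so delivery is to non-pacemaker neighbours only
    received: list[list[float]] = [[] for _ in range(n)]
    for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
        for src, dst in ((u, v), (v, u)):
            for t_e in autonomous[src]:
                draw = prop_rng.uniform()
                delay = dyn.transmission_delay + dyn.delay_jitter * prop_rng.standard_normal()
                if pacemaker[dst]:
                    continue
                if t_e >= decouple_onset:
                    continue
                if (u, v) in deleted and t_e >= delete_onset:
                    continue
                if draw < dyn.transmission_prob:
                    t_a = t_e + max(delay, 0.5 * dyn.frame_interval)
                    if t_a < dyn.duration:
                        received[dst].append(t_a)

    truth_events = [np.sort(np.concatenate([autonomous[i], np.asarray(received[i])]))
                    for i in range(n)]

    # render traces; synaptically evoked transients carry a smaller peak than
    # intrinsic ones so that correlated variance stays localized to edges
    n_frames = int(round(dyn.duration / dyn.frame_interval))
    times = np.arange(n_frames) * dyn.frame_interval
    values = np.full((n, n_frames), dyn.baseline, dtype=float)
    support = int(np.ceil(6 * dyn.kernel_decay / dyn.frame_interval))
    drift_period = dyn.duration  # slow relative to the ±30 s baseline window
    amp_recv = dyn.amplitude * dyn.propagated_amplitude_scale
    for i in range(n):
        rng = cell_rngs[i]
        phase = rng.uniform(0, 2 * np.pi)
        values[i] += dyn.drift_amplitude * np.sin(2 * np.pi * times / drift_period + phase)
        per_event = [(t_e, dyn.amplitude) for t_e in autonomous[i]] + \
                    [(t_e, amp_recv) for t_e in received[i]]
        for t_e, amp in per_event:
            j0 = int(np.ceil(t_e / dyn.frame_interval))
            j1 = min(j0 + support, n_frames)
            if j0 >= n_frames:
                continue
            values[i, j0:j1] += amp * _calcium_kernel(
                times[j0:j1] - t_e, dyn.kernel_rise, dyn.kernel_decay)
        if dyn.noise_sd > 0:
            values[i] += rng.normal(0, dyn.noise_sd, size=n_frames)

    traces = TraceSet(values=values, frame_interval=dyn.frame_interval,
                      roi_ids=[f"cell_{i:03d}" for i in range(n)])
    return SimulatedRecording(traces=traces, truth_graph=net,
                              pacemaker_mask=pacemaker,
                              truth_events=truth_events, seed=seed)


def render_stack(rec: SimulatedRecording, positions: np.ndarray,
                 radii: np.ndarray | float = 2.5,
                 shape: tuple[int, int] = (64, 64),
                 background: float = 10.0) -> np.ndarray:
    """Render a recording as an image stack with Gaussian cell footprints.

    Each frame is ``background`` plus, for every cell, a 2-D Gaussian of
    SD ``radius`` at the cell position scaled by that cell's trace value.
    Returns a float (n_frames, H, W) array, writable as TIFF.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = rec.n_cells
    if positions.shape != (n, 2):
        raise ValueError("positions must be (n_cells, 2) (row, col)")
    h, w = shape
    if np.any(positions < 0) or np.any(positions[:, 0] >= h) or np.any(positions[:, 1] >= w):
        raise ValueError("cell positions must lie within the image bounds")
    uniq = {tuple(p) for p in positions.round(3)}
    if len(uniq) < n:
        warnings.warn("overlapping identical cell positions")
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    rows, cols = np.mgrid[0:h, 0:w]
    foot = np.empty((n, h, w))
    for i in range(n):
        d2 = (rows - positions[i, 0]) ** 2 + (cols - positions[i, 1]) ** 2
        foot[i] = np.exp(-d2 / (2 * radii[i] ** 2))
    stack = background + np.einsum("cf,chw->fhw", rec.traces.values, foot)
    return stack


def write_stack_tiff(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, stack.astype(np.float32))
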