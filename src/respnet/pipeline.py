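"""End-to-end orchestration: simulate or load → normalize → events → network → report.

A run is fully described by a :class:`RunConfig`; every randomized stage
(simulation, scrambling, graph rewiring) has its own explicit seed so a rerun
with the same config is byte-identical.  ``analyze_recording`` writes all
stage outputs plus a provenance record (config, seeds, package versions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frequency, metrics, network, synth, traces

log = logging.getLogger("respnet")


@dataclass
class RunConfig:
    """All inputs and stage parameters for one analysis run."""

    # input: either a trace-table CSV or a simulation block
    input_csv: str | None = None
    network_spec: dict = field(default_factory=dict)
    dynamics_spec: dict = field(default_factory=dict)
    perturbations: list[dict] = field(default_factory=list)
    sim_seed: int = 0
    # stage parameters
    window_half_width: float = 30.0
    threshold_frac: float = 0.20
    min_separation: float = 2.0
    n_scrambles: int = 100
    scramble_seed: int = 1
    n_random: int = 100
    random_seed: int = 2
    gamma_mode: str = "ratio"
    epochs: list[list] = field(default_factory=list)
    outdir: str = "results/run"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def reseed(self, base: int) -> None:
        """Derive the three stage seeds deterministically from one base seed."""
        self.sim_seed = base
        self.scramble_seed = base + 1
        self.random_seed = base + 2


def simulate_from_config(cfg: RunConfig) -> synth.SimulatedRecording:
    net_spec = synth.NetworkSpec(**cfg.network_spec)
    dyn = synth.DynamicsSpec(**cfg.dynamics_spec)
    perts = [synth.PerturbationSpec(**p) for p in cfg.perturbations]
    g = synth.generate_network(net_spec)
    return synth.simulate_recording(g, dyn, perts, seed=cfg.sim_seed)


def analyze_recording(cfg: RunConfig):
    """Run the full pipeline and write all artifacts to ``cfg.outdir``.

    Returns (NetworkSummary, FrequencyReport, functional graph, paths dict).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    if cfg.input_csv:
        ts = traces.TraceSet.from_csv(cfg.input_csv)
        rec = None
        log.info("stage=load input=%s cells=%d frames=%d", cfg.input_csv,
                 ts.n_cells, ts.n_frames)
    else:
        rec = simulate_from_config(cfg)
        ts = rec.traces
        truth_path = outdir / "truth.json"
        rec.save_truth_json(truth_path)
        paths["truth"] = str(truth_path)
        log.info("stage=simulate cells=%d frames=%d seed=%d", ts.n_cells,
                 ts.n_frames, cfg.sim_seed)

    norm = traces.normalize_dff(ts, window_half_width=cfg.window_half_width)
    norm.to_csv(outdir / "normalized_traces.csv")
    paths["normalized_traces"] = str(outdir / "normalized_traces.csv")

    events = traces.detect_events(norm, threshold_frac=cfg.threshold_frac,
                                  min_separation=cfg.min_separation)
    events.to_csv(outdir / "events.csv")
    paths["events"] = str(outdir / "events.csv")
    log.info("stage=events active=%d/%d threshold=%.2f", events.n_active,
             ts.n_cells, cfg.threshold_frac)

    corr = network.correlation_matrix(norm)
    cut = network.scrambled_cutoff(norm, n_scrambles=cfg.n_scrambles,
                                   seed=cfg.scramble_seed)
    network.attach_cutoff(corr, cut, cfg.n_scrambles, cfg.scramble_seed)
    corr.to_csv(outdir / "correlation_matrix.csv", roi_ids=ts.roi_ids)
    paths["correlation_matrix"] = str(outdir / "correlation_matrix.csv")

    g = network.build_graph(corr, events, centroids=ts.roi_centroids)
    network.edges_to_csv(g, outdir / "edges.csv", roi_ids=ts.roi_ids)
    paths["edges"] = str(outdir / "edges.csv")
    log.info("stage=network cutoff=%.4f edges=%d", cut, g.number_of_edges())

    summary = metrics.normalize_metrics(g, n_random=cfg.n_random,
                                        seed=cfg.random_seed,
                                        gamma_mode=cfg.gamma_mode)
    summary.to_csv(outdir / "summary.csv")
    paths["summary"] = str(outdir / "summary.csv")

    freq = frequency.frequency_and_cv(events)
    freq.to_csv(outdir / "frequencies.csv")
    paths["frequencies"] = str(outdir / "frequencies.csv")

    if cfg.epochs:
        comp = frequency.compare_epochs(
            events, [(float(s), float(e), str(lb)) for s, e, lb in cfg.epochs])
        comp.to_csv(outdir / "epoch_comparison.csv")
        paths["epoch_comparison"] = str(outdir / "epoch_comparison.csv")

    prov = {"config": cfg.to_dict(),
            "seeds": {"sim": cfg.sim_seed, "scramble": cfg.scramble_seed,
                      "random": cfg.random_seed},
            "versions": _versions()}
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    paths["provenance"] = str(outdir / "provenance.json")
    return summary, freq, g, paths


def _versions() -> dict:
    import networkx
    import scipy

    return {"respnet": "0.1.0", "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "networkx": networkx.__version__}


def report(summary_paths: list) -> pd.DataFrame:
    """Aggregate per-recording summaries into a mean ± SD table.

    One row per summary parameter with the across-recording mean and sample
    SD (ddof=1; SD is 0 for a single recording).  Raises on an empty list or
    on summaries with mismatched columns.
    """
    if not summary_paths:
        raise ValueError("no summaries to aggregate")
    frames = [pd.read_csv(p) for p in summary_paths]
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise ValueError("summaries have mixed schemas")
    stacked = pd.concat(frames, ignore_index=True)
    num = stacked.select_dtypes("number")
    out = pd.DataFrame({
        "parameter": num.columns,
        "mean": num.mean().to_numpy(),
        "sd": (num.std(ddof=1).fillna(0.0).to_numpy()
               if len(stacked) > 1 else np.zeros(num.shape[1])),
    })
    return out
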