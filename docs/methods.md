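# Methods

## Overview

`respnet` implements the functional-network analysis used for calcium-imaging
recordings of respiratory brainstem circuits (preBötzinger complex,
pFRG/RTN): fluorescence traces are normalized to a sliding local baseline
(ΔF/F₀), Ca²⁺ transients are detected as peaks rising at least 20% above a
running baseline, pairwise Pearson correlations are thresholded at a cut-off
derived from circularly time-shifted surrogate traces, and the resulting
functional graph is summarized with small-world metrics normalized against
degree-preserving randomized networks.  A synthetic-recording generator with
known coupling topology, pacemaker labels and event times makes every stage
verifiable against ground truth.

## Trace processing

**ΔF/F₀.**  For each cell and frame, F₀(t) is the mean raw intensity within
±30 s of t (window truncated at the recording edges, inclusive of t), and
ΔF/F₀ = (F − F₀)/F₀.  The centered window reads "30 s before and after" a
sample as one symmetric window; including the central sample changes F₀ by
less than one part in 30 at the frame rates in scope (0.1–2 s intervals).
Cells whose baseline is ever non-positive are flagged and excluded from
correlation rather than silently producing unbounded ratios.  ΔF/F₀ is
invariant to multiplicative gain (illumination, expression level) but not to
additive offsets — both properties are asserted in the tests.

**Event detection.**  Events are local maxima of ΔF/F₀ whose height above a
running baseline is at least `threshold_frac` (default 0.20).  The baseline
is the running 10th percentile of the normalized trace over a 60 s window —
a robust floor that follows slow drift without tracking the transients
themselves.  Maxima closer than `min_separation` (default 2 s, on the order
of the transient decay time) are merged keeping the larger.  A cell is
"active" iff it has at least one event.

**Nerve/population traces** are band-filtered with a 4th-order zero-phase
Butterworth filter, full-wave rectified, and smoothed with a 1 s moving
average.  The default cutoff is 0.06 Hz in low-pass mode, as conventionally
printed for this preparation; since a 0.06 Hz low-pass would also attenuate
respiratory bursts at ~0.05–0.13 Hz, the filter mode is configurable and a
high-pass variant is available.  Bursts are threshold crossings (fraction of
the signal maximum, default 0.5) merged across gaps shorter than
`min_burst_gap`, reported as bursts/min with the inter-burst-interval CV.

## Correlation network

Pearson r is computed for every unordered pair of valid (non-constant,
baseline-valid) cells.  The significance cut-off follows the surrogate-data
construction: in each of `n_scrambles` (default 100) realizations, every
trace is independently circularly shifted by a uniform offset in
[1, n_frames−1]; the 99th percentile (linear interpolation) of the pooled
upper-triangle correlations is recorded, and the cut-off is the mean of
these percentiles.  Circular shifting preserves each trace's marginal
distribution and autocorrelation while destroying cross-cell alignment, so
the cut-off estimates the chance-alignment quantile.  Edges join active cell
pairs with signed r ≥ cut-off (anti-correlated pairs are not edges); weights
retain r for visualization.

By construction this null admits ≈1% of unstructured pairs as chance edges.
That is the intended operating point of the method and it is calibrated in
the tests (≤3% admitted over 10 independent noise recordings); its
consequence for graph-level metrics is discussed under *Limitations*.

## Graph metrics

- correlating pairs = edge count; active cells = nodes; correlations per
  active cell = mean degree (2E/N); connectivity = E / (N choose 2).
- Mean clustering C averages the local clustering coefficient over all nodes
  (degree < 2 contributes 0).  Mean shortest path L averages over connected
  unordered pairs only; the disconnected-pair fraction is reported alongside.
- λ = L / ⟨L_random⟩ and σ = C / ⟨C_random⟩ over `n_random` (default 100)
  degree-preserving rewirings of the graph (double edge swaps, 10·E swaps
  per realization; a density-matched random graph is used, with a warning,
  when the degree sequence admits no swaps).
- The small-world index is γ = σ/λ.  The slice-culture literature sometimes
  typesets this as a product; the reported values (σ ≈ 2.7, λ ≈ 0.7,
  γ ≈ 4.2) are only consistent with the ratio, which is also the standard
  definition, so the ratio is the default and the product is available via
  `gamma_mode="product"`.
- Connectivity as defined above gives ≈0.07–0.08 for the simulated study
  conditions (≈330 pairs among ≈93 active cells).  Published tables report
  0.8 for ≈560 pairs among ≈110 cells, which is inconsistent with the
  stated definition (560/5995 ≈ 0.09); the definition is implemented
  verbatim and the discrepancy left unreconciled.

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes:

- **Topology** (`NetworkSpec`): ring lattice, Watts–Strogatz small world,
  Erdős–Rényi, planted clusters (dense clusters bridged by a few designated
  hub cells), or empty.  Defaults n=100, k=6, rewire 0.1.
- **Dynamics** (`DynamicsSpec`): a fraction of cells (default 0.31 — the
  fraction observed to stay rhythmic under synaptic blockade) are pacemakers
  emitting quasi-periodic events: gamma-distributed inter-event intervals
  with mean 1/rate and CV `rate_jitter_cv` (default 0.2).  The default rate
  is 25 mHz, matching network mean frequencies of tens of mHz in this
  preparation; each pacemaker starts at a random phase within its first
  period so that cells are not artificially synchronized at t = 0.
- **Propagation**: each autonomous source event propagates once (single hop,
  no cascades) to each graph neighbour with probability `transmission_prob`
  after a jittered delay (0.3 ± 0.1 s).  Single-hop propagation keeps
  correlated variance localized to graph edges, which is what makes edge
  recovery well defined.  Delivery is to non-pacemaker targets only: in an
  intrinsically bursting cell the evoked response is occluded by its own
  oscillation, so a pacemaker's event rate is purely intrinsic.  This is
  what makes decoupling-style perturbations leave pacemaker frequencies
  untouched, as observed with gap-junction block.
- **Transients and imaging**: each event adds a difference-of-exponentials
  kernel (rise 0.3 s, decay 2 s — typical cytosolic Ca²⁺ scale) normalized
  to unit peak.  Intrinsic events have amplitude 60 intensity units on a
  baseline of 100 (peak ΔF/F ≈ 0.6, a strong burst); synaptically evoked
  transients are scaled by `propagated_amplitude_scale` (default 0.5, i.e.
  peak ΔF/F ≈ 0.3 — above the 20% detection criterion).  Traces add a slow
  sinusoidal drift (period = recording duration, ≥ half the recording by
  construction, stressing the ±30 s baseline window) and white Gaussian
  noise, sampled at the frame interval (default 0.5 s, duration 300 s).
- **Perturbations** from a given onset: `decouple_all` (synaptic blockade),
  `delete_edge_fraction` (gap-junction-block-like edge removal),
  `scale_rate` (opioid/K⁺-like rate change), `add_tonic_rate` (Poisson
  drive in every cell, tonic depolarization).
- **Rendering**: recordings can be rasterized into TIFF stacks of 2-D
  Gaussian cell footprints over a flat background, closing the loop with the
  ROI-extraction stage (SD-over-time image → Gaussian smooth → Otsu
  threshold → connected components → per-ROI mean traces).

Determinism: one seed sequence per recording; per-cell generators, the
propagation stream and the perturbation stream are spawned from it, so a
recording is bit-reproducible and pacemaker identity is invariant to which
perturbations are applied (paired control/treatment runs share cells).

### What the generator does not emulate

Wave-like propagation delays across space, cascading multi-hop excitation,
bursting envelopes and sighs, photobleaching rundown, motion, correlated
(shared) noise, and neuron/glia distinctions beyond the pacemaker label.
Passing tests therefore demonstrate correctness of the analysis under the
model's assumptions, not performance on arbitrary real recordings.

## The edge-recovery benchmark

The reference problem for structure recovery is a planted Watts–Strogatz
graph (n=100, k=6, rewire 0.1) with transmission probability 0.8 and
peak-SNR 5 (noise SD = amplitude/5).  Two benchmark-specific choices make
every planted edge functionally expressed and identifiable:

1. **Drive**: every cell receives autonomous Poisson events at 20 mHz
   (tonic mode, no pacemakers).  Under single-hop propagation an edge
   between two silent cells carries no signal, so with only 31% of cells
   autonomously active roughly half the edges would be invisible in
   principle; driving all cells expresses all edges.
2. **Evoked amplitude** is set to 0.3 of intrinsic.  A pair connected by an
   edge shares variance ∝ 2·a·p (each side's own events appear in the
   other), while a pair that merely shares m common neighbours shares
   ∝ m·(a·p)².  Identifiability requires m·(a·p)² to sit below the chance
   cut-off while 2·a·p sits well above it; with p = 0.8 and m ≈ 2–3 this
   holds at a = 0.3 but fails at the physiological default a = 0.5, where
   common-input pairs become spurious edges.

With these settings the recovered graph matches the planted one at
F1 ≈ 0.86–0.90 (precision ≈ 0.8, recall ≈ 0.97) across seeds — computed by
`analysis/03_edge_recovery.py` and the acceptance script.

## Numerical choices

- Time of frame i is i·frame_interval; frames and pixel coordinates are
  0-based; event times are in seconds.
- Percentiles use linear interpolation (NumPy default).
- Sliding means use exact truncated windows (cumulative sums), not padded
  convolutions.
- Peak detection uses prominence-style height above the running percentile
  baseline with a minimum peak distance; ties resolve to the larger peak.
- Frequency is (n−1)/(t_last − t_first) within the epoch — the inverse mean
  inter-event interval — rather than n/duration, avoiding edge bias; cells
  with < 2 events have frequency 0, and CV (sample SD/mean of intervals, %)
  requires ≥ 3 events.
- Aggregate reports use the sample SD (ddof = 1).
- "Regularly spiking" cells default to interval CV ≤ 50% (configurable).

## Limitations

- **Chance-edge floor and σ recovery.**  The 99th-percentile null admits
  ≈1% of all cell pairs as edges regardless of recording length (the null
  is self-calibrating).  For 100 active cells that is ≈46 spurious,
  uniformly placed edges on top of ≈300 true ones.  Spurious random edges
  dilute the rewiring-normalized clustering σ of the recovered graph by
  ≈25–45% relative to the planted graph (measured directly by
  `analysis/03_edge_recovery.py`), even at recall ≈ 1.  Edge-level recovery
  (F1) is robust to this; σ of a thresholded graph is not, and σ values
  from this method should be read with that bias in mind.
- Pearson correlation on continuous traces cannot distinguish direct
  coupling from strong common input in general; the benchmark quantifies
  the regime where the distinction holds.  An event-train correlation mode
  exists but the continuous-trace Pearson is the default.
- Lagged/directed interactions, partial correlation and community structure
  are out of scope.
- The mean shortest path is computed over connected pairs only; strongly
  fragmented graphs are summarized together with their disconnected-pair
  fraction rather than by an imputed path length.
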