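# intervalkinetics

Residence-time analysis for single-molecule live-cell imaging of
DNA-binding proteins, with photobleaching deconvolved by **interval
imaging**.

## The problem

When a fluorescently tagged protein (e.g. a YPet fusion of a nucleotide
excision repair factor such as UvrA or Mfd in *E. coli*) is tracked on DNA
in a living cell, a bound focus disappears either because the protein
dissociates or because its fluorophore photobleaches. Continuous imaging
cannot distinguish the two, so binding lifetimes longer than the bleaching
lifetime are unmeasurable.

Interval imaging fixes this by inserting a dark interval between
consecutive frames. Each frame exposes for τ_int (0.1 s) while the
time-lapse time τ_tl between frame starts varies across acquisitions
(e.g. τ_tl ∈ {0.1, 0.2, 0.5, 1, 2, 4, 8, 10} s). The bleach dose per
*frame* is then constant while the observation window stretches, and the
apparent decay rate of the dwell-time distribution at each setting is

```
k_eff(τ_tl) = k_b · τ_int / τ_tl + k_off
```

so the product k_eff·τ_tl is affine in τ_tl with slope k_off (the true
dissociation rate) and intercept k_b·τ_int (the normalized bleach rate).
For a mixture of kinetic populations, the cumulative residence time
distribution (CRTD) at each τ_tl — the number of binding events lasting at
least m frames — follows

```
CRTD(m; τ_tl) ∝ Σᵢ Aᵢ · exp(−(k_b τ_int/τ_tl + k_off,i) · m · τ_tl)
```

and a **global fit** across the whole τ_tl grid, sharing the amplitudes
Aᵢ, off rates k_off,i and bleach rate k_b, deconvolves dissociation from
bleaching. Linearity of the k_eff·τ_tl vs τ_tl plot selects between one-
and two-population models; uncertainties come from refitting ten bootstrap
subsamples of 80% of the compiled events. The method resolves off rates
that are at least threefold apart.

## What the package provides

| module | contents |
|---|---|
| `kinetics` | `KineticModel`, `AcquisitionProtocol`, closed-form `effective_rate` / `survival` / `expected_crtd` |
| `simulate` | `simulate_events` (ground-truth binding-event tables), `simulate_movie` (synthetic two-phase TIFF stacks with emitter ground truth) |
| `detect` | background flattening, discoidal average filter (r_in = 1, r_out = 3), thresholded foci detection, 3-px consecutive-frame linking, copy-number estimation, intensity time courses |
| `fitcrtd` | `build_crtd`, per-τ_tl `fit_keff_single`, linearity-based `diagnose_model_order`, `fit_global`, `bootstrap_fit`, 25-min `window_partition` |
| `config` / `pipeline` / `cli` | YAML-configured, seed-reproducible end-to-end runs (`intervalkinetics run`, `simulate-events`, `simulate-movie`, `detect`, `fit`, `bootstrap`, `report`) |

Event tables move between stages as plain CSV (columns
`acquisition_id, tau_tl_s, start_frame, n_frames, x_px, y_px,
wall_clock_s`), so detected real-data events and simulated events are
interchangeable inputs to the fitter.

## Worked example

Simulate a two-population mixture (72% at 1.6 s, 28% at 24 s, k_b =
5.5 s⁻¹ — the regime of UvrA-YPet in cells lacking UvrB and Mfd) and
recover its parameters:

```python
import intervalkinetics as ik

model = ik.KineticModel.from_lifetimes(
    amplitudes=[0.72, 0.28], lifetimes_s=[1.6, 24.0], k_b=5.5)
protocol = ik.AcquisitionProtocol()          # 8-point grid, 0.1 s frames
events = ik.simulate_events(model, protocol, n_events_per_tau=4366, seed=11)
crtds = ik.build_crtds(events, protocol)
series = ik.build_keff_series(crtds)
order = ik.diagnose_model_order(series)      # lack-of-fit on k_eff·τ_tl plot
fit = ik.fit_global(crtds, protocol, model_order=order)
fit.bootstrap_sd = ik.bootstrap_fit(events, protocol, order, seed=12)
print("model order:", order, " lack-of-fit p =", round(series.lof_pvalue, 3))
print(ik.report([("all", fit)]))
```

prints

```
model order: 2  lack-of-fit p = 0.01
# Interval-imaging dissociation-kinetics fit

| window | order | A_fast (%) | tau_fast (s) | A_slow (%) | tau_slow (s) | k_b (1/s) | n |
|---|---|---|---|---|---|---|---|
| all | 2 | 70.2 ± 0.83 | 1.76 ± 0.03 | 29.8 ± 0.83 | 25 ± 0.31 | 5.55 ± 0.026 | 34928 |
```

The diagnostic rejects a single population (p = 0.01 < 0.05), and the
global fit recovers the generating lifetimes (1.76 vs 1.6 s, 25 vs 24 s),
amplitudes (70 vs 72%) and bleach rate (5.55 vs 5.5 s⁻¹) within a few
percent at ~35,000 events; the ± values are SDs over ten bootstrap
subsamples of 80% of the events.

The same fit runs from the shell on any events CSV:

```sh
intervalkinetics fit --events events.csv --model-order auto --out fit.json
```

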