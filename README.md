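# smfskit

Simulation and analysis of AFM-based single-molecule force spectroscopy
(SMFS) pulling experiments, built around the workflow used to measure
ligand-induced mechanical stabilization of protein receptors — e.g.
cellulosomal cohesin domains probed without and with their dockerin ligand
through a fingerprinted polyprotein construct.

## What it does

In a constant-velocity SMFS experiment a polyprotein tethered between a
surface and a cantilever is stretched; each domain unfolds in a sawtooth
of rupture events. The analysis chain implemented here is:

1. **Simulation** (`smfskit.simulate`) — constant-velocity force-distance
   curves of a polyprotein (ddFLN4 fingerprint + cohesin + receptor-ligand
   pulling handle): serial worm-like-chain elasticity balanced against a
   Hookean cantilever, stochastic unfolding by integration of the Bell
   hazard k(F) = k₀·exp(F·Δx/k_BT) along the trajectory, plus Gaussian
   force noise, baseline drift and a deflection-calibration (InvOLS)
   error. Ground truth (true rupture forces, loading rates, contour-length
   increments) is recorded separately for validation.
2. **Correction** (`smfskit.correct`) — InvOLS rescaling, baseline-offset
   removal from the trailing 5% of samples, moving-median smoothing.
3. **Event detection and fingerprinting** (`smfskit.events`) — rupture
   detection on the smoothed sawtooth, transformation of each inter-event
   stretch to contour-length space via the inverted Marko-Siggia relation

   F(x) = (k_BT/L_p)·[1/(4(1−x/L_c)²) − 1/4 + x/L_c],

   and the single-molecule filter: traces are kept only if they show the
   ddFLN4 fingerprint (34 nm total release, normally in two substeps), one
   45 nm cohesin increment and a final handle rupture.
4. **Rupture statistics** (`smfskit.bellevans`, `smfskit.fitting`) — the
   Bell-Evans rupture-force density at loading rate r,

   p(F) = (k₀/r)·exp[(Δx/k_BT)·F − (k₀·k_BT/(r·Δx))·(e^{Δx·F/k_BT} − 1)],

   fitted to force histograms (bin-averaged, Levenberg-Marquardt), KDE
   modes for non-Bell-shaped distributions, and the dynamic force
   spectrum: the most probable force grows linearly in ln r,

   ⟨F(r)⟩ = (k_BT/Δx)·ln(r·Δx/(k₀·k_BT)),

   whose fit yields the distance to the transition state Δx and the
   zero-force off rate k₀ with covariance-based standard deviations.
5. **Panels** (`smfskit.pipeline`, CLI `smfskit`) — constructs ×
   {apo, bound, control} × pulling speeds end to end, with apo-vs-bound
   most-probable-force shifts, negative-control checks and per-construct
   dynamic force spectra.

Since rupture datasets of this kind are generally not deposited, the
verification surface is **parameter recovery**: simulate from published
kinetic parameters, analyze, and confirm the parameters come back.

## Worked example

```python
from smfskit.experiments import COH1_APO, COH1_BOUND, dfs_recovery, fingerprint_experiment

for name, p in [("apo", COH1_APO), ("bound", COH1_BOUND)]:
    fit = dfs_recovery(p, n_per_rate=2000, seed=1)
    print(f"Coh1 {name:5s}  generated dx={p.delta_x:.2f} nm, k0={p.k0:.2g}/s  "
          f"recovered dx={fit.params.delta_x:.3f} +/- {fit.param_sds[0]:.3f} nm, "
          f"k0={fit.params.k0:.2g}/s")

res = fingerprint_experiment(n_curves=500, seed=1)
print(f"fingerprint: {res.n_accepted}/{res.n_curves} traces accepted "
      f"({100*res.acceptance_rate:.1f}%)")
print(f"median ddFLN4 increment = {res.fingerprint_median_nm:.2f} nm, "
      f"median cohesin increment = {res.cohesin_median_nm:.2f} nm")
```

prints

```
Coh1 apo    generated dx=0.34 nm, k0=0.013/s  recovered dx=0.341 +/- 0.007 nm, k0=0.013/s
Coh1 bound  generated dx=0.16 nm, k0=0.0086/s  recovered dx=0.161 +/- 0.003 nm, k0=0.0087/s
fingerprint: 479/500 traces accepted (95.8%)
median ddFLN4 increment = 34.27 nm, median cohesin increment = 45.11 nm
```

The first two lines are the dynamic-force-spectrum loop: 2000 rupture
forces per loading rate are drawn from the Bell-Evans density at four
rates spanning 10³–10⁵ pN/s, the per-rate most probable force is taken as
the KDE mode, and the force–ln(rate) line is fitted; the generating Δx and
k₀ come back within the fit uncertainty. The last two lines run the full
curve-level pipeline on 500 noisy simulated curves; the fingerprint filter
keeps ~96% of the (all-clean) traces and the measured contour-length
increments land on the configured 34 nm / 45 nm releases.

A full comparative panel from the shell:

```sh
smfskit panel --config panel.json --seed 1 --out out/
smfskit figures --report out/report.json --out out/figs
```

where `panel.json` lists constructs with their apo/bound (and optionally
control) Bell-Evans parameters, pulling speeds and curves per cell.

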