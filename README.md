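# piecewisefc

Piecewise group-level phase-synchrony connectivity analysis for
event-locked EEG (oddball paradigms), with a fully specified synthetic
generator so every stage can be validated against known ground truth.

## The problem

Event-related EEG connectivity is non-stationary: functional links appear
and disappear within a single stimulus-locked epoch, so a single
whole-epoch synchrony estimate both blurs real effects and inflates noise.
This package implements a piecewise, multi-subject analysis for
two-condition (target / non-target) epoched EEG:

1. **Subject-level synchrony.** For each channel pair (*c, c′*), frequency
   *f* and time sample *t*, the per-trial cross-spectrum
   ΔΦ<sub>ft</sub>(n; c, c′) = W<sub>ft</sub>(n; c) W*<sub>ft</sub>(n; c′)
   is formed from complex Morlet wavelet coefficients, and the trial
   ensemble is reduced to either

   - **PLI** = |E<sub>n</sub>{sgn Im ΔΦ}| — the phase-lag index, the
     consistency of the lead/lag sign across trials, or
   - **wPLI** = |E<sub>n</sub>{Im ΔΦ}| / E<sub>n</sub>{|Im ΔΦ|} — the
     weighted phase-lag index, which down-weights near-zero-lag trials and
     is therefore insensitive to the instantaneous (volume-conduction)
     mixing that produces spurious zero-lag coupling.

   Values are averaged over the bins of a rhythm band
   (δ = [2–5], θ = [5–8], α = [8–14], β = [14–30] Hz; closed edges).

2. **Quasi-stationary windows.** The epoch is split into non-overlapping
   windows τ<sub>i</sub> — fixed length τ, a single whole-epoch window
   (the stationary baseline), or variable windows placed at the change
   points of a time-resolved CSP+LDA decoding-accuracy curve — and each
   link's synchrony is reduced to its within-window expectation
   ỹ<sub>i</sub><sup>mΩλ</sup>(v), per subject *m* and condition λ.

3. **Link selection.** Either unsupervised (*pUTh*: keep links whose
   across-subject mean reaches a fraction *q* of the strongest link) or
   supervised (*pSTh*: two-sided Mann–Whitney between target and
   non-target values — across the M subjects within each window, and
   across the N<sub>τ</sub> windows within each subject — with
   Benjamini–Hochberg FDR across links). The per-window masks
   κ<sub>i</sub>(v) and per-subject masks κ<sub>m</sub>(v) combine as

   κ(v) = (κ₁ ∨ … ∨ κ<sub>N<sub>τ</sub></sub>) ∧ (κ₁ ∨ … ∨ κ<sub>M</sub>),

   i.e. a link must show a label effect in at least one window *and* in at
   least one subject's window dynamics.

4. **Brain-graph summaries.** Network density D = |κ| / V with
   V = C(C−1)/2, node strength
   γ<sub>t</sub>(v) = κ(v) Σ<sub>m</sub> ŷ<sub>t</sub><sup>m</sup>(v)
   unfolded onto channels, per-channel relevance counts for topographic
   export, and a leave-subjects-out consistency report that books which
   links appear/disappear when subjects are removed.

The synthetic generator plants time-localised, narrow-band, phase-lagged
couplings in chosen channel pairs and conditions, so sensitivity,
false-positive rate, type-I control and zero-lag robustness are all
measurable quantities rather than hopes.

## Worked example

```python
import numpy as np
import piecewisefc as pfc

# 8 subjects, 6 channels, 80 trials (20% targets): one theta coupling
# planted target-only at pi/2 lag between channels 0 and 3 in [0.2, 0.5] s
params = pfc.SimulationParams(
    M=8, C=6, N=80, fs=250.0, snr=2.5, seed=21,
    couplings=[pfc.PlantedCoupling(pair=(0, 3), band_center=6.5,
                                   phase_lag=np.pi / 2,
                                   window=(0.2, 0.5), condition="target")])
dataset, truth = pfc.simulate_dataset(params)

gen = np.random.default_rng(0)
per_subject = [pfc.subject_connectivity(sub, "theta", metric="wpli", rng=gen)
               for sub in dataset]
scheme = pfc.make_fixed_windows((0.0, 0.8), 0.1)   # 8 windows of 100 ms
wc = pfc.stack_windowed(per_subject, scheme)

result = pfc.psth(wc, alpha=0.05)                  # supervised selection
combined = result["combined"].values

from piecewisefc.links import link_pairs
pairs = link_pairs(6)
print("selected links:", [tuple(map(int, pairs[v]))
                          for v in np.flatnonzero(combined)])
print(f"network density: {pfc.network_density(combined):.3f}")
summary = pfc.confidence_summary(result["tests_windows"], result["combined"])
print(f"min p over selected links: {summary['min_p']:.2e}")
```

prints

```
selected links: [(0, 3)]
network density: 0.067
min p over selected links: 1.55e-04
```

— the single planted link (0, 3) is recovered, it is the only one of the
15 possible links selected (density 1/15 ≈ 0.067), and the strongest
window-level target/non-target contrast on it reaches p ≈ 1.5 × 10⁻⁴
before FDR.

The same pipeline is available from the shell:

```sh
piecewise-fc simulate --config sim.yaml --out dataset/
piecewise-fc run --config run.yaml
```

where `run.yaml` names the data (or simulation parameters), metric, bands,
windowing mode, thresholding rule and seed; the run writes per-stage
outputs plus a manifest with content hashes, so identical configs produce
verifiably identical results.

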