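"""Time-resolved category decodability with a planted evoked transient.

Plants a car-selective occipital response at 150 ms (amplitude five times
the noise innovation) in 10 simulated subjects, computes the pair-averaged
pooled category d' curve, and reports when it first becomes reliably
above its pre-stimulus baseline (latency) and where it peaks.
"""

from eegmvpa import group_dimension_curve
from eegmvpa.synth import EffectSpec, SynthConfig, generate_group
from eegmvpa.timestats import latency_peak, signed_rank_vs_baseline

effect = EffectSpec(dimension="category", level="car", spatial_pattern="occipital",
                    onset_ms=150.0, width_ms=5.0, amplitude=25.0)
cfg = SynthConfig(n_subjects=10, epoch_window=(-150.0, 249.0),
                  noise_sd=5.0, effects=(effect,), seed=7)
datasets = generate_group(cfg)

raw = group_dimension_curve(datasets, "category", baseline=False)
trace = signed_rank_vs_baseline(raw, baseline_window=(-150.0, 0.0))
lp = latency_peak(raw, trace)

print(f"group curve: {raw.values.shape[0]} subjects x {raw.values.shape[1]} bins")
print(f"latency  : {lp.latency_ms:.0f} ms  (first sustained significant bin; "
      "expected within ~20 ms of the planted 150 ms transient center)")
print(f"peak     : {lp.peak_ms:.0f} ms, d' = {lp.peak_value:.2f} "
      "(raw pooled-category d'; the planted transient dominates)")
n_sig = int(trace.significant.sum())
print(f"{n_sig} of {int((raw.time_ms > 0).sum())} post-stimulus bins significant "
      "(Wilcoxon signed-rank vs pre-stimulus baseline, FDR q < 0.05)")
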