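"""Electrode-wise decodability: where on the scalp is the information?

Each electrode's d' is computed in that electrode's one-dimensional
voltage space and averaged over a +/-25 ms window; with an occipital
planted effect the posterior electrodes should carry the map's maxima.
"""

from eegmvpa import scalp_map
from eegmvpa.design import PERI_OCCIPITAL, generate_design
from eegmvpa.synth import EffectSpec, SynthConfig, generate_subject

effect = EffectSpec("category", "car", "occipital", onset_ms=150.0,
                    width_ms=5.0, amplitude=25.0)
cfg = SynthConfig(epoch_window=(-150.0, 249.0), effects=(effect,), seed=3)
ds = generate_subject(generate_design(), cfg, 1)

m = scalp_map(ds, ("category", "car", "face"), center_ms=150.0,
              baseline_window=(-150.0, 0.0))
top = m.top_channels(9)
print(f"scalp map at {m.center_ms:.0f} ms (averaged {m.averaging_window[0]:.0f}"
      f"..{m.averaging_window[1]:.0f} ms), {m.values.size} electrodes")
print("top 9 electrodes:", ", ".join(top))
print("planted (peri-occipital) group:", ", ".join(sorted(PERI_OCCIPITAL)))
print(f"recovered {len(set(top) & set(PERI_OCCIPITAL))}/9 planted electrodes in the top 9")
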