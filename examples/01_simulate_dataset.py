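"""Simulate a small epoched-EEG study and write it to disk.

The design is the 192-image factorial (4 categories x 4 exemplars x
4 variation types x 3 levels); each subject sees every image 3 times
(576 trials), recorded on 31 channels and reduced to 5 ms bins.
"""

from pathlib import Path

from eegmvpa import generate_design, generate_group, write_epochs
from eegmvpa.synth import SynthConfig

design = generate_design()
print(f"stimulus design: {len(design)} images, "
      f"{design.groupby(['category', 'exemplar']).ngroups} objects")

cfg = SynthConfig(n_subjects=2, seed=1)
datasets = generate_group(cfg)
for ds in datasets:
    print(f"subject {ds.subject_id}: voltages {ds.voltages.shape} "
          f"(channels x 5ms-bins x trials), epoch {ds.time_ms[0]:.0f}..{ds.time_ms[-1]:.0f} ms")

out = Path("scratch/example_dataset")
for ds in datasets:
    write_epochs(ds, out / f"subject_{ds.subject_id:02d}")
print(f"wrote dataset directories under {out}/ (binary float32 + JSON + TSV)")
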