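"""Generate a synthetic comparative phosphoproteomics study and save it.

Creates 5 training species (2 datasets each) and 5 paired test species of
serine-centered 21-mer windows with kingdom-specific planted motifs, then
writes the window tables and the study design to ./study_out/.
"""

from pathlib import Path

import phosphosig as ps
from phosphosig import io

out = Path("study_out")
out.mkdir(exist_ok=True)

cfg = ps.SimulationConfig(seed=1, windows_per_dataset=200)
train, test, design, truth = ps.generate_study(cfg)

for (species, dataset), windows in train.items():
    io.write_window_table(windows, out / f"train_{species}_{dataset}.tsv")
for species, windows in test.items():
    io.write_window_table(windows, out / f"test_{species}.tsv")
io.write_study_design(design, out / "design.yaml")

print(f"training datasets: {len(train)}, test datasets: {len(test)}")
print(f"windows per dataset: {cfg.windows_per_dataset}")
for kingdom, motifs in truth.items():
    patterns = ", ".join(m.pattern for m in motifs)
    print(f"  {kingdom:12s} planted motif: {patterns} "
          f"(stamped in ~{motifs[0].insertion_prob:.0%} of windows)")
print(f"wrote window tables and design.yaml to {out}/")
# Each kingdom's motif is a fixed block around the phosphoserine; the
# pipeline should later recover its sub-n-grams as kingdom-specific.
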