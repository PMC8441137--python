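"""Simulate the working audit dataset.

Generates one synthetic literature audit with the default study conditions
(560 papers published over six decades, four study types, exponential data
decay, a 40-paper reproduction subsample with nested stage counts), prints
its count bookkeeping, and writes the tables under results/synthetic/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from datadecay.audit import summarize_counts, write_audit_table
from datadecay.simulate import SimulationConfig, TrueParams, simulate_dataset

SEED = 20240901

out = ROOT / "results" / "synthetic"
out.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(seed=SEED)
dataset, latents = simulate_dataset(cfg, TrueParams())
write_audit_table(dataset, out / "papers.csv", out / "results.csv")
latents.paper_effects.to_csv(out / "latents_paper.csv", index=False)
latents.year_effects.to_csv(out / "latents_year.csv", index=False)

counts = summarize_counts(dataset)
(out / "counts.txt").write_text(counts.as_text() + "\n")
print(f"seed {SEED}: wrote {out}/papers.csv and results.csv")
print(counts.as_text())
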