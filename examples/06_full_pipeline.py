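"""Run every stage through the config-driven pipeline driver.

Equivalent to `gliarev run --config cfg.yaml` on the shell; each stage
persists a table so any stage can be re-run later from disk.
"""

import gliarev as g

config = {
    "seed": 7,
    "outdir": "scratch/example_run",
    "input": {"simulate": {"n_cells_per_sample": 150, "n_genes": 1200}},
    "stages": ["qc", "cluster", "dam", "trajectory", "de", "reversal", "genesets"],
    "trajectory": {"celltypes": ["oligodendrocyte"]},
    "de": {"celltypes": ["microglia"]},
}

status = g.run_pipeline(config)
print(f"pipeline exit status: {status}")

import pandas as pd

rev = pd.read_csv("scratch/example_run/reversal.csv")
print("\nreversal estimates:")
print(rev.round(3).to_string(index=False))
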