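"""Simulate a paired single-cell Hi-C + methylation dataset and write it out.

The generator plants cell-type structure in the Hi-C contacts (one clique
of promoters per type) and couples methylation to sequence and clique
membership, so the written files contain a learnable signal.
"""

import tempfile

import numpy as np

from promethyl import SimConfig, simulate_dataset, write_dataset

config = SimConfig(
    n_chroms=1, chrom_length=120_000, n_promoters=12,
    cell_types=("A", "B"), cells_per_type=10, clique_size=4, seed=7,
)
ds = simulate_dataset(config)

with tempfile.TemporaryDirectory() as outdir:
    manifest = write_dataset(ds, outdir)
    print(f"wrote dataset to {outdir} (manifest: {manifest})")

n_contacts = [len(c.contacts) for c in ds.cells]
n_calls = [len(c.methylation) for c in ds.cells]
levels = ds.cpg_probs["probability"]
print(f"cells: {len(ds.cells)} ({', '.join(sorted(set(ds.truth['cell_type'])))})")
print(f"contacts per cell: median {int(np.median(n_contacts))}")
print(f"methylation calls per cell: median {int(np.median(n_calls))}")
print(f"planted CpG methylation probability: mean {levels.mean():.3f} "
      f"(clique CpGs are shifted up by beta_topo on the logit scale)")
# Each cell is one sparse contact list + one sparse coverage file; the truth
# table records the planted type of every cell for later scoring.
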