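"""Run the whole pipeline end to end and print the run report.

simulate -> classify -> noise -> introns -> models, all in one seeded run
directory with a digest manifest; equivalent to
`gbmnoise all --seed 5 --outdir runs/demo` on the command line.
"""

from gbmnoise.config import SimConfig
from gbmnoise.pipeline import run_all, summarize_run

outdir = "runs/demo"
cfg = SimConfig(seed=5, n_genes=600, reads_per_cell=5000)
manifest = run_all(cfg, outdir)
print(f"{len(manifest['digests'])} output files written to {outdir}\n")
print(summarize_run(outdir))
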