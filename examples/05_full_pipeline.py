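"""One reproducible end-to-end run: simulate -> classify -> enrich -> network.

Writes labeling/cluster/enrichment/network files plus report.md into the
output directory; rerunning with the same seed reproduces every file byte
for byte.
"""

from tfinet import pipeline
from tfinet.simulate import SimConfig

config = pipeline.RunConfig(seed=42, sim=SimConfig(n_genes=200, seed=42))
issues = pipeline.validate_config(config)
assert not issues, issues

outdir = pipeline.run_all(config, "pipeline_demo")
print((outdir / "report.md").read_text())
# the report states the TFI count, recovery vs planted truth, DE counts,
# per-class enrichment of the called TFI set, and the network statistics
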