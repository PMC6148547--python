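"""Run the complete cascade end-to-end on a synthetic bundle and compare
the report against the planted ground truth.

Equivalent to `mirkey simulate` + `mirkey run`, but entirely in memory.
"""

import json

from mirkey import SyntheticConfig, run_stages, synthetic_inputs

cfg = SyntheticConfig(seed=42)
inputs, truth = synthetic_inputs(cfg)
report = run_stages(inputs, seed=42)

print(json.dumps(report.summary, indent=1, sort_keys=True))
print("\nplanted anchors:   ", truth.anchor_genes)
print("reported key genes:", report.summary["key_genes"])
print("designated pathways:", truth.designated_pathways)
print("crucial pathways:   ", report.summary["crucial_pathways"])
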