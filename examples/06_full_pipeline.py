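"""End-to-end run: synthetic bundle in, stratified-test report out.

Simulates a dataset (structures, sequences, exon tables, mappings),
then runs the complete analysis: interface extraction, reference
selection, mask construction, redundancy reduction, decoy generation,
and the CMH tests over a threshold grid.
"""

import tempfile
from pathlib import Path

from spliceshield.pipeline import RunConfig, run_full_analysis
from spliceshield.simulate import SimConfig, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    out = Path(tmp) / "report"
    simulate_dataset(SimConfig(n_genes=12, bias=0.3, seed=5), bundle)
    cfg = RunConfig(
        input_dir=str(bundle),
        out_dir=str(out),
        thresholds=[10, 30, 50, 70, 100],
        n_controls=300,
        seed=5,
    )
    summary = run_full_analysis(cfg)
    results = summary["results"]
    print(results.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("\nfiles written:", sorted(p.name for p in out.iterdir()))
# Each row is one mode × test × threshold: the pooled real and
# randomized removal frequencies, the CMH statistic, and its p-value.
# The provenance block (seed, config hash) makes the run reproducible.
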