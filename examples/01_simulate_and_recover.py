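"""Simulate a phosphoproteomics experiment and recover planted kinase activities.

Plants +/-1 log2-unit activity shifts on 20 of 120 kinases, generates
peptide-level evidence (2 fragments per site group, sigma = 0.5 log2 units
of measurement noise, 5% missing values, 3 replicates per condition), runs
the full pipeline and prints how well the kinase z-scores recover the truth.
"""

import json
from pathlib import Path
import tempfile

from phosphokin import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        output_dir=str(Path(tmp) / "demo"),
        mode="simulate",
        contrast=("treated", "control"),
        seed=1,
    )
    out = run_pipeline(cfg)
    report = json.loads((out / "recovery.json").read_text())

print("Recovery of planted kinase activities")
print(f"  sign accuracy            : {report['sign_accuracy']:.3f}")
print(f"  rank corr (active only)  : {report['rank_correlation_active']:.3f}")
print(f"  rank corr (all kinases)  : {report['rank_correlation']:.3f}")
print(f"  null kinases with P<0.05 : {report['type1_error']:.3f}")
print()
print("Sign accuracy is the fraction of the 20 planted kinases whose inferred")
print("Z carries the planted direction; the active-only rank correlation is")
print("Spearman between planted shifts and Z where ranks are informative (the")
print("all-kinase value is capped at 0.648 by the 100 tied null kinases); the")
print("last line is the false-positive rate on the 100 null kinases.")
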