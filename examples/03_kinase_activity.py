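"""The substrate-set kinase activity z-score on a hand-checkable fixture.

Six detected site groups carry log2 fold changes {1, -1, 1, -1, 2, -2}
(mean mu = 0, sample SD s = sqrt(2.4)). One kinase targets the sites with
fold changes {1, 2}, so M = 1.5, se = s/sqrt(2), Z = (M - mu)/se = 1.369
and the two-tailed normal P is 0.171.
"""

import pandas as pd

from phosphokin import KinaseSubstrateMap, infer_kinase_activities

fold_changes = pd.Series({
    "P1_S1": 1.0, "P2_S2": -1.0, "P3_S3": 1.0,
    "P4_S4": -1.0, "P5_S5": 2.0, "P6_S6": -2.0,
})
ksmap = KinaseSubstrateMap({"KIN1": frozenset({"P1_S1", "P5_S5"})})

result = infer_kinase_activities(fold_changes, ksmap, min_substrates=2)
print(result[["kinase", "m", "M", "mu", "s", "se", "Z", "pvalue", "significant"]]
      .round(4).to_string(index=False))
print()
print("m substrates were detected; their mean fold change M sits Z standard")
print("errors above the overall mean mu, where se = s/sqrt(m) scales the")
print("spread s of all detected fold changes. P = 0.171 > 0.05: two substrates")
print("are not enough evidence for a real activity shift here.")
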