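"""Screen designs the way the selection pipeline does.

Shows the composite confidence score (pTM x pLDDT x TM-score, top-3 models),
the prediction agreement/convergence filter and the per-position 9-mer
fragment-quality filter on small constructed tables.
"""

from igtandem.filters import (composite_score, af2_agreement_filter,
                              fragment_quality_filter)

records = [(0.92, 95.0, 0.96), (0.90, 94.0, 0.95), (0.89, 93.0, 0.94),
           (0.40, 70.0, 0.50), (0.91, 92.0, 0.93)]
result = composite_score(records)
print(f"composite score over top-3 models: {result.score:.3f} "
      f"-> verdict: {result.verdict} (discard <= 0.6, select > 0.7)")

stats = [{"plddt": 93.0, "rmsd": 0.6}, {"plddt": 95.0, "rmsd": 0.8},
         {"plddt": 96.0, "rmsd": 0.4}, {"plddt": 92.0, "rmsd": 0.9},
         {"plddt": 88.0, "rmsd": 1.3}]
basic = af2_agreement_filter(stats, min_passing=1)
conv = af2_agreement_filter(stats, min_passing=5)
print(f"agreement (>=1 of 5 with pLDDT>90, RMSD<1Å): "
      f"{'pass' if basic.passed else 'fail'} ({basic.n_passing}/5 models)")
print(f"convergence (all 5): {'pass' if conv.passed else 'fail'} "
      f"— one low-confidence model breaks it")

fragments = [[0.4, 0.9], [0.6], [1.1, 0.8], [0.95]]
verdict = fragment_quality_filter(fragments, threshold=1.0)
print(f"fragment filter at 1.0 Å: {'pass' if verdict.passed else 'fail'} "
      f"(every position needs one 9-mer strictly below the bound)")
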