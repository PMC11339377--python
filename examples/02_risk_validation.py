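"""Validate a forest-loss-risk surface against a realised loss map.

Realised loss is simulated by flipping a coin per forest cell with its own
risk probability — so the risk surface is a well-calibrated but imperfect
predictor, exactly the situation point-based validation measures.
"""

import numpy as np

from cfreserve import SyntheticConfig, generate_landscape, validate_risk

land = generate_landscape(SyntheticConfig(seed=3))
rng = np.random.default_rng(99)

truth = land.risk.like((rng.random(land.risk.shape) < land.risk.values).astype(float))

result = validate_risk(land.risk, truth, n=3000, seed=1)
print(f"AUC          {result.auc:.2f}   (rank-based; 0.5 = chance)")
print(f"sensitivity  {result.sensitivity:.2f}   (true-positive rate at the kappa-optimal cut)")
print(f"specificity  {result.specificity:.2f}   (true-negative rate)")
print(f"PCC          {result.pcc:.2f}   (fraction classified correctly)")
print(f"cut-point    {result.cutpoint:.2f}   (threshold maximising Cohen's kappa)")

# Specificity typically exceeds sensitivity here: cells with low predicted
# risk almost never convert, while loss among mid-risk cells is a coin flip.
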