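"""Family-wise Bayesian model selection over the semantic model space.

The 27 base modulation patterns partition three ways (task, laterality,
dorsoventral level). Synthetic group evidence favoring word-driven, left-
lateralized modulation is analyzed with random-effects BMS, and a found
model is credited to families by modulation-bit agreement.
"""

import numpy as np

from dcmsearch import EvidenceMatrix, build_semantic_families, \
    match_to_families, rfx_gibbs
from dcmsearch.semantic import semantic_constraints

spec = semantic_constraints()
scheme = build_semantic_families(spec)

# synthetic group evidence: subjects favor "Words/Left/*" base patterns
rng = np.random.default_rng(0)
cols = [format(0, "08b") + p.bits for p in scheme.patterns]
fe = rng.normal(0.0, 0.5, size=(10, 27))
boost = [k for k, p in enumerate(scheme.patterns)
         if p.family["task"] == "Words" and p.family["laterality"] == "Left"]
fe[:, boost] += 5.0

for partition in ("task", "laterality"):
    res = rfx_gibbs(EvidenceMatrix(fe, cols), families=scheme,
                    partition=partition, n_samples=8000, burn_in=800, seed=1)
    lead = np.argmax(res.expected_probability)
    print(f"{partition}: expected family probabilities "
          f"{dict(zip(res.columns, np.round(res.expected_probability, 3).tolist()))}")
    print(f"  winner: {res.columns[lead]} "
          f"(exceedance {res.exceedance_probability[lead]:.3f})")

# credit a search result to families through its modulation bits
found = spec.structure("10110011" + "00001100")  # Words on left regions
credit = match_to_families(found, scheme)
print("found model family credit:",
      {p: {k: round(v, 2) for k, v in c.items() if v > 0}
       for p, c in credit.items()})
# Exceedance probability is the chance the family is the most frequent in
# the population; the credit dict shows how a single found model supports
# each hypothesis about the network.
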