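"""Interaction confidence scoring from experimental evidence.

Simulates evidence counts (e.g. assays and publications per interaction)
from a known logistic model, refits the model, and scores interactions.
The scores are probabilities in (0, 1) and can be used directly as edge
confidences for reconstruction.
"""

import numpy as np

from anchornet.fixtures import generate_evidence
from anchornet.scoring import (
    ConfidenceModel,
    EvidenceRecord,
    fit_confidence_model,
    score_interactions,
)

truth = ConfidenceModel(
    intercept=-1.0, coefficients=np.array([0.8, -0.5]), lam=0.0,
    schema=("assays", "publications"),
)
pairs = [(f"P{i:04d}", f"Q{i:04d}") for i in range(5000)]
records, labels = generate_evidence(pairs, truth, seed=1)

model = fit_confidence_model(records, labels, lam=0.0, schema=truth.schema)
print(f"true model:   intercept {truth.intercept:+.3f}, "
      f"coefficients {truth.coefficients}")
print(f"fitted model: intercept {model.intercept:+.3f}, "
      f"coefficients {np.round(model.coefficients, 3)}")

examples = [
    EvidenceRecord(("EGFR", "GRB2"), (3.0, 2.0)),
    EvidenceRecord(("EGFR", "RAND1"), (0.0, 0.0)),
]
for pair, conf in score_interactions(model, examples).items():
    print(f"confidence {pair[0]}-{pair[1]}: {conf:.3f}")

# A well-supported interaction (many assays) scores high; an unsupported
# pair falls back to roughly sigmoid(intercept) ~ 0.27.
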