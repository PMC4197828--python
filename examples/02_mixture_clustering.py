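"""Cluster expression profiles with the volume-varying Gaussian mixture.

Draws profiles from a known three-component mixture (shared orientation
and shape, distinct volumes), selects the component number by BIC, and
classifies profiles with the misassignment-controlled threshold-MAP rule.
"""

import numpy as np

from mapktome import gen_mixture_profiles, select_K, threshold_map_assign, unit_det_shape

C = unit_det_shape(np.array([[1.0, 0.25], [0.25, 1.0]]))
means = np.array([[0.0, 0.0], [2.2, 0.0], [0.0, 2.2]])
X, labels = gen_mixture_profiles(
    3000, 2, 3, proportions=[0.3, 0.4, 0.3], means=means,
    volumes=[0.7, 1.0, 1.5], shape_matrix=C, seed=4,
)

model, trace = select_K(X.to_numpy(), K_range=range(2, 6), n_starts=4, seed=0)
print("BIC trace (lower is better):")
print(trace.round(1).to_string(index=False))
print(f"\nselected K = {model.K}; fitted volumes {np.sort(model.volumes).round(2)} "
      f"(planted 0.7, 1.0, 1.5 up to scale)")

assignment = threshold_map_assign(model, X.to_numpy(), alpha=0.05)
print(f"\nthreshold tau = {assignment.tau:.3f}: {assignment.n_classified} of {len(X)} "
      f"profiles classified; estimated misassignment {100 * assignment.fap:.1f}% "
      f"(about {assignment.expected_misassigned} profiles), controlled at 5%")

mask = assignment.table["classified"].to_numpy()
from mapktome.validation import best_match_error

err = best_match_error(labels[mask], assignment.table["label"].to_numpy()[mask])
print(f"true misclassification among classified: {100 * err:.1f}% — the rule "
      "trades coverage for accuracy on overlapping components")
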