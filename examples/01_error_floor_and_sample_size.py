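"""How accurate can a two-class linear discriminant possibly be?

For two Gaussian classes with shared covariance sigma^2*I whose centroids sit
a distance d from the ideal boundary, the misclassification probability has a
closed form that no amount of training data can beat.  The Monte Carlo
experiment then shows the extra penalty of estimating the boundary from a
finite sample: the 95% band of training accuracy at n = 59 points per class.
"""

import numpy as np

from pfda_audit import SeparationSpec, accuracy_experiment, pwrong
from pfda_audit.power import batch_training_accuracy

d, sigma = 1.7, 1.414
print(f"error floor P_wrong(d={d}, sigma={sigma}) = {pwrong(d, sigma):.3f}")
print(f"  -> best possible training accuracy {1 - pwrong(d, sigma):.3f}")

ci = accuracy_experiment(SeparationSpec(n_per_class=59, sigma=sigma, trials=10_000, seed=1))
print(f"at n = 59/class over 10,000 trials: median A = {ci.median:.3f}, "
      f"95% band ({ci.lo:.3f}, {ci.hi:.3f})")
print("  -> even the optimistic training accuracy swings by "
      f"{ci.width:.3f} purely from sampling")

acc = batch_training_accuracy(2560, 1.0, 2.0, 5_000, np.random.default_rng(2))
print(f"A_LB (2.5th pct) at d/sigma = 2.0, n = 2560: {np.percentile(acc, 2.5):.3f}")
print("  -> only at d/sigma ~ 2 and thousands of points does the lower bound "
      "approach the 0.975 needed for P_rand <= 0.05")
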