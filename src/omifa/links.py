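"""Link functions for the non-gaussian noise models.

Counts are modelled as y ~ Poisson(lambda(x)) with the softplus rate link
lambda(x) = log(1 + e^x); binary data as y ~ Bernoulli(sigma(x)) with the
logistic link. Both are overflow-safe for |x| up to at least 1e3.
"""

import numpy as np
from scipy.special import expit


def link_lambda(x):
    """Softplus rate link, log(1 + e^x)."""
    return np.logaddexp(0.0, x)


def link_sigma(x):
    """Logistic link, 1 / (1 + e^-x)."""
    return expit(x)
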