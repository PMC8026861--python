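"""Direct-formula reference implementations used by the acceptance script.

Written straight from the defining equations and independent of the
package internals; they serve only to measure formula-level agreement.
"""

from __future__ import annotations


def _fixed_pooled(thetas, variances):
    w = [1.0 / v for v in variances]
    return sum(wi * ti for wi, ti in zip(w, thetas)) / sum(w)


def cochran_q_direct(thetas, variances) -> float:
    mu = _fixed_pooled(thetas, variances)
    return sum((t - mu) ** 2 / v for t, v in zip(thetas, variances))


def dl_tau2_direct(thetas, variances) -> float:
    k = len(thetas)
    q = cochran_q_direct(thetas, variances)
    w = [1.0 / v for v in variances]
    c = sum(w) - sum(wi * wi for wi in w) / sum(w)
    return max(0.0, (q - (k - 1)) / c)


def pooled_direct(thetas, variances):
    """(pooled effect, se) under the Q<=df fixed / else DL-random rule."""
    k = len(thetas)
    q = cochran_q_direct(thetas, variances)
    if q <= k - 1:
        w = [1.0 / v for v in variances]
    else:
        tau2 = dl_tau2_direct(thetas, variances)
        w = [1.0 / (v + tau2) for v in variances]
    pooled = sum(wi * ti for wi, ti in zip(w, thetas)) / sum(w)
    return pooled, sum(w) ** -0.5
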