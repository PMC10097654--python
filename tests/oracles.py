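"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form conjugate algebra used by the
package: the posterior is evaluated by brute-force dense-grid integration
of likelihood x prior so the two routes can disagree.
"""

import numpy as np
from scipy.special import logsumexp


def grid_slope_quantiles(x, y, prior, probs):
    """Marginal slope quantiles by dense-grid numerical integration over
    (intercept, slope, sigma^2) for the Gaussian linear model with a
    normal-inverse-gamma prior."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(y)
    b1c, b0c = np.polyfit(x, y, 1)
    resid = y - (b0c + b1c * x)
    s2h = float(resid @ resid) / max(n - 2, 1)
    sxx = ((x - x.mean()) ** 2).sum()
    se1 = np.sqrt(s2h / sxx)
    se0 = np.sqrt(s2h * (1 / n + x.mean() ** 2 / sxx))

    b1 = np.linspace(b1c - 12 * se1, b1c + 12 * se1, 1601)
    b0 = np.linspace(b0c - 12 * se0, b0c + 12 * se0, 301)
    ls2 = np.linspace(np.log(s2h) - 9, np.log(s2h) + 9, 301)
    s2 = np.exp(ls2)

    sy2, sy, sx_, sxy, sx2 = (y @ y, y.sum(), x.sum(), x @ y, x @ x)
    log_marg = np.empty(len(b1))
    for lo in range(0, len(b1), 200):
        c1 = b1[lo:lo + 200][:, None, None]
        c0 = b0[None, :, None]
        sse = (sy2 - 2 * c0 * sy - 2 * c1 * sxy + 2 * c0 * c1 * sx_
               + n * c0 ** 2 + c1 ** 2 * sx2)
        quad = sse + (c0 ** 2 + c1 ** 2) / prior.g
        lp = (-(n / 2 + 1) * ls2[None, None, :]     # likelihood + coef prior scale
              - quad / (2 * s2[None, None, :])
              - (prior.a0 + 1) * ls2[None, None, :]  # inverse-gamma on sigma^2
              - prior.b0 / s2[None, None, :]
              + ls2[None, None, :])                  # jacobian of the log grid
        log_marg[lo:lo + 200] = logsumexp(lp, axis=(1, 2))
    dens = np.exp(log_marg - log_marg.max())
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
    cdf /= cdf[-1]
    return np.interp(probs, cdf, b1)
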