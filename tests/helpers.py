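"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: brute-force
enumeration for the tie-respecting partition, dense grid quadrature for a
small logistic posterior, and a literal step-by-step DerSimonian-Laird
computation.
"""

import itertools

import numpy as np
from scipy.special import expit, logsumexp


def brute_force_partition(values, n_groups=5):
    """Enumerate every tie-respecting ordered partition of ``values`` into at
    most ``n_groups`` contiguous groups; return per-unique-value group indices
    of the partition nearest to equal size.

    Nearest to equal size == minimal sum of squared group sizes (the group
    count is fixed, so the two objectives coincide); ties resolve to the cut
    sequence minimal under right-to-left lexicographic comparison.
    """
    uniq, counts = np.unique(values, return_counts=True)
    b = len(uniq)
    m = min(b, n_groups)
    best_key, best_bounds = None, None
    for cuts in itertools.combinations(range(1, b), m - 1):
        bounds = (0,) + cuts + (b,)
        sizes = [int(counts[s:e].sum()) for s, e in zip(bounds[:-1], bounds[1:])]
        key = (sum(s * s for s in sizes), tuple(reversed(cuts)))
        if best_key is None or key < best_key:
            best_key, best_bounds = key, bounds
    groups = np.empty(b, dtype=int)
    for g, (s, e) in enumerate(zip(best_bounds[:-1], best_bounds[1:])):
        groups[s:e] = g
    return uniq, groups


def grid_posterior_mean_beta(X, y, prior_sds, n_points=41, half_width=5.0):
    """Posterior mean of the treatment coefficient by dense grid quadrature.

    Model: logit P(y=1) = X @ theta with independent Normal(0, prior_sds)
    priors.  The grid for each coefficient spans +-``half_width`` posterior
    SDs around the penalized MLE (found by Newton iterations).  Returns the
    posterior mean of theta[1] (the treatment coefficient).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    p = X.shape[1]
    prior_var = np.asarray(prior_sds, float) ** 2

    # Penalized MLE + curvature via Newton-Raphson.
    theta = np.zeros(p)
    for _ in range(50):
        mu = expit(X @ theta)
        grad = X.T @ (y - mu) - theta / prior_var
        W = mu * (1 - mu)
        hess = -(X.T * W) @ X - np.diag(1.0 / prior_var)
        step = np.linalg.solve(hess, grad)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-10:
            break
    sds = np.sqrt(np.diag(np.linalg.inv(-hess)))

    axes = [np.linspace(theta[j] - half_width * sds[j],
                        theta[j] + half_width * sds[j], n_points)
            for j in range(p)]
    # Collapse observations to unique covariate patterns for speed.
    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    successes = np.bincount(inverse, weights=y, minlength=len(patterns))
    totals = np.bincount(inverse, minlength=len(patterns))

    mesh = np.meshgrid(*axes, indexing="ij")
    theta_grid = np.stack([m.ravel() for m in mesh], axis=1)  # (G, p)
    lp = theta_grid @ patterns.T  # (G, patterns)
    loglik = lp @ successes - np.logaddexp(0.0, lp) @ totals
    logprior = -0.5 * np.sum(theta_grid**2 / prior_var, axis=1)
    logpost = loglik + logprior
    w = np.exp(logpost - logsumexp(logpost))
    return float(np.sum(w * theta_grid[:, 1]))


def dersimonian_laird_by_hand(tables):
    """Spreadsheet-style DL computation from (events_i, n_i, events_c, n_c) rows."""
    ys, vs = [], []
    for a, n1, c, n2 in tables:
        b, d = n1 - a, n2 - c
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        ys.append(np.log((a * d) / (b * c)))
        vs.append(1 / a + 1 / b + 1 / c + 1 / d)
    y, v = np.array(ys), np.array(vs)
    w = 1 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_fe) ** 2)
    k = len(y)
    tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w))) if k > 1 else 0.0
    w_re = 1 / (v + tau2)
    mu = np.sum(w_re * y) / np.sum(w_re)
    se = np.sum(w_re) ** -0.5
    return mu, se, tau2
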