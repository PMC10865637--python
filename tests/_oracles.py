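"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the Wilson interval is
recovered by root-finding on the score-test inversion, kappa by an explicit
tally-and-formula script, and expected success rates by numerical integration
of the logistic response over the truncated-normal pH distribution.
"""

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm


def wilson_by_root_finding(p_hat, n, level=0.95):
    """Bounds of {p0 : |p_hat - p0| <= z sqrt(p0(1-p0)/n)} via brentq."""
    z = norm.ppf(0.5 + level / 2)

    def score(p0):
        return (p_hat - p0) ** 2 - z * z * p0 * (1 - p0) / n

    # score() is positive outside the interval, negative inside; the score-test
    # centre is always strictly inside.
    eps = 1e-12
    inside = (p_hat + z * z / (2 * n)) / (1 + z * z / n)
    lower = brentq(score, eps, inside) if score(eps) > 0 else 0.0
    upper = brentq(score, inside, 1 - eps) if score(1 - eps) > 0 else 1.0
    return lower, upper


def kappa_from_table(a, b, c, d):
    """Cohen's kappa computed directly from 2x2 counts."""
    n = a + b + c + d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    return (p_o - p_e) / (1 - p_e)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def expected_success_fixed_rater(a, b, tau, ph_mean, ph_sd, lo, hi, n_grid=10_000):
    """Expected success rate of one (a, b) rater, integrating the logistic
    response over the truncated-normal pH density on each side of tau.

    The balanced design puts half the annotation mass on each side.
    """
    halves = []
    for side_lo, side_hi, hypoxic in ((lo, tau, True), (tau, hi, False)):
        al, be = (side_lo - ph_mean) / ph_sd, (side_hi - ph_mean) / ph_sd
        grid = np.linspace(side_lo + 1e-9, side_hi - 1e-9, n_grid)
        w = truncnorm.pdf(grid, al, be, loc=ph_mean, scale=ph_sd)
        w /= w.sum()
        p_hyp = _sigmoid(a + b * (tau - grid))
        correct = p_hyp if hypoxic else 1.0 - p_hyp
        halves.append(float((w * correct).sum()))
    return 0.5 * halves[0] + 0.5 * halves[1]


def expected_success_default_cohort(cfg, n_ph=2_000, n_nodes=21):
    """Expected pooled success under a generator config, integrating over the
    bias (normal) and discrimination (log-normal) distributions with
    Gauss-Hermite quadrature on top of the pH integration."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w_norm = weights / weights.sum()
    a_vals = cfg.bias_mean + cfg.bias_sd * nodes
    b_vals = np.exp(np.log(cfg.discrimination_median) + cfg.discrimination_sigma_log * nodes)
    total = 0.0
    for a, wa in zip(a_vals, w_norm):
        for b, wb in zip(b_vals, w_norm):
            total += wa * wb * expected_success_fixed_rater(
                a, b, cfg.threshold, cfg.ph_mean, cfg.ph_sd, *cfg.ph_bounds, n_grid=n_ph
            )
    return total


def fixed_design_se_of_b(ph, tau, a, b):
    """Asymptotic SE of the ML discrimination estimate for a rater shown the
    fixed case set ``ph``, from the 2x2 Fisher information of the logistic fit."""
    x = tau - np.asarray(ph, dtype=float)
    p = _sigmoid(a + b * x)
    w = p * (1 - p)
    info = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    return float(np.sqrt(np.linalg.inv(info)[1, 1]))
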