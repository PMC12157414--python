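"""Independent reference implementations used only to check aseqc.

Each oracle takes a route disjoint from the package's own code path:
adaptive quadrature instead of fixed-order Gauss-Hermite, explicit Python
loops instead of vectorized kernels.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import gammaln


def _log_sig(z: float) -> float:
    return -np.logaddexp(0.0, -z)


def bln_log_pmf_quad(r: int, t: int, mu: float, sigma: float) -> float:
    """BLN log pmf by adaptive quadrature over the latent logit ratio.

    The integrand is exponentiated after shifting by its maximum (located by
    bounded scalar minimization) so the integral never underflows.
    """

    def g(z: float) -> float:
        return (
            r * _log_sig(z)
            + (t - r) * _log_sig(-z)
            - 0.5 * ((z - mu) / sigma) ** 2
        )

    res = minimize_scalar(
        lambda z: -g(z), bounds=(mu - 60.0, mu + 60.0), method="bounded",
        options={"xatol": 1e-12},
    )
    gmax = g(res.x)
    val, _ = quad(
        lambda z: np.exp(g(z) - gmax), -np.inf, np.inf,
        limit=500, epsabs=1e-14, epsrel=1e-13,
    )
    log_binom = gammaln(t + 1) - gammaln(r + 1) - gammaln(t - r + 1)
    return float(log_binom + gmax + np.log(val) - np.log(sigma * np.sqrt(2 * np.pi)))


def mixture_log_pmf_quad(r: int, t: int, mu: float, sigma: float, epsilon: float) -> float:
    """Uniform-BLN mixture log pmf built on the quadrature oracle."""
    log_bln = bln_log_pmf_quad(r, t, mu, sigma)
    if epsilon == 0.0:
        return log_bln
    return float(
        np.logaddexp(np.log1p(-epsilon) + log_bln, np.log(epsilon) - np.log(t + 1.0))
    )


def medcouple_brute(values) -> float:
    """All-pairs medcouple by explicit loops, with the published tie kernel.

    For the k observations tied with the median m, pairs (i-th tied value on
    the low side, j-th on the high side; both 1-based ascending) use the sign
    kernel: -1 if i + j - 1 < k, 0 if i + j - 1 = k, +1 if i + j - 1 > k.
    """
    x = sorted(float(v) for v in values)
    n = len(x)
    if n % 2:
        m = x[n // 2]
    else:
        m = 0.5 * (x[n // 2 - 1] + x[n // 2])
    lower = [v for v in x if v <= m]
    upper = [v for v in x if v >= m]
    k = sum(1 for v in x if v == m)
    n_lower_strict = len(lower) - k  # tied values sit at the top of `lower`

    h = []
    for a, xi in enumerate(lower):
        for b, xj in enumerate(upper):
            if xi == m and xj == m:
                i = a - n_lower_strict + 1  # 1-based index within the tie block
                j = b + 1
                h.append(float(np.sign(i + j - 1 - k)))
            else:
                h.append(((xj - m) - (m - xi)) / (xj - xi))
    return float(np.median(h))


def adjusted_fences_recomputed(values) -> tuple[float, float]:
    """Skew-adjusted fences recomputed directly from the formula.

    Uses the brute-force medcouple and numpy's linear-interpolation (type 7)
    quartiles, mirroring the published fence definition term by term.
    """
    x = np.asarray(values, dtype=float)
    mc = medcouple_brute(x)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    if mc >= 0:
        return q1 - 1.5 * np.exp(-4 * mc) * iqr, q3 + 1.5 * np.exp(3 * mc) * iqr
    return q1 - 1.5 * np.exp(-3 * mc) * iqr, q3 + 1.5 * np.exp(4 * mc) * iqr


def select_most_expressed(variants_df):
    """Brute-force most-expressed-SNP selection for aggregation checks.

    Returns {(sample_id, gene_id): variant_id} choosing max total_count with
    ties broken by ascending (contig, position, variant_id).
    """
    chosen = {}
    for row in variants_df.itertuples():
        key = (row.sample_id, row.gene_id)
        cand = (-row.total_count, row.contig, row.position, row.variant_id)
        if key not in chosen or cand < chosen[key]:
            chosen[key] = cand
    return {key: cand[3] for key, cand in chosen.items()}
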