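"""Independent reference implementations used as test oracles.

These deliberately recompute each statistic by a different route than
the package (explicit 0/1 ANOVA, exhaustive enumeration, literal
sorting) so that agreement is evidence, not tautology.
"""

import math

import numpy as np

from poolscan.diversity import SiteAlleleFreq


def wc_theta_oracle(counts_a, n_a, counts_b, n_b):
    """Weir-Cockerham theta from explicit 0/1 allele arrays.

    ``counts_*`` are reference-allele counts among ``n_*`` sampled
    alleles per site. Runs the two-population ANOVA literally (between
    and within sums of squares on the indicator data, variance
    components, ratio of sums over sites).
    """
    num = 0.0
    den = 0.0
    for ka, na, kb, nb in zip(counts_a, n_a, counts_b, n_b):
        x_a = np.concatenate([np.ones(ka), np.zeros(na - ka)])
        x_b = np.concatenate([np.ones(kb), np.zeros(nb - kb)])
        n_t = na + nb
        grand = np.concatenate([x_a, x_b]).mean()
        ssb = na * (x_a.mean() - grand) ** 2 + nb * (x_b.mean() - grand) ** 2
        ssw = ((x_a - x_a.mean()) ** 2).sum() + ((x_b - x_b.mean()) ** 2).sum()
        msp = ssb / 1.0  # r - 1 = 1
        msg = ssw / (n_t - 2)
        nc = n_t - (na**2 + nb**2) / n_t
        a = (msp - msg) / nc
        num += a
        den += a + msg
    return num / den


def fisher_two_sided_oracle(table):
    """Exhaustive two-sided Fisher p on a 2x2 table: sum the
    hypergeometric pmf of every table with the observed margins whose
    probability does not exceed the observed one (tiny relative slack
    for float ties)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def kendall_w_oracle(matrix):
    """Direct-formula Kendall's W with mid-ranks and tie correction,
    ranking by explicit sorting rather than scipy."""
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    ranks = np.zeros_like(matrix)
    tie_term = 0.0
    for j in range(m):
        order = np.argsort(matrix[:, j], kind="stable")
        r = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and matrix[order[k + 1], j] == matrix[order[i], j]:
                k += 1
            mid = (i + k) / 2 + 1
            for t in range(i, k + 1):
                r[order[t]] = mid
            group = k - i + 1
            tie_term += group**3 - group
            i = k + 1
        ranks[:, j] = r
    sums = ranks.sum(axis=1)
    s = ((sums - sums.mean()) ** 2).sum()
    return 12 * s / (m**2 * (n**3 - n) - m * tie_term)


def allele_freq_site(pos, allele_counts, scaffold="sc1"):
    """Build a SiteAlleleFreq from an {allele: count} map."""
    ranked = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (maj, n_maj), (mnr, n_min) = ranked[0], ranked[1]
    return SiteAlleleFreq(scaffold, pos, maj, mnr if n_min else None, n_maj, n_min)
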