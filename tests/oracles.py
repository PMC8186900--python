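"""Independent brute-force oracles used to validate the exact tests.

These are deliberately naive: exact rational hypergeometric enumeration for
the 2x2 Fisher tests and full enumeration of the Levene-Haldane conditional
distribution for the HWE exact test.  They share no code with the package.
"""

from fractions import Fraction
from math import comb


def fisher_enum(a: int, b: int, c: int, d: int, sidedness: str) -> Fraction:
    """Fisher exact p by enumerating the hypergeometric support of the table.

    Margins fixed: N = a+b+c+d draws, K = a+c successes, n = a+b in group 1.
    One-sided = upper tail P(X >= a); two-sided = total probability of all
    tables no more likely than the observed one.
    """
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)
    denom = comb(N, n)
    probs = {x: Fraction(comb(K, x) * comb(N - K, n - x), denom) for x in range(lo, hi + 1)}
    if sidedness == "one":
        return sum(p for x, p in probs.items() if x >= a)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def hwe_enum(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Levene-Haldane exact HWE p by enumerating all feasible het counts.

    Conditional on n diploids and the minor-allele count, P(het = k) is
    proportional to 2^k / (n_hom_major! k! n_hom_minor!); the p-value sums
    the probabilities of the configurations no more likely than observed.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    minor = min(n_alt, 2 * n - n_alt)
    weights = {}
    for k in range(minor % 2, minor + 1, 2):
        n_min_hom = (minor - k) // 2
        n_maj_hom = n - k - n_min_hom
        if n_maj_hom < 0:
            continue
        weights[k] = Fraction(2**k * _multinomial(n_maj_hom, k, n_min_hom))
    total = sum(weights.values())
    probs = {k: w / total for k, w in weights.items()}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def _multinomial(*parts: int) -> int:
    from math import factorial

    n = sum(parts)
    out = factorial(n)
    for p in parts:
        out //= factorial(p)
    return out


def bh_enum(pvals: list[float]) -> list[float]:
    """Literal min-over-larger-p definition of the BH step-up q-value:
    q_i = min over sorted positions r with p_(r) >= p_i of p_(r) * m / r."""
    m = len(pvals)
    p_sorted = sorted(pvals)
    qs = []
    for p in pvals:
        cands = [p_sorted[r - 1] * m / r for r in range(1, m + 1) if p_sorted[r - 1] >= p]
        qs.append(min(1.0, min(cands)))
    return qs
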