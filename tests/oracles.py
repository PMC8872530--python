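"""Independent brute-force oracles used by the tests.

These enumerate the full discrete probability space of the generative
model at a single site — founder alleles, meiotic transmissions,
pseudo-haploid picks and error flips — and therefore do not share any
code with the vectorised samplers or the closed-form expectation they
are used to check.
"""

from itertools import product


def _states(prob):
    """Binary variable: (value, probability) pairs."""
    return ((1, prob), (0, 1.0 - prob))


def exact_mismatch_probability(p: float, relationship: str, error_rate: float) -> float:
    """Exact P(pseudo-haploid mismatch) at one site by full enumeration."""
    e = error_rate
    total = 0.0
    if relationship == "same_individual":
        for (g1, w1), (g2, w2), (ca, wa), (cb, wb), (fa, wfa), (fb, wfb) in product(
            _states(p), _states(p), _states(0.5), _states(0.5), _states(e), _states(e)
        ):
            a = (g1 if ca else g2) ^ fa
            b = (g1 if cb else g2) ^ fb
            if a != b:
                total += w1 * w2 * wa * wb * wfa * wfb
    elif relationship == "unrelated":
        for (a1, w1), (a2, w2), (b1, w3), (b2, w4), (ca, wa), (cb, wb), (fa, wfa), (
            fb,
            wfb,
        ) in product(
            _states(p),
            _states(p),
            _states(p),
            _states(p),
            _states(0.5),
            _states(0.5),
            _states(e),
            _states(e),
        ):
            a = (a1 if ca else a2) ^ fa
            b = (b1 if cb else b2) ^ fb
            if a != b:
                total += w1 * w2 * w3 * w4 * wa * wb * wfa * wfb
    elif relationship == "parent_child":
        # parent (p1, p2); child = (transmitted parental allele, population draw o)
        for (p1, w1), (p2, w2), (o, w3), (t, wt), (ca, wa), (cb, wb), (fa, wfa), (
            fb,
            wfb,
        ) in product(
            _states(p),
            _states(p),
            _states(p),
            _states(0.5),
            _states(0.5),
            _states(0.5),
            _states(e),
            _states(e),
        ):
            child = ((p1 if t else p2), o)
            a = (p1 if ca else p2) ^ fa
            b = (child[0] if cb else child[1]) ^ fb
            if a != b:
                total += w1 * w2 * w3 * wt * wa * wb * wfa * wfb
    elif relationship == "full_siblings":
        # parents (m1, m2) and (f1, f2); each sibling inherits one maternal
        # and one paternal allele; pseudo-haploid pick between the two.
        for (m1, w1), (m2, w2), (f1, w3), (f2, w4), (c1m, wc1), (c1f, wc2), (
            c2m,
            wc3,
        ), (c2f, wc4), (ca, wa), (cb, wb), (fa, wfa), (fb, wfb) in product(
            _states(p),
            _states(p),
            _states(p),
            _states(p),
            _states(0.5),
            _states(0.5),
            _states(0.5),
            _states(0.5),
            _states(0.5),
            _states(0.5),
            _states(e),
            _states(e),
        ):
            sib1 = ((m1 if c1m else m2), (f1 if c1f else f2))
            sib2 = ((m1 if c2m else m2), (f1 if c2f else f2))
            a = (sib1[0] if ca else sib1[1]) ^ fa
            b = (sib2[0] if cb else sib2[1]) ^ fb
            if a != b:
                total += (
                    w1 * w2 * w3 * w4 * wc1 * wc2 * wc3 * wc4 * wa * wb * wfa * wfb
                )
    else:
        raise ValueError(relationship)
    return total


def exact_ibs_share_probability(p: float, relationship: str) -> float:
    """Exact P(two diploid genotypes share >= 1 allele identical by state)."""
    if relationship == "unrelated":
        # no sharing iff one genotype is hom-ref and the other hom-alt
        q = 1.0 - p
        return 1.0 - 2.0 * (p**2) * (q**2)
    raise ValueError(relationship)
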