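"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they validate: Fisher's exact test
is re-derived by exhaustive hypergeometric enumeration in exact rational
arithmetic, the Welch test from its closed-form statistic and
degrees-of-freedom formula, and the binding calls by plain-Python
re-enumeration.
"""

from fractions import Fraction
from math import comb, sqrt

from scipy import stats


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration, exact rationals.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs)
    return float(total)


def welch_p(xs, ys) -> float:
    """Two-sided Welch t-test p from the closed-form statistic and df."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    sx, sy = vx / nx, vy / ny
    t = (mx - my) / sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx ** 2 / (nx - 1) + sy ** 2 / (ny - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def enumerate_binding(probe_rows, condition: str, threshold: float):
    """Brute-force bound probes/genes from a list of probe dicts.

    Returns (bound_probe_ids, per-gene dict of
    {n_bound, signal_sum, types}) with replicate-mean signals summed over
    bound probes only.
    """
    cond = condition.lower()
    bound_ids = set()
    genes = {}
    for row in probe_rows:
        gene = row["gene_id"]
        genes.setdefault(gene, {"n_bound": 0, "signal_sum": 0.0, "types": set()})
    for row in probe_rows:
        if row[f"pvalue_{cond}"] <= threshold:
            bound_ids.add(row["probe_id"])
            sig_cols = sorted(k for k in row if k.startswith(f"signal_{cond}_"))
            mean_sig = sum(row[k] for k in sig_cols) / len(sig_cols)
            g = genes[row["gene_id"]]
            g["n_bound"] += 1
            g["signal_sum"] += mean_sig
            g["types"].add(row["probe_type"])
    return bound_ids, genes
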