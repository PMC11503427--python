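import numpy as np
import pandas as pd
import pytest

from thyrosens.data_model import Cohort


def build_cohort(
    tsh, ft4, ui, period=None, anti_tpo=None, anti_tpo_positive=None, ids=None
) -> Cohort:
    """Assemble a small cohort from parallel value lists."""
    n = len(tsh)
    df = pd.DataFrame(
        {
            "sample_id": ids if ids is not None else [f"s{i}" for i in range(n)],
            "period": period if period is not None else ["T1"] * n,
            "tsh": tsh,
            "ft4": ft4,
            "anti_tpo": anti_tpo if anti_tpo is not None else [np.nan] * n,
            "anti_tpo_positive": pd.array(
                anti_tpo_positive if anti_tpo_positive is not None else [False] * n,
                dtype="boolean",
            ),
            "ui": ui,
        }
    )
    return Cohort(df)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Five samples with hand-checkable fT4/TSH ranks (paired in increasing order)."""
    return build_cohort(
        tsh=[0.5, 1.0, 1.5, 2.0, 2.5],
        ft4=[1.0, 1.1, 1.2, 1.3, 1.4],
        ui=[50.0, 120.0, 180.0, 300.0, 90.0],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (explicit sums/counting only; no scipy/
# statsmodels/np.percentile so they stay independent of the implementation).
# ---------------------------------------------------------------------------


def brute_quartiles_linear(values):
    """Rank interpolation between order statistics at h = q(n-1)."""
    s = sorted(float(v) for v in values)
    n = len(s)

    def at(q):
        h = q * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return at(0.25), at(0.75)


def brute_fence(values, k=1.5):
    q1, q3 = brute_quartiles_linear(values)
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    return lower, upper, [v for v in values if v < lower or v > upper]


def brute_ecdf(values, convention="ecdf_leq"):
    out = []
    n = len(values)
    for x in values:
        below = sum(1 for v in values if v < x)
        equal = sum(1 for v in values if v == x)
        if convention == "ecdf_leq":
            out.append((below + equal) / n)
        else:  # hazen: (midrank - 0.5)/n
            midrank = below + (equal + 1) / 2
            out.append((midrank - 0.5) / n)
    return out


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def brute_f_oneway(samples):
    """Explicit between/within sums of squares."""
    all_vals = [v for s in samples for v in s]
    n = len(all_vals)
    k = len(samples)
    grand = sum(all_vals) / n
    ssb = sum(len(s) * (sum(s) / len(s) - grand) ** 2 for s in samples)
    ssw = sum(sum((v - sum(s) / len(s)) ** 2 for v in s) for s in samples)
    return (ssb / (k - 1)) / (ssw / (n - k))


def brute_chi2(table):
    table = [[float(c) for c in row] for row in table]
    total = sum(sum(row) for row in table)
    rows = [sum(row) for row in table]
    cols = [sum(table[i][j] for i in range(len(table))) for j in range(len(table[0]))]
    stat = 0.0
    for i in range(len(table)):
        for j in range(len(table[0])):
            e = rows[i] * cols[j] / total
            stat += (table[i][j] - e) ** 2 / e
    return stat
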