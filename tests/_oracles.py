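"""Brute-force oracles shared across test modules."""

import numpy as np
import pandas as pd
from scipy import stats as sstats


def duncan_oracle(values, groups, alpha):
    """All-pairs Duncan range test by direct definition.

    Two groups differ when the gap between their means exceeds the
    critical range for the span the pair occupies among the sorted means,
    with the containment rule that no pair inside a nonsignificant range
    is declared different.  Returns the boolean 'differ' matrix.
    """
    df = pd.DataFrame({"y": values, "g": groups})
    means = df.groupby("g")["y"].mean().sort_values(ascending=False)
    k = len(means)
    n = df.groupby("g").size()
    df_e = len(df) - k
    mse = sum(
        ((df[df.g == name].y - means[name]) ** 2).sum() for name in means.index
    ) / df_e
    n_h = k / (1.0 / n).sum()
    differ = pd.DataFrame(False, index=means.index, columns=means.index)
    for i in range(k):
        for j in range(i + 1, k):
            span = j - i + 1
            pr = 1 - (1 - alpha) ** (span - 1)
            q = sstats.studentized_range.ppf(1 - pr, span, df_e)
            crit = q * np.sqrt(mse / n_h)
            if means.iloc[i] - means.iloc[j] > crit:
                differ.iloc[i, j] = differ.iloc[j, i] = True
    for i in range(k):
        for j in range(k - 1, i, -1):
            if not differ.iloc[i, j]:
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        differ.iloc[a, b] = differ.iloc[b, a] = False
    return differ


def letters_match_differ(letters: dict, differ: pd.DataFrame) -> bool:
    """True when letter sharing encodes exactly the complement of 'differ'."""
    for a in differ.index:
        for b in differ.columns:
            if a == b:
                continue
            shares = bool(set(letters[a]) & set(letters[b]))
            if shares == bool(differ.loc[a, b]):
                return False
    return True
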