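"""Non-phylogenetic window comparisons: variances, ranges, Levene's test
(Brown-Forsythe median centering by default) and the exact two-tailed sign
test.  Test units are species means (one value per species), never raw
specimen values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LeveneResult",
    "SignTestResult",
    "levene_test",
    "sign_test",
    "variance_and_range",
    "window_comparison_table",
]


@dataclass(frozen=True)
class LeveneResult:
    F: float
    df1: int
    df2: int
    p: float
    center: str


@dataclass(frozen=True)
class SignTestResult:
    n: int  # non-zero deltas
    k: int  # negative deltas
    p: float  # two-tailed exact binomial probability


def levene_test(groups: list[np.ndarray | list], center: str = "median") -> LeveneResult:
    """Levene's test for unequal variances across two or more groups.

    ``center='median'`` is the Brown-Forsythe variant (robust default);
    ``center='mean'`` is classic Levene.  F is compared against
    F(k-1, N-k).
    """
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    F, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    N = sum(len(a) for a in arrays)
    # two identical groups give 0/0 in the F ratio; the statistic is 0 by
    # convention and the test has no evidence against equal variances
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    return LeveneResult(F=float(F), df1=k - 1, df2=N - k, p=float(p), center=center)


def sign_test(deltas: np.ndarray | list) -> SignTestResult:
    """Exact two-tailed sign test on the signs of the deltas.

    Zero deltas are excluded; ``k`` counts negative deltas; the p-value is
    the binom.test-style two-tailed probability at p0 = 0.5 (sum of outcome
    probabilities no larger than the observed one, capped at 1).
    """
    d = np.asarray(deltas, dtype=float)
    nz = d[d != 0.0]
    if len(nz) == 0:
        raise ValueError("all deltas are zero; sign test undefined")
    n = int(len(nz))
    k = int(np.sum(nz < 0))
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return SignTestResult(n=n, k=k, p=float(min(p, 1.0)))


def variance_and_range(species_niches: pd.DataFrame, variable: str,
                       kind: str) -> dict:
    """Sample variance (n-1 divisor), min and max of the species means for
    one climate variable and window kind."""
    sub = species_niches[species_niches["kind"] == kind]
    vals = sub[f"{variable}_mean"].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError(f"need >= 2 species for {variable}/{kind}, got {len(vals)}")
    return {"variance": float(np.var(vals, ddof=1)),
            "min": float(vals.min()), "max": float(vals.max()),
            "n_species": int(len(vals))}


def window_comparison_table(species_niches: pd.DataFrame,
                            kind_a: str = "specimen_specific",
                            kind_b: str = "clade_seasonal") -> pd.DataFrame:
    """Variance/range comparison plus Levene's test for each climate
    variable between two window kinds."""
    rows = []
    for var in ("tmean_c", "ppt_mm", "cwd_mm"):
        a = variance_and_range(species_niches, var, kind_a)
        b = variance_and_range(species_niches, var, kind_b)
        ga = species_niches.loc[species_niches["kind"] == kind_a,
                                f"{var}_mean"].to_numpy(dtype=float)
        gb = species_niches.loc[species_niches["kind"] == kind_b,
                                f"{var}_mean"].to_numpy(dtype=float)
        lev = levene_test([ga, gb])
        rows.append({
            "variable": var, "kind_A": kind_a, "kind_B": kind_b,
            "variance_A": a["variance"], "variance_B": b["variance"],
            "range_A": f"{a['min']:.6g}..{a['max']:.6g}",
            "range_B": f"{b['min']:.6g}..{b['max']:.6g}",
            "levene_F": lev.F, "levene_p": lev.p,
        })
    return pd.DataFrame(rows)
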