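"""Statistical procedures and histology count-fraction arithmetic.

The experimental design contrasts per-animal scalars (ON-OFF or CNO-SAL
transforms) between groups with classical two-tailed Student t-tests (pooled
variance, df = n1 + n2 - 2, which matches the reported degrees of freedom),
tests normality with a Monte-Carlo Lilliefors test, correlates with Pearson's
method, and adjusts families of p-values with Benjamini-Hochberg FDR.
Histology overlap fractions (e.g. GFP+/NeuN+) are computed either pooled over
animals or as per-animal means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "t_test",
    "pearson_r",
    "lilliefors_test",
    "lilliefors_statistic",
    "lilliefors_null_distribution",
    "fdr_adjust",
    "overlap_fractions",
    "cohort_screen_fraction",
]


def t_test(a, b, paired: bool = False) -> tuple[float, int, float]:
    """Two-tailed Student t-test; returns (t, df, p).

    Unpaired tests use pooled variance (df = n1 + n2 - 2); paired tests
    require equal-length matched samples (df = n - 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires matched sample sizes")
        d = a - b
        if np.ptp(d) == 0 and len(np.unique(d)) == 1 and d[0] != 0:
            raise ValueError("zero variance of paired differences; t undefined")
        res = sps.ttest_rel(a, b)
        df = len(a) - 1
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0.0, len(a) + len(b) - 2, 1.0
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    t = float(res.statistic)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance; t undefined")
    return t, df, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed p (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs matched samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance between the sample and a normal with estimated mean/SD."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample")
    cdf = sps.norm.cdf((x - x.mean()) / sd)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors_null_distribution(
    n: int, n_mc: int = 10000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic at sample size n."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = np.sort(rng.standard_normal((n_mc, n)), axis=1)
    mu = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf((samples - mu) / sd)
    grid = np.arange(1, n + 1) / n
    up = (grid - cdf).max(axis=1)
    down = (cdf - (grid - 1.0 / n)).max(axis=1)
    return np.maximum(up, down)


def lilliefors_test(x, n_mc: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test with a seeded Monte-Carlo p-value.

    The null distribution of the KS statistic (normal with estimated
    parameters) is simulated at the exact sample size; p uses the standard
    (1 + exceedances) / (n_mc + 1) estimator.  Requires n >= 4.
    """
    x = np.asarray(x, float)
    if len(x) < 4:
        raise ValueError("lilliefors_test requires n >= 4")
    d = lilliefors_statistic(x)
    null = lilliefors_null_distribution(len(x), n_mc, seed)
    p = (1.0 + np.sum(null >= d)) / (n_mc + 1.0)
    return d, float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def overlap_fractions(table: pd.DataFrame, pooling: str = "pooled") -> pd.DataFrame:
    """Marker-overlap fractions per region from per-animal count tables.

    ``table`` columns: ``animal``, ``region`` (dlPAG/lPAG/vlPAG), ``marker_a``
    (denominator counts), ``overlap``.  Rows for lPAG and vlPAG are combined
    into an additional ``l/vlPAG`` region (counts summed per animal before any
    fraction is formed).  ``pooling``:

    * ``"pooled"`` - sum(overlap) / sum(marker_a) over animals;
    * ``"per_animal_mean"`` - mean over animals of per-animal fractions;
      animals with a zero denominator are excluded with a warning.
    """
    if pooling not in ("pooled", "per_animal_mean"):
        raise ValueError("pooling must be 'pooled' or 'per_animal_mean'")
    t = table.copy()
    if np.any(t["overlap"] > t["marker_a"]):
        raise ValueError("overlap counts exceed denominator counts")
    if np.any((t[["marker_a", "overlap"]] < 0).to_numpy()):
        raise ValueError("negative counts")
    combined = (
        t[t["region"].isin(["lPAG", "vlPAG"])]
        .groupby("animal", as_index=False)[["marker_a", "overlap"]]
        .sum()
        .assign(region="l/vlPAG")
    )
    t = pd.concat([t, combined], ignore_index=True)
    rows = []
    for region, grp in t.groupby("region", sort=False):
        per_animal = grp.groupby("animal")[["marker_a", "overlap"]].sum()
        if pooling == "pooled":
            denom = per_animal["marker_a"].sum()
            if denom == 0:
                raise ValueError(f"zero total denominator in region {region!r}")
            frac = per_animal["overlap"].sum() / denom
        else:
            ok = per_animal["marker_a"] > 0
            if not ok.all():
                import warnings

                warnings.warn(f"excluding {int((~ok).sum())} zero-denominator animals in {region!r}")
            frac = (per_animal.loc[ok, "overlap"] / per_animal.loc[ok, "marker_a"]).mean()
        rows.append({"region": region, "fraction": float(frac), "n_animals": per_animal.shape[0]})
    return pd.DataFrame(rows).set_index("region")


def cohort_screen_fraction(pass_count: int, total: int) -> float:
    """Percentage of a cohort passing a screen, to one decimal (63/69 -> 91.3)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= pass_count <= total:
        raise ValueError("pass_count must lie in [0, total]")
    return round(100.0 * pass_count / total, 1)
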