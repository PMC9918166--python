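"""Cohort-level nonparametric statistics and report tables.

Continuous descriptors are summarised as median and interquartile range and
compared between girls and boys with the Mann–Whitney test.  Phenotype
prevalences are tested against a 50% null with the exact binomial test and
compared between sexes with Fisher's exact test.  Age associations use
Spearman rank correlation with SE(rho) = sqrt((1 − rho²)/(n − 2)) and a
two-sided p from t = rho·sqrt((n − 2)/(1 − rho²)) on n − 2 degrees of
freedom.  Significance is two-sided at alpha = 0.05; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "summarize",
    "mann_whitney",
    "prevalence_binomial",
    "fisher_exact",
    "spearman_rho_se",
    "spearman_age",
    "summary_table",
    "prevalence_table",
    "correlation_table",
    "DESCRIPTOR_COLUMNS",
    "FLAG_COLUMNS",
]

#: descriptor columns reported in the summary and correlation tables
DESCRIPTOR_COLUMNS = ["sd1d", "sd1a", "sd2d", "sd2a", "sdnnd", "sdnna", "c1d", "c2d", "ctd", "nd"]
#: phenotype columns reported in the prevalence table
FLAG_COLUMNS = ["hra1", "hra2", "hrat", "hran", "hracomp"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]
    extra: dict | None = None


def _round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so 93.75 → 93.8), unlike banker's rounding."""
    factor = 10.0**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * math.copysign(1.0, value)


def summarize(values) -> dict[str, float]:
    """Median and IQR bounds (linear-interpolation quantiles, 'type 7')."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {"median": float("nan"), "q25": float("nan"), "q75": float("nan"), "n": 0}
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return {"median": float(med), "q25": float(q25), "q75": float(q75), "n": int(arr.size)}


def mann_whitney(a, b, *, exact: bool = False) -> TestResult:
    """Two-sided Mann–Whitney U.

    Default is the normal approximation with tie and continuity corrections;
    ``exact=True`` enumerates the null distribution (small samples, no ties).
    Two samples with all values identical give p = 1 by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    if np.all(np.concatenate([a, b]) == a.flat[0]):
        return TestResult(statistic=a.size * b.size / 2.0, p=1.0,
                          method="mann-whitney", n=(a.size, b.size))
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                      method="mann-whitney", n=(a.size, b.size))


def prevalence_binomial(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials against p0.

    Two-sided p sums the probabilities of all outcomes no more likely than
    the observed k.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n and n >= 1")
    res = sps.binomtest(int(k), int(n), p0, alternative="two-sided")
    return TestResult(statistic=float(k), p=float(res.pvalue), method="binomial", n=(int(n),))


def fisher_exact(table) -> TestResult:
    """Fisher's exact test on a 2×2 table.

    Reports the probability-mass two-sided p (the pipeline default) and the
    smaller directional one-sided p under ``extra``.  A zero margin gives
    p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(statistic=float("nan"), p=1.0, method="fisher",
                          n=(int(t.sum()),), extra={"one_sided": 1.0, "two_sided": 1.0})
    odds, p_two = sps.fisher_exact(t, alternative="two-sided")
    p_less = sps.fisher_exact(t, alternative="less")[1]
    p_greater = sps.fisher_exact(t, alternative="greater")[1]
    one_sided = float(min(p_less, p_greater))
    return TestResult(
        statistic=float(odds), p=float(p_two), method="fisher", n=(int(t.sum()),),
        extra={"one_sided": one_sided, "two_sided": float(p_two)},
    )


def spearman_rho_se(rho: float, n: int) -> float:
    """Standard error of a Spearman correlation: sqrt((1 − rho²)/(n − 2))."""
    if n < 3:
        raise ValueError("n must be at least 3")
    return math.sqrt(max(1.0 - rho * rho, 0.0) / (n - 2))


def spearman_age(values, ages) -> TestResult:
    """Tie-aware Spearman correlation of a descriptor with age.

    rho is computed on average ranks; p is two-sided from the t
    approximation with n − 2 degrees of freedom.
    """
    v = np.asarray(values, float)
    a = np.asarray(ages, float)
    if v.shape != a.shape or v.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if np.all(v == v[0]) or np.all(a == a[0]):
        raise ValueError("Spearman correlation undefined for zero-variance input")
    rv = sps.rankdata(v)
    ra = sps.rankdata(a)
    rho = float(np.clip(np.corrcoef(rv, ra)[0, 1], -1.0, 1.0))
    n = v.size
    se = spearman_rho_se(rho, n)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(statistic=rho, p=p, method="spearman", n=(n,), extra={"se": se})


# ---------------------------------------------------------------------------
# report tables over a per-subject record set
# ---------------------------------------------------------------------------

def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) < 1:
        raise ValueError("empty record set")
    return records


def summary_table(records: pd.DataFrame, by_sex: bool = True) -> pd.DataFrame:
    """Median/IQR per descriptor for all children and optionally per sex,
    with the girls-vs-boys Mann–Whitney p in the last column."""
    records = _check_records(records)
    rows = []
    girls = records[records["sex"] == "girl"] if by_sex else None
    boys = records[records["sex"] == "boy"] if by_sex else None
    for col in DESCRIPTOR_COLUMNS:
        row: dict[str, float | str] = {"parameter": col}
        row.update({f"all_{k}": v for k, v in summarize(records[col]).items() if k != "n"})
        if by_sex:
            for name, grp in (("girls", girls), ("boys", boys)):
                if len(grp) == 0:
                    continue  # absent group: column omitted
                row.update({f"{name}_{k}": v for k, v in summarize(grp[col]).items() if k != "n"})
            if len(girls) and len(boys):
                ga = girls[col].dropna()
                ba = boys[col].dropna()
                if len(ga) and len(ba):
                    row["p_girls_vs_boys"] = mann_whitney(ga, ba).p
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def prevalence_table(records: pd.DataFrame) -> pd.DataFrame:
    """Counts, percentages, binomial p (vs 50%), and girls-vs-boys Fisher p
    per phenotype.  Subjects whose underlying ratios are undefined are
    excluded from the denominators."""
    records = _check_records(records)
    usable = records[records["defined"]] if "defined" in records.columns else records
    rows = []
    for flag in FLAG_COLUMNS:
        sub = usable.dropna(subset=[flag])
        n = len(sub)
        k = int(sub[flag].sum())
        row: dict[str, float | str] = {
            "phenotype": flag,
            "count": k,
            "n": n,
            "percent": _round_half_away(100.0 * k / n, 1) if n else float("nan"),
            "p_binomial": prevalence_binomial(k, n).p if n else float("nan"),
        }
        g = sub[sub["sex"] == "girl"]
        b = sub[sub["sex"] == "boy"]
        if len(g) and len(b):
            kg, kb = int(g[flag].sum()), int(b[flag].sum())
            row.update({
                "girls_count": kg, "girls_n": len(g),
                "girls_percent": _round_half_away(100.0 * kg / len(g), 1),
                "boys_count": kb, "boys_n": len(b),
                "boys_percent": _round_half_away(100.0 * kb / len(b), 1),
                "p_fisher": fisher_exact([[kg, len(g) - kg], [kb, len(b) - kb]]).p,
            })
        rows.append(row)
    return pd.DataFrame(rows).set_index("phenotype")


def correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho, its SE, and two-sided p of each descriptor against age."""
    records = _check_records(records)
    rows = []
    for col in DESCRIPTOR_COLUMNS:
        sub = records.dropna(subset=[col, "age"])
        try:
            res = spearman_age(sub[col].to_numpy(), sub["age"].to_numpy())
            rows.append({"parameter": col, "rho": res.statistic,
                         "se": res.extra["se"], "p": res.p, "n": res.n[0]})
        except ValueError:
            rows.append({"parameter": col, "rho": float("nan"),
                         "se": float("nan"), "p": float("nan"), "n": len(sub)})
    return pd.DataFrame(rows).set_index("parameter")
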