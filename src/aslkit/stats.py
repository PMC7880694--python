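"""Nonparametric cohort statistics with SPSS conventions.

Mann–Whitney U for genotype contrasts, Friedman for the age effect,
Wilcoxon signed-rank for paired contrasts (age post hocs, anesthesia,
CO₂ effect on ATT), Bonferroni correction over consecutive-age pairs,
and median (Tukey-hinge IQR) summaries.

SPSS conventions are used throughout because the reported asymptotic Z
statistics are only reproducible under them: zero differences are
dropped before ranking, the rank variance is tie-corrected, and no
continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman",
    "bonferroni_posthoc",
    "median_iqr",
    "cohort_report",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, optional Z/dof, two-sided p, group sizes."""

    name: str
    statistic: float
    p: float
    z: float | None = None
    dof: int | None = None
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.z is not None and not np.isfinite(self.z):
            raise ValueError("Z must be finite")


def _tie_term(values: np.ndarray) -> float:
    """Σ(t³ − t) over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``mode='exact'`` enumerates the null distribution (valid without
    ties), ``'asymptotic'`` uses the tie-corrected, continuity-corrected
    normal approximation for p, ``'auto'`` picks exact for min(n) ≤ 10
    with no ties.  The reported U is the statistic for ``x`` (number of
    (x, y) pairs with x > y, ties counting ½); the accompanying Z is the
    plain tie-corrected standardization of U without continuity
    correction (the SPSS display convention).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and has_ties:
        mode = "asymptotic"
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    nx, ny = x.size, y.size
    mean = nx * ny / 2.0
    n_tot = nx + ny
    var = nx * ny / 12.0 * ((n_tot + 1) - _tie_term(pooled) / (n_tot * (n_tot - 1)))
    z = (u - mean) / np.sqrt(var) if var > 0 else 0.0
    return TestResult(
        name="mann-whitney-u", statistic=u, p=float(res.pvalue), z=float(z), n=(nx, ny)
    )


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Paired Wilcoxon signed-rank test, SPSS asymptotic Z.

    Differences are post − pre; zero differences are dropped; W+ is the
    sum of ranks of positive differences;

        Z = (W+ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48)

    with no continuity correction; p is the two-sided normal tail.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    d = post - pre
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        raise ValueError("fewer than 2 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    if var <= 0:
        raise ValueError("degenerate variance (all differences tied at one value)")
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(
        name="wilcoxon-signed-rank", statistic=w_plus, p=min(p, 1.0), z=float(z), n=(n,)
    )


def friedman(values: np.ndarray) -> TestResult:
    """Friedman test on an n_subjects × k_conditions matrix, tie-corrected.

    χ² = [12/(n·k·(k+1)) · ΣR_j² − 3·n·(k+1)] / C with the tie
    correction C = 1 − Σ(t³−t)/(n·(k³−k)); dof = k − 1.
    """
    m = np.asarray(values, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n, k >= 2")
    if np.isnan(m).any():
        raise ValueError("missing values not allowed (complete cases only)")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(col_sums @ col_sums) - 3.0 * n * (k + 1)
    ties = sum(_tie_term(row) for row in m)
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:
        # every row fully tied: no rank information, χ² is identically 0
        if abs(chi2) > 1e-12:
            raise ValueError("degenerate tie structure in Friedman test")
        chi2 = 0.0
    else:
        chi2 /= correction
    dof = k - 1
    p = float(sps.chi2.sf(chi2, dof))
    return TestResult(name="friedman", statistic=float(chi2), p=p, dof=dof, n=(n, k))


def bonferroni_posthoc(
    pvalues: dict[str, float], alpha: float = 0.05, m: int | None = None
) -> pd.DataFrame:
    """Bonferroni decisions: significant iff p < alpha/m.

    ``m`` defaults to the number of comparisons supplied (e.g. the three
    consecutive-age pairs of a four-age design, giving the 0.0167
    cut-off).
    """
    if m is None:
        m = len(pvalues)
    if m < 1:
        raise ValueError("m must be >= 1")
    cutoff = alpha / m
    return pd.DataFrame(
        [
            {"comparison": name, "p": p, "cutoff": cutoff, "significant": p < cutoff}
            for name, p in pvalues.items()
        ]
    )


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with Tukey hinges (the SPSS display convention).

    Hinges are medians of the lower/upper halves, each half including
    the overall median when n is odd.
    """
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("empty sample")
    n = v.size
    med = float(np.median(v))
    half = (n + 1) // 2
    lower = v[:half]
    upper = v[n - half :]
    return med, float(np.median(lower)), float(np.median(upper))


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------


def _pivot(df: pd.DataFrame, endpoint: str, anesthesia: str, genotype: str) -> pd.DataFrame:
    sub = df[
        (df["endpoint"] == endpoint)
        & (df["anesthesia"] == anesthesia)
        & (df["genotype"] == genotype)
    ]
    return sub.pivot(index="mouse_id", columns="age_months", values="value")


def cohort_report(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the study's statistical battery on a cohort endpoint table.

    Per endpoint and age: Mann–Whitney genotype contrasts.  Per genotype
    (complete cases across the isoflurane ages): Friedman age effect on
    CBF and CVR, with Wilcoxon post hocs over consecutive ages under
    Bonferroni (m = number of consecutive pairs).  Paired Wilcoxon for
    the anesthesia effect (last isoflurane vs U&A session) and the CO₂
    effect on ATT.  Returns a tidy table of test results.
    """
    rows: list[dict] = []
    genotypes = sorted(df["genotype"].unique())

    # genotype contrasts per endpoint/age/anesthesia
    for (endpoint, anesthesia, age), sub in df.groupby(
        ["endpoint", "anesthesia", "age_months"]
    ):
        groups = [
            sub.loc[sub["genotype"] == g, "value"].to_numpy() for g in genotypes
        ]
        if len(groups) == 2 and all(g.size for g in groups):
            r = mann_whitney_u(groups[0], groups[1])
            rows.append(
                {
                    "test": "mann-whitney genotype",
                    "endpoint": endpoint,
                    "anesthesia": anesthesia,
                    "age_months": age,
                    "statistic": r.statistic,
                    "z": r.z,
                    "dof": None,
                    "p": r.p,
                    "n": str(r.n),
                }
            )

    iso_ages = sorted(
        df.loc[df["anesthesia"] == "isoflurane", "age_months"].unique()
    )
    consecutive = list(zip(iso_ages[:-1], iso_ages[1:]))
    for endpoint in ("cbf", "cvr"):
        for geno in genotypes:
            wide = _pivot(df, endpoint, "isoflurane", geno)
            if wide.shape[1] < 2:
                continue
            complete = wide.dropna()
            if complete.shape[0] >= 2:
                r = friedman(complete.to_numpy())
                rows.append(
                    {
                        "test": "friedman age",
                        "endpoint": endpoint,
                        "anesthesia": "isoflurane",
                        "age_months": None,
                        "statistic": r.statistic,
                        "z": None,
                        "dof": r.dof,
                        "p": r.p,
                        "n": str(r.n) + f" {geno}",
                    }
                )
            for a0, a1 in consecutive:
                pair = wide[[a0, a1]].dropna()
                if pair.shape[0] < 2:
                    continue
                try:
                    r = wilcoxon_signed_rank(pair[a0], pair[a1])
                except ValueError:
                    continue
                rows.append(
                    {
                        "test": "wilcoxon age posthoc",
                        "endpoint": endpoint,
                        "anesthesia": "isoflurane",
                        "age_months": f"{a0}-{a1}",
                        "statistic": r.statistic,
                        "z": r.z,
                        "dof": None,
                        "p": r.p,
                        "n": str(r.n) + f" {geno} cutoff={alpha / max(len(consecutive), 1):.4f}",
                    }
                )

    # anesthesia effect: last isoflurane age vs U&A session, paired per mouse
    ua = df[df["anesthesia"] != "isoflurane"]
    if not ua.empty and iso_ages:
        ua_name = ua["anesthesia"].iloc[0]
        last_iso = iso_ages[-1]
        for endpoint in ("cbf", "cvr"):
            for geno in genotypes:
                pre = _pivot(df, endpoint, "isoflurane", geno).get(last_iso)
                post_wide = _pivot(df, endpoint, ua_name, geno)
                if pre is None or post_wide.empty:
                    continue
                post = post_wide.iloc[:, 0]
                paired = pd.concat([pre, post], axis=1, keys=["pre", "post"]).dropna()
                if paired.shape[0] < 2:
                    continue
                r = wilcoxon_signed_rank(paired["pre"], paired["post"])
                rows.append(
                    {
                        "test": "wilcoxon anesthesia",
                        "endpoint": endpoint,
                        "anesthesia": f"isoflurane->{ua_name}",
                        "age_months": last_iso,
                        "statistic": r.statistic,
                        "z": r.z,
                        "dof": None,
                        "p": r.p,
                        "n": str(r.n) + f" {geno}",
                    }
                )

    # CO2 effect on ATT (baseline vs hypercapnic te-pCASL), paired per mouse
    for geno in genotypes:
        base = _pivot(df, "att", "isoflurane", geno)
        hyper = _pivot(df, "att_co2", "isoflurane", geno)
        if base.empty or hyper.empty:
            continue
        age = base.columns[-1]
        paired = pd.concat(
            [base[age], hyper[age]], axis=1, keys=["pre", "post"]
        ).dropna()
        if paired.shape[0] < 2:
            continue
        r = wilcoxon_signed_rank(paired["pre"], paired["post"])
        rows.append(
            {
                "test": "wilcoxon att co2",
                "endpoint": "att",
                "anesthesia": "isoflurane",
                "age_months": age,
                "statistic": r.statistic,
                "z": r.z,
                "dof": None,
                "p": r.p,
                "n": str(r.n) + f" {geno}",
            }
        )
    return pd.DataFrame(rows)
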