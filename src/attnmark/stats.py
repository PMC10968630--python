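"""Inferential layer: paired t tests, Pearson correlations, power analysis,
and the summary report tables.

Conventions follow the standard small-sample EEG/psychology toolkit:

* paired t:  t = mean(d) / (sd(d)/sqrt(n)) with the n−1 sd, df = n−1,
  two-tailed p from the central t distribution, Cohen's d = mean(d)/sd(d),
  which equals t/sqrt(n) identically.
* Pearson r:  two-tailed p via the exact transform
  t = r sqrt(n−2) / sqrt(1−r²) with df = n−2.
* power for a two-sided test of ρ = 0: noncentral-t approximation with
  noncentrality ρ sqrt(n) / sqrt(1−ρ²) against the central-t critical value
  at df = n−2; the minimal sample size is found by an upward scan from n = 4.

No multiple-comparison correction is applied by default; an optional
Bonferroni / Benjamini–Hochberg adjustment is available on the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "StatResult",
    "PowerSpec",
    "paired_t",
    "pearson",
    "p_from_r",
    "correlation_power",
    "correlation_sample_size",
    "build_report",
    "REPORT_MEASURES",
]

#: measure columns of the correlation report tables, in fixed order
REPORT_MEASURES = ("acs_total", "rt_interference", "n2d", "p3d")
_MEASURE_TITLES = {
    "acs_total": "ACS",
    "rt_interference": "RT_interference",
    "n2d": "N2d",
    "p3d": "P3d",
}


@dataclass(frozen=True)
class StatResult:
    """One test: statistic, df, two-tailed p, effect size (d or r), n."""

    label: str
    statistic: float
    df: int
    p_two_tailed: float
    effect_size: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a correlation power analysis."""

    rho: float
    alpha_level: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if not 0 < abs(self.rho) < 1:
            raise ValueError("|rho| must lie in (0, 1)")


def paired_t(x, y, label: str = "paired_t") -> StatResult:
    """Paired-samples t test of x vs y with Cohen's d = t/sqrt(n)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite with no missing pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * st.t.sf(abs(t), n - 1)
    return StatResult(label, float(t), n - 1, float(p), float(d.mean() / sd), n)


def pearson(x, y, label: str = "pearson") -> StatResult:
    """Pearson correlation with the exact two-tailed t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        # perfectly collinear: the t transform degenerates; report p = 0
        r = 1.0 if r > 0 else -1.0
        return StatResult(label, np.inf if r > 0 else -np.inf, n - 2, 0.0, r, n)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * st.t.sf(abs(t), n - 2)
    return StatResult(label, float(t), n - 2, float(p), r, n)


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a printed correlation coefficient at sample size n."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * st.t.sf(abs(t), n - 2))


def correlation_power(rho: float, n: int, alpha_level: float = 0.05) -> float:
    """Power of the two-sided test of ρ = 0 at sample size n.

    Noncentral-t approximation: the test statistic under the alternative is
    treated as noncentral t with df = n−2 and noncentrality
    ρ sqrt(n) / sqrt(1−ρ²).
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("|rho| must lie in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    df = n - 2
    tcrit = st.t.isf(alpha_level / 2.0, df)
    nc = rho * np.sqrt(n) / np.sqrt(1.0 - rho * rho)
    return float(st.nct.sf(tcrit, df, nc) + st.nct.cdf(-tcrit, df, nc))


def correlation_sample_size(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n whose computed power reaches the target, by upward scan."""
    n = 4
    while n <= n_max:
        if correlation_power(spec.rho, n, spec.alpha_level) >= spec.target_power:
            return n
        n += 1
    raise RuntimeError(f"no n <= {n_max} reaches power {spec.target_power}")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _corr_cell(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(r, p) for one table cell; p is NaN when n < 3 (degenerate)."""
    if x.size < 3:
        return (float(np.corrcoef(x, y)[0, 1]) if x.size == 2 else np.nan, np.nan)
    res = pearson(x, y)
    return res.effect_size, res.p_two_tailed


def _adjust(p_values: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return p_values
    flat = p_values.ravel()
    ok = np.isfinite(flat)
    adj = flat.copy()
    m = int(ok.sum())
    if method == "bonferroni":
        adj[ok] = np.minimum(flat[ok] * m, 1.0)
    elif method == "fdr_bh":
        order = np.argsort(flat[ok])
        ranked = flat[ok][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(ranked, 1.0)
        adj[ok] = vals
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return adj.reshape(p_values.shape)


def build_report(
    spectral: pd.DataFrame,
    erpbehav: pd.DataFrame,
    correction: str | None = None,
    decimals: int = 3,
) -> dict[str, pd.DataFrame]:
    """Build the four summary tables from per-subject metric frames.

    ``spectral`` is long-format with columns subject_id, condition,
    electrode, theta_beta_ratio_sqrt, alpha_power_sqrt.  ``erpbehav`` has one
    row per subject with columns subject_id, acs_total, rt_interference,
    n2d, p3d.  Returns:

    * ``descriptives`` — mean and SE of the square-root-transformed
      theta/beta ratio and alpha power per condition x electrode;
    * ``tbr_correlations`` / ``alpha_correlations`` — r and p of each EEG
      metric row (condition x electrode) against the four attentional-control
      measures;
    * ``measure_correlations`` — the 4 x 4 inter-measure correlation table
      (lower triangle; diagonal shown as em dash).
    """
    spec_subj = set(spectral["subject_id"])
    beh_subj = set(erpbehav["subject_id"])
    if spec_subj != beh_subj:
        raise ValueError(
            "subject sets differ; missing from spectral: "
            f"{sorted(beh_subj - spec_subj)}; missing from behavior: "
            f"{sorted(spec_subj - beh_subj)}"
        )
    erpbehav = erpbehav.sort_values("subject_id").reset_index(drop=True)

    # descriptives -----------------------------------------------------------
    rows = []
    for (cond, el), grp in spectral.groupby(["condition", "electrode"], sort=True):
        for metric in ("theta_beta_ratio_sqrt", "alpha_power_sqrt"):
            v = grp.sort_values("subject_id")[metric].to_numpy()
            rows.append(
                {
                    "metric": metric,
                    "condition": cond,
                    "electrode": el,
                    "mean": v.mean(),
                    "se": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan,
                    "n": v.size,
                }
            )
    descriptives = pd.DataFrame(rows).round(decimals)

    # EEG metric x measure correlation tables --------------------------------
    measures = {
        m: erpbehav[m].to_numpy(dtype=float) for m in REPORT_MEASURES
    }

    def metric_table(metric: str) -> pd.DataFrame:
        out_rows = []
        p_cells = []
        for (cond, el), grp in spectral.groupby(["condition", "electrode"], sort=True):
            v = grp.sort_values("subject_id")[metric].to_numpy(dtype=float)
            row: dict[str, object] = {"condition": cond, "electrode": el}
            for m in REPORT_MEASURES:
                r, p = _corr_cell(v, measures[m])
                row[f"r_{_MEASURE_TITLES[m]}"] = r
                row[f"p_{_MEASURE_TITLES[m]}"] = p
                p_cells.append(p)
            out_rows.append(row)
        tbl = pd.DataFrame(out_rows)
        if correction is not None:
            pcols = [c for c in tbl.columns if c.startswith("p_")]
            tbl[pcols] = _adjust(tbl[pcols].to_numpy(dtype=float), correction)
        return tbl.round(decimals)

    tbr_tbl = metric_table("theta_beta_ratio_sqrt")
    alpha_tbl = metric_table("alpha_power_sqrt")

    # inter-measure table ----------------------------------------------------
    k = len(REPORT_MEASURES)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i):
            r, p = _corr_cell(measures[REPORT_MEASURES[i]], measures[REPORT_MEASURES[j]])
            r_mat[i, j], p_mat[i, j] = r, p
    if correction is not None:
        tril = np.tril_indices(k, -1)
        p_mat[tril] = _adjust(p_mat[tril], correction)
    titles = [_MEASURE_TITLES[m] for m in REPORT_MEASURES]
    inter = pd.DataFrame(
        np.round(r_mat, decimals), index=titles, columns=titles, dtype=object
    )
    inter_p = pd.DataFrame(np.round(p_mat, decimals), index=titles, columns=titles, dtype=object)
    for i in range(k):
        inter.iloc[i, i] = "—"
        inter_p.iloc[i, i] = "—"
        for j in range(i + 1, k):
            inter.iloc[i, j] = ""
            inter_p.iloc[i, j] = ""

    return {
        "descriptives": descriptives,
        "tbr_correlations": tbr_tbl,
        "alpha_correlations": alpha_tbl,
        "measure_correlations": inter,
        "measure_correlations_p": inter_p,
    }
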