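"""Marginal models of MNP outcomes: GEE with exchangeable working
correlation clustered by subject, paired pipeline comparisons, and cohort
summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GEEFit",
    "TermEstimate",
    "fit_gee",
    "paired_comparison",
    "summarize_mnp",
    "simulate_mnp_table",
    "MULTIVARIABLE_MODELS",
]

log = logging.getLogger(__name__)

#: Multivariable model term sets fitted by the report stage.
MULTIVARIABLE_MODELS: tuple[tuple[str, ...], ...] = (
    ("age_years", "asm_use"),
    ("age_years", "suprathreshold"),
    ("asm_use", "suprathreshold"),
    ("age_years", "asm_use", "suprathreshold"),
)

COHORT_COLUMNS = (
    "subject_id", "block_id", "measure", "window", "mnp", "attained",
    "hemisphere", "day", "block_order", "suprathreshold", "asm_use", "age_years",
)


@dataclass
class TermEstimate:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass
class GEEFit:
    """Identity-link Gaussian GEE fit with robust (sandwich) inference."""

    terms: list[TermEstimate]
    n_obs: int
    n_clusters: int
    measure: str | None = None
    window: str | None = None
    formula: str = ""
    result: object = field(default=None, repr=False)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name or t.term.startswith(name):
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.term,
                    "estimate": t.estimate,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "z": t.z,
                    "p": t.p,
                }
                for t in self.terms
            ]
        )


def _prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    for col in ("suprathreshold", "asm_use", "attained"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "hemisphere" in df.columns:
        df["hemisphere"] = df["hemisphere"].astype(str)
    return df


def fit_gee(
    table: pd.DataFrame,
    terms: list[str] | tuple[str, ...],
    measure: str | None = None,
    window: str | None = None,
    outcome: str = "mnp",
) -> GEEFit:
    """Fit ``outcome ~ terms`` as a linear marginal model.

    Gaussian working variance, identity link, exchangeable working
    correlation clustered on ``subject_id``, robust sandwich standard errors;
    two-sided p-values from the normal reference for Z. Because cohorts of
    this kind have few clusters (~18 subjects), the sandwich uses the
    bias-reduced (Mancl-DeRouen) form and confidence intervals use t critical
    values with (clusters - parameters) degrees of freedom; the plain
    sandwich under-covers badly at this size. The table is filtered to one
    measure x window when those are given.
    """
    df = _prepare_table(table)
    if measure is not None:
        df = df[df["measure"] == measure]
    if window is not None:
        df = df[df["window"] == window]
    if df.empty:
        raise ValueError("no rows after filtering")
    for term in terms:
        if term not in df.columns:
            raise ValueError(f"term {term!r} not present in table")
        if df[term].nunique() < 2:
            raise ValueError(f"term {term!r} is constant; singular design")
    if df["subject_id"].nunique() < 2:
        raise ValueError("GEE clustering needs at least 2 subjects")

    rhs = " + ".join(f"C({t})" if df[t].dtype == object else t for t in terms)
    formula = f"{outcome} ~ {rhs}"

    # a noiseless (exactly linear) table breaks the GEE scale estimate;
    # report the exact OLS solution with degenerate inference instead
    ols = sm.OLS.from_formula(formula, data=df).fit()
    if ols.ssr < 1e-10 * len(df):
        log.warning("outcome is an exact linear function of the terms; degenerate fit")
        terms_out = [
            TermEstimate(term=name, estimate=float(ols.params[name]),
                         ci_low=float(ols.params[name]), ci_high=float(ols.params[name]),
                         z=float("inf"), p=0.0)
            for name in ols.params.index
            if name != "Intercept"
        ]
        return GEEFit(terms=terms_out, n_obs=len(df),
                      n_clusters=df["subject_id"].nunique(),
                      measure=measure, window=window, formula=formula, result=ols)

    model = sm.GEE.from_formula(
        formula,
        groups="subject_id",
        data=df,
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit(cov_type="bias_reduced")
    n_clusters = df["subject_id"].nunique()
    dof = max(n_clusters - len(res.params), 1)
    tcrit = float(sps.t.ppf(0.975, dof))
    terms_out = []
    for name in res.params.index:
        if name == "Intercept":
            continue
        est = float(res.params[name])
        se = float(res.bse[name])
        if not np.isfinite(se) or se <= 0:
            log.warning("degenerate standard error for %s; reporting infinite Z", name)
            terms_out.append(TermEstimate(term=name, estimate=est, ci_low=est,
                                          ci_high=est, z=float("inf") if est else 0.0,
                                          p=0.0 if est else 1.0))
            continue
        z = est / se
        terms_out.append(
            TermEstimate(
                term=name,
                estimate=est,
                ci_low=est - tcrit * se,
                ci_high=est + tcrit * se,
                z=z,
                p=float(2.0 * sps.norm.sf(abs(z))),
            )
        )
    return GEEFit(
        terms=terms_out,
        n_obs=len(df),
        n_clusters=df["subject_id"].nunique(),
        measure=measure,
        window=window,
        formula=formula,
        result=res,
    )


def paired_comparison(values_a, values_b) -> tuple[float, float, float]:
    """Two-sided paired t-test on per-block differences.

    Returns (mean difference, t, p). Exact ties (all differences zero) use
    the convention p = 1; zero variance with a nonzero mean difference is a
    degenerate exact shift and is reported as t = inf, p = 0 (logged).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length paired series with >= 3 blocks")
    d = b - a
    md = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if md == 0.0:
            log.info("paired comparison: exact tie, p = 1 convention")
            return 0.0, 0.0, 1.0
        log.warning("paired comparison: exact constant shift, p -> 0")
        return md, float(np.inf) * np.sign(md), 0.0
    t, p = sps.ttest_rel(b, a)
    return md, float(t), float(p)


def summarize_mnp(table: pd.DataFrame, measure: str, window: str) -> tuple[int, int, int, int]:
    """(mean, sd, q80, max) of MNP for one measure x window.

    Mean and SD are rounded to the nearest whole pulse; q80 is the smallest
    observed MNP value covering at least 80% of blocks.
    """
    df = table[(table["measure"] == measure) & (table["window"] == window)]
    if df.empty:
        raise ValueError(f"no rows for {measure}/{window}")
    vals = df["mnp"].to_numpy(dtype=float)
    mean = int(round(float(vals.mean())))
    sd = int(round(float(vals.std(ddof=1)))) if vals.size > 1 else 0
    q80 = None
    for v in np.sort(np.unique(vals)):
        if np.mean(vals <= v) >= 0.8:
            q80 = int(v)
            break
    return mean, sd, q80, int(vals.max())


def simulate_mnp_table(
    n_subjects: int = 18,
    rows_per_subject: int = 7,
    intercept: float = 37.0,
    age_slope: float = -4.6,
    within_subject_corr: float = 0.3,
    total_sd: float = 10.0,
    age_range: tuple[float, float] = (7.0, 13.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort table with a known linear age effect.

    mnp = intercept + age_slope * (age - age_range[0]) + u_subject + eps,
    where Var(u) = rho * total_sd^2 and Var(eps) = (1 - rho) * total_sd^2
    gives an exchangeable within-subject correlation of rho. Used as ground
    truth for GEE recovery checks.
    """
    rng = np.random.default_rng(seed)
    rho = within_subject_corr
    ages = rng.uniform(*age_range, n_subjects)
    u = rng.normal(0.0, np.sqrt(rho) * total_sd, n_subjects)
    rows = []
    for i in range(n_subjects):
        for j in range(rows_per_subject):
            eps = rng.normal(0.0, np.sqrt(1.0 - rho) * total_sd)
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "block_id": f"S{i:02d}_b{j}",
                    "measure": "local",
                    "window": "early",
                    "mnp": intercept + age_slope * (ages[i] - age_range[0]) + u[i] + eps,
                    "attained": True,
                    "hemisphere": ("left", "right")[j % 2],
                    "day": 1 + (j // 4),
                    "block_order": (j % 4) + 1,
                    "suprathreshold": bool(rng.random() < 0.5),
                    "asm_use": bool(i % 2),
                    "age_years": float(ages[i]),
                }
            )
    return pd.DataFrame(rows)
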