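"""Group-comparison statistics for pathway activity score tables.

Three contrast families cover the study designs this package targets:

* unpaired two-group comparisons — two-sided Mann-Whitney U rank-sum test
  with Bonferroni correction over the contrast family;
* paired before/after designs — two-sided paired t-test;
* repeated-measures time courses — linear mixed-effects model with a
  categorical time fixed effect and a random intercept per subject, with a
  per-contrast Wald t-test (between-subject degrees of freedom) of each
  post-baseline time against baseline.

Significance annotation follows the convention ``** p < 0.01``,
``*** p < 0.001``, ``**** p < 0.0001``, ``ns`` otherwise; p < 0.01 is the
significance cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: annotation thresholds, checked in order
ANNOTATION_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"))

#: exact Mann-Whitney distribution used up to this combined sample size
EXACT_MW_MAX_N = 12


@dataclass
class ComparisonResult:
    """One group contrast for one pathway."""

    pathway_name: str
    contrast_label: str
    statistic_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int  # size of the Bonferroni family (1 = uncorrected)
    annotation: str

    def __post_init__(self) -> None:
        expected = min(1.0, self.m * self.p_raw)
        if not np.isclose(self.p_adjusted, expected, rtol=1e-12, atol=1e-300):
            raise ValueError("p_adjusted inconsistent with Bonferroni family size")
        if self.annotation != annotate(self.p_adjusted):
            raise ValueError("annotation inconsistent with p_adjusted")


def annotate(p: float) -> str:
    """Map a p-value to its figure annotation string."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, stars in ANNOTATION_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    return min(1.0, m * p_raw)


def mann_whitney_two_sided(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.  Symmetric under group swap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_t_two_sided(before, after) -> tuple[float, int, float]:
    """Two-sided paired t-test on differences after - before.

    Returns (t, df, p).  Zero-variance differences: all-zero -> p = 1 by
    convention (no change); constant non-zero difference is degenerate and
    raises.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired groups must have equal length")
    n = before.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if float(np.mean(d)) == 0.0:
            return 0.0, df, 1.0
        raise ValueError("degenerate differences: constant non-zero change")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def _contrast_wald(sub: pd.DataFrame) -> tuple[float, float]:
    """REML Wald statistic for the ``is_later`` effect; (t, coef).

    Fits pas ~ is_later with a random intercept per subject by REML.  When
    the subject variance sits on the zero boundary the MixedLM Hessian can
    be singular; the fallback then is the complete-pair within-subject
    difference estimate, which is the boundary limit of the same
    statistic for this design.
    """
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm("pas ~ is_later", sub, groups=sub["subject_id"]).fit(
                reml=True, method="lbfgs"
            )
            coef = float(fit.params["is_later"])
            se = float(fit.bse["is_later"])
            if np.isfinite(coef) and np.isfinite(se) and se > 0:
                return coef / se, coef
        except (np.linalg.LinAlgError, ValueError):
            pass
    wide = sub.pivot_table(index="subject_id", columns="is_later", values="pas")
    wide = wide.dropna()
    d = wide[1.0] - wide[0.0]
    n = len(d)
    sd = float(np.std(d, ddof=1))
    coef = float(np.mean(d))
    if sd == 0.0:
        return (0.0 if coef == 0.0 else np.sign(coef) * np.inf), coef
    return coef / (sd / np.sqrt(n)), coef


def lmm_timecourse(
    pas_long: pd.DataFrame,
    pathway: str | None = None,
    baseline: float | None = None,
) -> list[ComparisonResult]:
    """Mixed-model time-course contrasts: each later time vs baseline.

    Expects a long table with columns ``pas``, ``subject_id``,
    ``time_point`` (and ``pathway`` when ``pathway`` is not given as the
    single implied pathway).  The model is

        pas ~ C(time_point) + (1 | subject)

    fit by restricted maximum likelihood on the subset of samples at
    baseline and that time; each contrast's p-value is a Wald t-test of
    the time coefficient against a t distribution with n_subjects - 1
    degrees of freedom (between-within degrees of freedom, the
    small-sample reference for a subject-level contrast; the asymptotic
    chi-squared likelihood-ratio reference is anti-conservative at the
    subject counts these designs have).  Location shifts of the response
    leave all p-values unchanged.
    """
    required = {"pas", "subject_id", "time_point"}
    missing = required - set(pas_long.columns)
    if missing:
        raise ValueError(f"PAS table missing columns: {sorted(missing)}")
    data = pas_long.copy()
    if pathway is not None:
        if "pathway" in data.columns:
            data = data.loc[data["pathway"] == pathway]
        name = pathway
    else:
        names = data["pathway"].unique() if "pathway" in data.columns else ["(all)"]
        if len(names) != 1:
            raise ValueError("multiple pathways in table; pass pathway=")
        name = str(names[0])
    data = data.dropna(subset=["pas", "subject_id", "time_point"])
    if data["subject_id"].nunique() < 2:
        raise ValueError(
            "need >=2 subjects for a mixed model; use the paired t-test for "
            "a single-subject before/after design"
        )
    times = np.sort(data["time_point"].unique())
    if times.size < 2:
        raise ValueError("need >=2 time points")
    base = float(times[0]) if baseline is None else float(baseline)
    if base not in set(float(t) for t in times):
        raise ValueError(f"baseline time {base} not present")
    subjects_at_base = set(data.loc[data["time_point"] == base, "subject_id"])
    if not set(data["subject_id"]) <= subjects_at_base:
        missing_subj = sorted(set(data["subject_id"]) - subjects_at_base)
        raise ValueError(f"subjects missing baseline observation: {missing_subj}")

    later = [float(t) for t in times if float(t) != base]
    results = []
    for t_point in later:
        sub = data.loc[data["time_point"].isin([base, t_point])].copy()
        sub["is_later"] = (sub["time_point"] == t_point).astype(float)
        t_stat, _ = _contrast_wald(sub)
        df_t = sub.loc[sub["is_later"] == 1.0, "subject_id"].nunique() - 1
        p = float(2.0 * sps.t.sf(abs(t_stat), df_t)) if np.isfinite(t_stat) else 0.0
        results.append(
            ComparisonResult(
                pathway_name=name,
                contrast_label=f"{base:g}h vs {t_point:g}h",
                statistic_name="wald_t",
                statistic=float(t_stat),
                p_raw=p,
                p_adjusted=p,
                m=1,
                annotation=annotate(p),
            )
        )
    return results


def compare_groups(
    pas_long: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    group_col: str = "group_label",
    family: str = "per_pathway",
) -> pd.DataFrame:
    """Mann-Whitney + Bonferroni over a contrast plan, per pathway.

    ``contrasts`` is a list of (group A, group B) label pairs.  The
    Bonferroni family size is the number of contrasts per pathway
    (``family='per_pathway'``, the default) or contrasts x pathways
    (``family='across_pathways'``).
    """
    if family not in ("per_pathway", "across_pathways"):
        raise ValueError(f"unknown family policy: {family!r}")
    pathways = sorted(pas_long["pathway"].unique())
    known = set(pas_long[group_col].dropna().unique())
    for a, b in contrasts:
        for g in (a, b):
            if g not in known:
                raise ValueError(f"contrast references unknown group {g!r}")
    m = len(contrasts) if family == "per_pathway" else len(contrasts) * len(pathways)
    rows = []
    for pathway in pathways:
        sub = pas_long.loc[pas_long["pathway"] == pathway]
        for a, b in contrasts:
            x = sub.loc[sub[group_col] == a, "pas"].to_numpy()
            y = sub.loc[sub[group_col] == b, "pas"].to_numpy()
            label = f"{a} vs {b}"
            if x.size < 2 or y.size < 2:
                rows.append(
                    {
                        "pathway": pathway,
                        "contrast": label,
                        "statistic_name": "MannWhitneyU",
                        "statistic": np.nan,
                        "p_raw": np.nan,
                        "p_adjusted": np.nan,
                        "m": m,
                        "annotation": "not evaluable",
                    }
                )
                continue
            u, p = mann_whitney_two_sided(x, y)
            p_adj = bonferroni(p, m)
            rows.append(
                {
                    "pathway": pathway,
                    "contrast": label,
                    "statistic_name": "MannWhitneyU",
                    "statistic": u,
                    "p_raw": p,
                    "p_adjusted": p_adj,
                    "m": m,
                    "annotation": annotate(p_adj),
                }
            )
    return pd.DataFrame(rows)
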