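"""Pre/post randomized-trial statistics for per-subject HRV metric panels.

Within-group change uses a paired t-test when the paired differences pass a
Shapiro–Wilk normality check (alpha = 0.05) and the Wilcoxon signed-rank
test otherwise.  The between-group end-of-study comparison is an ANCOVA —
an OLS of the post value on the study arm with age and the same metric's
baseline value as covariates — with Sidak-adjusted pairwise arm contrasts
as post hoc tests.  Descriptive summaries are formatted mean (SD) for
normal samples and median (Q1–Q3) otherwise, mirroring the trial tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


@dataclass
class SubjectRecord:
    """Arm, age and the pre/post metric panels for one participant."""

    subject_id: str
    arm: str
    age: float
    pre: Dict[str, Optional[float]]
    post: Dict[str, Optional[float]]

    def __post_init__(self) -> None:
        if set(self.pre) != set(self.post):
            raise ValueError("pre and post panels must contain the same metric keys")


@dataclass
class MetricComparison:
    """All trial statistics for one metric."""

    metric: str
    within_p: Dict[str, float]          # per-arm within-group p
    within_test: Dict[str, str]         # per-arm test used
    ancova_p: float                     # omnibus arm effect p
    posthoc_raw: Dict[str, float]       # pairwise contrast p, unadjusted
    posthoc_sidak: Dict[str, float]     # Sidak-adjusted pairwise p
    summaries: Dict[str, Dict[str, str]]  # arm -> {"pre": ..., "post": ...}
    n_used: int                         # subjects after listwise deletion

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialResult:
    """Per-metric comparisons for a whole trial."""

    metrics: Dict[str, MetricComparison] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v.to_dict() for k, v in self.metrics.items()}


def sidak_adjust(p: float, k: int) -> float:
    """Sidak multiplicity adjustment, 1 - (1 - p)^k, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return float(min(1.0, 1.0 - (1.0 - p) ** k))


def within_group_change(pre: Sequence[float], post: Sequence[float],
                        normality_alpha: float = NORMALITY_ALPHA) -> Tuple[float, str]:
    """Two-sided p for the paired pre→post change, with a normality gate.

    Shapiro–Wilk on the paired differences selects the paired t-test
    (normal) or the Wilcoxon signed-rank test.  All-zero differences give
    p = 1 by convention.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    ok = ~(np.isnan(pre) | np.isnan(post))
    d = post[ok] - pre[ok]
    if d.size < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.all(d == 0):
        return 1.0, "degenerate (no change)"
    sw_p = stats.shapiro(d).pvalue
    if sw_p > normality_alpha:
        p = stats.ttest_rel(post[ok], pre[ok]).pvalue
        return float(p), "paired t-test"
    p = stats.wilcoxon(d, alternative="two-sided").pvalue
    return float(p), "Wilcoxon signed-rank"


def summarize(values: Sequence[float], normality_alpha: float = NORMALITY_ALPHA) -> str:
    """Format a sample as ``mean (SD)`` or ``median (Q1–Q3)``.

    The branch is chosen by Shapiro–Wilk at alpha = 0.05; constant samples
    are reported as mean (0.0).  SD is the sample SD (ddof=1), the usual
    descriptive-table convention; quartiles use linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("need at least 3 values to summarize")
    if np.all(v == v[0]):
        return f"{v[0]:.1f} (0.0)"
    normal = stats.shapiro(v).pvalue > normality_alpha
    if normal:
        return f"{np.mean(v):.1f} ({np.std(v, ddof=1):.1f})"
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def _records_frame(records: Sequence[SubjectRecord], metric: str) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "arm": r.arm,
                "age": r.age,
                "baseline": r.pre.get(metric),
                "post": r.post.get(metric),
            }
        )
    df = pd.DataFrame(rows)
    n0 = len(df)
    df = df.dropna(subset=["age", "baseline", "post"])
    dropped = n0 - len(df)
    if dropped:
        logger.info("metric %s: dropped %d subjects with missing values (listwise)", metric, dropped)
    return df


def ancova_end_of_study(
    records: Sequence[SubjectRecord],
    metric: str,
    covariates: Tuple[str, ...] = ("age", "baseline"),
) -> Tuple[float, Dict[str, float], Dict[str, float], int]:
    """ANCOVA of the end-of-study value on arm, adjusting for covariates.

    Fits ``post ~ C(arm) [+ age + baseline]`` by OLS, returns the omnibus
    arm-effect p (type-II F), the raw pairwise contrast p-values and their
    Sidak adjustment, and the number of subjects used.  With an empty
    covariate tuple this reduces to a one-way ANOVA on the post values.
    """
    df = _records_frame(records, metric)
    arms = sorted(df["arm"].unique())
    if len(arms) < 2 or df.groupby("arm").size().min() < 3:
        raise ValueError("need at least 2 arms with at least 3 subjects each")

    cols = ["age", "baseline"]
    x_check = df[[c for c in cols if c in covariates]]
    if len(covariates) and np.linalg.matrix_rank(
        np.column_stack([np.ones(len(df))] + [x_check[c] for c in x_check])
    ) < x_check.shape[1] + 1:
        raise ValueError("collinear covariates: age/baseline are constant or linearly dependent")

    formula = "post ~ C(arm)" + "".join(f" + {c}" for c in covariates)
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    omnibus_p = float(anova.loc["C(arm)", "PR(>F)"])

    pairs = list(itertools.combinations(arms, 2))
    k = len(pairs)
    raw: Dict[str, float] = {}
    adj: Dict[str, float] = {}
    names = model.params.index
    for a, b in pairs:
        contrast = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == f"C(arm)[T.{a}]":
                contrast[i] += 1.0
            if name == f"C(arm)[T.{b}]":
                contrast[i] -= 1.0
        p = float(model.t_test(contrast).pvalue)
        key = f"{a} vs {b}"
        raw[key] = p
        adj[key] = sidak_adjust(p, k)
    return omnibus_p, raw, adj, len(df)


def _simulated_records(
    rng: np.random.Generator,
    n_per_arm: int,
    effect_sd: float,
    baseline_corr: float,
    shifted_arm: str = "water",
) -> List[SubjectRecord]:
    """Gaussian end-of-study data: one arm shifted by ``effect_sd`` within-group SDs.

    The baseline value correlates with the end-of-study value at
    ``baseline_corr``; age is an independent covariate with no effect, so
    the simulated outcome SD is the within-group post SD the design's
    '1 standard deviation' refers to.
    """
    recs: List[SubjectRecord] = []
    resid = float(np.sqrt(1.0 - baseline_corr**2))
    for arm in ("land", "water", "control"):
        for i in range(n_per_arm):
            base = float(rng.normal(0.0, 1.0))
            post = baseline_corr * base + resid * float(rng.normal(0.0, 1.0))
            if arm == shifted_arm:
                post += effect_sd
            recs.append(
                SubjectRecord(
                    subject_id=f"{arm}{i}", arm=arm, age=float(rng.normal(60.0, 8.0)),
                    pre={"m": base}, post={"m": post},
                )
            )
    return recs


def estimate_design_power(
    n_per_arm: int = 26,
    effect_sd: float = 1.0,
    n_reps: int = 2000,
    alpha: float = 0.05,
    baseline_corr: float = 0.5,
    seed: Optional[int] = None,
) -> float:
    """Empirical power of the ANCOVA omnibus test at a between-group shift.

    Monte-Carlo over ``n_reps`` trials with one arm shifted by ``effect_sd``
    within-group SDs of the end-of-study value; returns the fraction of
    omnibus p-values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        p, _, _, _ = ancova_end_of_study(
            _simulated_records(rng, n_per_arm, effect_sd, baseline_corr), "m"
        )
        hits += p < alpha
    return hits / n_reps


def estimate_type1_error(
    n_per_arm: int = 26,
    n_reps: int = 1000,
    alpha: float = 0.05,
    baseline_corr: float = 0.5,
    seed: Optional[int] = None,
) -> Dict[str, float]:
    """Null rejection rates of the ANCOVA omnibus and within-group tests."""
    rng = np.random.default_rng(seed)
    ancova_hits = 0
    within_hits = 0
    for _ in range(n_reps):
        recs = _simulated_records(rng, n_per_arm, 0.0, baseline_corr)
        p, _, _, _ = ancova_end_of_study(recs, "m")
        ancova_hits += p < alpha
        arm = [r for r in recs if r.arm == "water"]
        pw, _ = within_group_change(
            [r.pre["m"] for r in arm], [r.post["m"] for r in arm]
        )
        within_hits += pw < alpha
    return {"ancova": ancova_hits / n_reps, "within": within_hits / n_reps}


def analyze_trial(
    records: Sequence[SubjectRecord],
    metrics: Optional[Sequence[str]] = None,
    covariates: Tuple[str, ...] = ("age", "baseline"),
) -> TrialResult:
    """Run the full within/between comparison for every metric."""
    if not records:
        raise ValueError("no subject records")
    if metrics is None:
        metrics = sorted(records[0].pre.keys())
    result = TrialResult()
    for metric in metrics:
        df = _records_frame(records, metric)
        within_p: Dict[str, float] = {}
        within_test: Dict[str, str] = {}
        summaries: Dict[str, Dict[str, str]] = {}
        for arm, sub in df.groupby("arm"):
            p, test = within_group_change(sub["baseline"].to_numpy(), sub["post"].to_numpy())
            within_p[arm] = p
            within_test[arm] = test
            summaries[arm] = {
                "pre": summarize(sub["baseline"].to_numpy()),
                "post": summarize(sub["post"].to_numpy()),
            }
        omnibus_p, raw, adj, n_used = ancova_end_of_study(records, metric, covariates=covariates)
        result.metrics[metric] = MetricComparison(
            metric=metric, within_p=within_p, within_test=within_test,
            ancova_p=omnibus_p, posthoc_raw=raw, posthoc_sidak=adj,
            summaries=summaries, n_used=n_used,
        )
    return result
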