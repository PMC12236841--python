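"""The study's statistical decision tree and cohort summaries.

Group comparisons are routed by a Shapiro-Wilk normality gate on the
residuals (values minus group means):

* residuals normal, two groups      -> Student's t test
* residuals normal, three+ groups   -> one-way ANOVA + Holm-Sidak post hoc
* residuals non-normal, two groups  -> Mann-Whitney U
* residuals non-normal, three+      -> Kruskal-Wallis + Dunn's contrasts

Significance is read at p < 0.05 throughout; every routing decision and
threshold is logged in the returned result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalityGate",
    "Contrast",
    "StatResult",
    "CompareConfig",
    "ComparisonSpec",
    "CohortReport",
    "residual_normality",
    "compare",
    "dunn_test",
    "percent_change",
    "summarize_cohort",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityGate:
    """Outcome of the residual-normality gate."""

    normal: bool
    p_value: float | None
    forced_nonparametric: bool = False
    note: str = ""


@dataclass(frozen=True)
class Contrast:
    label_a: str
    label_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None
    group_sizes: tuple[int, ...]
    gate: NormalityGate
    posthoc: tuple[Contrast, ...] = ()
    significant: bool = False
    log: tuple[str, ...] = ()


@dataclass(frozen=True)
class CompareConfig:
    alpha: float = ALPHA
    gate_alpha: float = ALPHA
    equal_var: bool = True  # classic Student's t, matching the ANOVA branch


def residual_normality(groups: list[np.ndarray], gate_alpha: float = ALPHA) -> NormalityGate:
    """Shapiro-Wilk on within-group residuals; passes when p > gate_alpha.

    Any group with fewer than 3 observations, or an all-constant residual
    vector, forces the nonparametric branch with a note.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 3 for g in groups):
        return NormalityGate(
            normal=False, p_value=None, forced_nonparametric=True,
            note="group with n < 3: nonparametric branch forced",
        )
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(residuals) == 0:
        return NormalityGate(
            normal=False, p_value=None, forced_nonparametric=True,
            note="zero-variance residuals: nonparametric branch forced",
        )
    stat, p = sp_stats.shapiro(residuals)
    return NormalityGate(normal=bool(p > gate_alpha), p_value=float(p))


def dunn_test(
    groups: list[np.ndarray], labels: list[str], adjust: str = "sidak"
) -> list[Contrast]:
    """Dunn's rank-based multiple contrasts after Kruskal-Wallis.

    Pairwise z statistics on mean ranks of the pooled sample with the
    standard tie correction; family-wise adjustment by the Sidak step
    (``1 - (1-p)^m``), paralleling the parametric Holm-Sidak branch, or
    Bonferroni.
    """
    if adjust not in ("sidak", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sp_stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * sp_stats.norm.sf(abs(z))
            if adjust == "sidak":
                p_adj = 1.0 - (1.0 - min(p_raw, 1.0)) ** m
            else:
                p_adj = min(1.0, p_raw * m)
            out.append(
                Contrast(labels[i], labels[j], float(z), float(p_raw), float(min(p_adj, 1.0)))
            )
    return out


def _holm_sidak_posthoc(
    groups: list[np.ndarray], labels: list[str], equal_var: bool
) -> list[Contrast]:
    stats, p_raw, pairs = [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, p = sp_stats.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            stats.append(float(t))
            p_raw.append(float(p))
            pairs.append((labels[i], labels[j]))
    _, p_adj, _, _ = multipletests(p_raw, method="holm-sidak")
    return [
        Contrast(a, b, s, pr, float(pa))
        for (a, b), s, pr, pa in zip(pairs, stats, p_raw, p_adj)
    ]


def compare(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    cfg: CompareConfig = CompareConfig(),
) -> StatResult:
    """Route a 2+ group comparison through the gated decision tree."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match groups")
    gate = residual_normality(groups, cfg.gate_alpha)
    log = [
        f"normality gate: p={gate.p_value if gate.p_value is not None else 'n/a'}, "
        f"normal={gate.normal}" + (f" ({gate.note})" if gate.note else "")
    ]
    sizes = tuple(g.size for g in groups)
    posthoc: tuple[Contrast, ...] = ()
    if gate.normal:
        if len(groups) == 2:
            name = "t-test"
            stat, p = sp_stats.ttest_ind(groups[0], groups[1], equal_var=cfg.equal_var)
            df = sizes[0] + sizes[1] - 2
        else:
            name = "one-way ANOVA"
            stat, p = sp_stats.f_oneway(*groups)
            df = len(groups) - 1
            posthoc = tuple(_holm_sidak_posthoc(groups, labels, cfg.equal_var))
            log.append("post hoc: Holm-Sidak pairwise t tests")
    else:
        if len(groups) == 2:
            name = "Mann-Whitney U"
            stat, p = sp_stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            df = 1
        else:
            name = "Kruskal-Wallis"
            stat, p = sp_stats.kruskal(*groups)
            df = len(groups) - 1
            posthoc = tuple(dunn_test(groups, labels))
            log.append("post hoc: Dunn contrasts (Sidak family adjustment)")
    log.append(f"routed to {name}")
    return StatResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        df=float(df),
        group_sizes=sizes,
        gate=gate,
        posthoc=posthoc,
        significant=bool(p < cfg.alpha),
        log=tuple(log),
    )


def percent_change(reference: np.ndarray, treated: np.ndarray) -> float:
    """Percent decrease of the treated mean relative to the reference mean."""
    reference = np.asarray(reference, dtype=float)
    treated = np.asarray(treated, dtype=float)
    ref_mean = reference.mean()
    if ref_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (ref_mean - treated.mean()) / ref_mean


@dataclass(frozen=True)
class ComparisonSpec:
    """One planned comparison over the cohort table."""

    name: str
    metric: str
    factor: str  # column whose levels define the groups, e.g. "genotype"
    filters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortReport:
    descriptives: pd.DataFrame
    results: tuple[tuple[str, StatResult], ...]
    log: tuple[str, ...]


def summarize_cohort(
    table: pd.DataFrame,
    plan: list[ComparisonSpec] | None = None,
    cfg: CompareConfig = CompareConfig(),
    censor_column: str = "censored",
) -> CohortReport:
    """Descriptive summaries plus one gated comparison per planned contrast.

    Censored observations (e.g. no ABR response at the 80 dB ceiling),
    flagged in ``censor_column`` when present, are excluded from comparisons
    with their counts logged rather than imputed.
    """
    plan = plan or []
    log: list[str] = []
    work = table.copy()
    if censor_column in work.columns:
        n_cens = int(work[censor_column].sum())
        if n_cens:
            log.append(f"excluded {n_cens} censored observations")
        work = work[~work[censor_column].astype(bool)]
    known_metrics = set(work["metric"].unique())
    desc = (
        work.groupby(["metric", "genotype", "arm", "age", "frequency_khz"])["value"]
        .agg(
            n="count",
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            median="median",
            iqr=lambda v: v.quantile(0.75) - v.quantile(0.25),
        )
        .reset_index()
    )
    results = []
    for spec in plan:
        if spec.metric not in known_metrics:
            raise ValueError(f"plan references unknown metric {spec.metric!r}")
        sub = work[work["metric"] == spec.metric]
        for col, val in spec.filters.items():
            if col not in sub.columns:
                raise ValueError(f"plan filter references unknown column {col!r}")
            sub = sub[sub[col] == val]
        if spec.factor not in sub.columns:
            raise ValueError(f"plan factor references unknown column {spec.factor!r}")
        labels = sorted(sub[spec.factor].unique())
        groups = [sub.loc[sub[spec.factor] == lab, "value"].to_numpy() for lab in labels]
        if len(groups) < 2:
            raise ValueError(f"comparison {spec.name!r} selects fewer than 2 groups")
        res = compare(groups, [str(x) for x in labels], cfg)
        log.append(f"{spec.name}: {res.test_name}, p={res.p_value:.4g}")
        results.append((spec.name, res))
    return CohortReport(descriptives=desc, results=tuple(results), log=tuple(log))
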