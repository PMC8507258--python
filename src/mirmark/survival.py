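"""Median-split survival analysis and exhaustive miRNA-panel screening.

Patients are dichotomized at each marker's median tumour expression: strictly
above the median is "higher", at or below is "lower". Multi-miRNA panels use
the concordant-median rule by default — a patient joins the higher (lower)
group only when above (at/below) the median for *every* panel member, and
discordant patients are excluded. This conjunction shrinks groups roughly
geometrically with panel size, which is what motivates capping panels (at 5 by
default) and requiring a minimum group size (30 by default) before a panel is
tested. A mean-of-z-scores grouping that preserves group sizes is available
for sensitivity analysis (``grouping="meanscore"``).

Tested panels are compared by the two-group log-rank test, and the hazard
ratio of higher vs lower comes from a single-covariate Cox proportional-
hazards fit (Efron tie handling, 95% Wald CI) via lifelines. A panel "passes"
when its log-rank p is below alpha; no multiplicity correction is applied
across panels by default (an optional BH column can be added by callers from
the returned p-values).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .datatypes import ClinicalTable, CohortMatrix
from .errors import ValidationError

GROUPINGS = ("concordant", "meanscore")


@dataclass
class SurvivalGroups:
    """Higher/lower/excluded patient partition for one panel."""

    panel: tuple[str, ...]
    higher_ids: list[str]
    lower_ids: list[str]
    excluded_ids: list[str]
    medians: dict[str, float]

    @property
    def n_higher(self) -> int:
        return len(self.higher_ids)

    @property
    def n_lower(self) -> int:
        return len(self.lower_ids)


def median_split(values: pd.Series) -> SurvivalGroups:
    """Split patients at the median of one marker (ties go to "lower").

    Requires at least two distinct observed values; a constant marker cannot
    split anyone and raises.
    """
    v = values.dropna().astype(float)
    if v.nunique() < 2:
        raise ValidationError("median split impossible: all values identical")
    med = float(v.median())
    higher = list(v.index[v > med])
    lower = list(v.index[v <= med])
    return SurvivalGroups(
        panel=(str(values.name),) if values.name is not None else ("marker",),
        higher_ids=higher,
        lower_ids=lower,
        excluded_ids=[],
        medians={str(values.name): med},
    )


def panel_groups(
    expr: pd.DataFrame,
    panel: Sequence[str],
    grouping: str = "concordant",
) -> SurvivalGroups:
    """Patient grouping for a miRNA panel on a miRNA x patient frame.

    Patients missing any panel value are excluded from the analysis; medians
    are computed on the remaining (analyzed) patients. Under the concordant
    rule the higher group must be above the median for every panel miRNA and
    the lower group at-or-below for every one; everyone else is excluded.
    Under ``meanscore`` the panel score is the mean of per-miRNA z-scores and
    the split is a plain median split of that score (no exclusions).
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}")
    panel = tuple(panel)
    unknown = [m for m in panel if m not in expr.index]
    if unknown:
        raise ValidationError(f"panel miRNAs not in matrix: {unknown}")
    sub = expr.loc[list(panel)]
    complete = sub.columns[~sub.isna().any(axis=0)]
    sub = sub[complete]
    if sub.shape[1] == 0:
        raise ValidationError("no patients with complete panel values")
    if grouping == "meanscore":
        z = sub.sub(sub.mean(axis=1), axis=0)
        sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = z.div(sd, axis=0).fillna(0.0)
        score = z.mean(axis=0)
        score.name = "+".join(panel)
        groups = median_split(score)
        return SurvivalGroups(panel, groups.higher_ids, groups.lower_ids, [],
                              groups.medians)
    med = sub.median(axis=1)
    above = sub.gt(med, axis=0)
    all_above = above.all(axis=0)
    all_below = (~above).all(axis=0)
    higher = list(sub.columns[all_above])
    lower = list(sub.columns[all_below])
    excluded = list(sub.columns[~(all_above | all_below)])
    return SurvivalGroups(panel, higher, lower, excluded,
                          {m: float(med[m]) for m in panel})


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Standard two-group log-rank test -> (chi-square statistic, p-value).

    With no events in either group the curves are uninformative: returns
    (0, 1) with a warning instead of a division by zero.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, float)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, float)
    if len(ta) == 0 or len(tb) == 0:
        raise ValidationError("both groups must be non-empty")
    if (ta < 0).any() or (tb < 0).any():
        raise ValidationError("negative survival times")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, p = 1",
                      stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if math.isnan(chi2):
        return 0.0, 1.0
    return chi2, p


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se: float
    converged: bool


def cox_hr(group_indicator, times, events) -> CoxResult:
    """Hazard ratio (higher vs lower) from a single-covariate Cox PH fit.

    ``group_indicator`` is 0 for the lower group and 1 for the higher group.
    Complete separation or other convergence failures yield a flagged,
    non-converged result rather than an exception.
    """
    g = np.asarray(group_indicator, float)
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    if set(np.unique(g)) != {0.0, 1.0}:
        raise ValidationError("group indicator must contain both 0 and 1")
    df = pd.DataFrame({"time": t, "event": e, "higher": g})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["higher"])
        se = float(cph.standard_errors_["higher"])
        if not (math.isfinite(coef) and math.isfinite(se)) or se > 50:
            raise ValueError("degenerate fit")
        return CoxResult(
            hr=math.exp(coef),
            ci_low=math.exp(coef - 1.959963984540054 * se),
            ci_high=math.exp(coef + 1.959963984540054 * se),
            p_value=float(cph.summary.loc["higher", "p"]),
            log_hr=coef,
            se=se,
            converged=True,
        )
    except Exception:
        return CoxResult(math.nan, math.nan, math.nan, math.nan,
                         math.nan, math.nan, converged=False)


# ---------------------------------------------------------------------------
# panel enumeration and screening
# ---------------------------------------------------------------------------

def panel_count(n: int, k_min: int = 2, k_max: int = 5) -> int:
    """Number of unordered panels of sizes k_min..k_max over n miRNAs."""
    if k_min > k_max:
        raise ValidationError("k_min > k_max")
    return sum(math.comb(n, k) for k in range(k_min, k_max + 1))


def enumerate_panels(
    mirnas: Sequence[str], k_min: int = 2, k_max: int = 5
) -> Iterator[tuple[str, ...]]:
    """All unordered panels in deterministic lexicographic (input-order) order."""
    if k_min > k_max:
        raise ValidationError("k_min > k_max")
    if k_max > len(mirnas):
        raise ValidationError(f"k_max={k_max} exceeds {len(mirnas)} miRNAs")
    for k in range(k_min, k_max + 1):
        yield from itertools.combinations(mirnas, k)


@dataclass
class PanelScreenResult:
    """Outcome of an exhaustive panel screen for one stage/endpoint."""

    stage: str | None
    endpoint: str
    results: pd.DataFrame
    counts: pd.DataFrame          # per panel size: enumerated/tested/rejected/passing
    n_patients: int
    skipped: bool = False
    reason: str | None = None
    params: dict = field(default_factory=dict)

    def passing(self) -> pd.DataFrame:
        if self.results.empty:
            return self.results
        return self.results[self.results["passes"]]


def _empty_screen(stage, endpoint, n_patients, reason, params) -> PanelScreenResult:
    cols = ["panel", "size", "n_higher", "n_lower", "n_excluded",
            "logrank_chi2", "logrank_p", "hr", "hr_ci_low", "hr_ci_high",
            "cox_p", "cox_converged", "passes"]
    return PanelScreenResult(
        stage, endpoint, pd.DataFrame(columns=cols),
        pd.DataFrame(columns=["size", "enumerated", "tested", "rejected", "passing"]),
        n_patients, skipped=True, reason=reason, params=params,
    )


def screen_panels(
    expr: CohortMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    stage: str | None = None,
    endpoint: str = "OS",
    mirnas: Iterable[str] | None = None,
    k_min: int = 2,
    k_max: int = 5,
    min_group: int = 30,
    alpha: float = 0.05,
    grouping: str = "concordant",
    compute_hr: bool = True,
) -> PanelScreenResult:
    """Exhaustively screen miRNA panels for survival separation.

    ``expr`` is tumour expression (a CohortMatrix, whose tumour columns are
    used, or a plain miRNA x patient frame). Patients are restricted to the
    given stage (None = all stages) and to those with the endpoint recorded.
    Each enumerated panel is grouped; panels whose smaller group is below
    ``min_group`` are rejected without testing, the rest get a log-rank test
    (and a Cox HR when ``compute_hr``). Results are sorted by log-rank p.
    """
    if isinstance(expr, CohortMatrix):
        frame = expr.values[expr.tumour_samples]
    else:
        frame = expr
    params = dict(stage=stage, endpoint=endpoint, k_min=k_min, k_max=k_max,
                  min_group=min_group, alpha=alpha, grouping=grouping)

    clin = clinical.for_stage(stage)
    surv = clin.endpoint(endpoint)
    patients = [p for p in frame.columns if p in surv.index]
    if len(patients) < 2 * min_group:
        return _empty_screen(stage, endpoint, len(patients),
                             f"only {len(patients)} patients with {endpoint} data "
                             f"(need >= {2 * min_group})", params)
    frame = frame[patients]
    surv = surv.loc[patients]
    pool = [m for m in (mirnas if mirnas is not None else frame.index)
            if m in frame.index]
    if k_max > len(pool):
        return _empty_screen(stage, endpoint, len(patients),
                             f"k_max={k_max} exceeds pool of {len(pool)} miRNAs", params)

    times = surv["time"].to_numpy()
    events = surv["event"].to_numpy()
    col_pos = {p: i for i, p in enumerate(patients)}

    rows: list[dict] = []
    counts = {k: {"enumerated": 0, "tested": 0, "rejected": 0, "passing": 0}
              for k in range(k_min, k_max + 1)}
    for panel in enumerate_panels(pool, k_min, k_max):
        k = len(panel)
        counts[k]["enumerated"] += 1
        try:
            groups = panel_groups(frame, panel, grouping=grouping)
        except ValidationError:
            counts[k]["rejected"] += 1
            continue
        if min(groups.n_higher, groups.n_lower) < min_group:
            counts[k]["rejected"] += 1
            continue
        counts[k]["tested"] += 1
        hi = [col_pos[p] for p in groups.higher_ids]
        lo = [col_pos[p] for p in groups.lower_ids]
        chi2, p = logrank_test(times[hi], events[hi], times[lo], events[lo])
        row = {
            "panel": panel,
            "size": k,
            "n_higher": groups.n_higher,
            "n_lower": groups.n_lower,
            "n_excluded": len(groups.excluded_ids),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "hr": math.nan,
            "hr_ci_low": math.nan,
            "hr_ci_high": math.nan,
            "cox_p": math.nan,
            "cox_converged": False,
            "passes": bool(p < alpha),
        }
        if compute_hr:
            idx = hi + lo
            g = np.r_[np.ones(len(hi)), np.zeros(len(lo))]
            cox = cox_hr(g, times[idx], events[idx])
            row.update(hr=cox.hr, hr_ci_low=cox.ci_low, hr_ci_high=cox.ci_high,
                       cox_p=cox.p_value, cox_converged=cox.converged)
        if row["passes"]:
            counts[k]["passing"] += 1
        rows.append(row)

    results = pd.DataFrame(rows)
    if len(results):
        results = results.sort_values("logrank_p", kind="mergesort").reset_index(drop=True)
    count_tab = pd.DataFrame(
        [{"size": k, **v} for k, v in sorted(counts.items())]
    )
    return PanelScreenResult(stage, endpoint, results, count_tab, len(patients),
                             params=params)
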