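"""Paired statistical battery on per-animal condition means.

The battery mirrors a small-n within-animal design: a Shapiro-Wilk check on
the paired differences gates each one-tailed paired t test (falling back to
an exact one-tailed Wilcoxon signed-rank test on violation); bivariate
groups of measures are tested with a paired Hotelling's T², followed on a
significant result by Bonferroni-corrected post hoc paired t tests; effect
sizes are Cohen's d computed with the pooled SD of the per-animal condition
means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .core import PairedAnimalTable

ALPHA = 0.05


@dataclass
class StatReport:
    """Result of one test, JSON-serializable via ``to_dict``."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    one_tailed: bool = True
    effect_size: float | None = None
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    alpha: float = ALPHA
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "df": self.df,
             "p": self.p, "one_tailed": self.one_tailed, "alpha": self.alpha,
             "significant": self.significant}
        if self.effect_size is not None:
            d["cohens_d"] = self.effect_size
        if self.shapiro_w is not None:
            d["shapiro_w"] = self.shapiro_w
            d["shapiro_p"] = self.shapiro_p
        if self.notes:
            d["notes"] = list(self.notes)
        return d


def _diffs(table: PairedAnimalTable | np.ndarray) -> np.ndarray:
    if isinstance(table, PairedAnimalTable):
        return table.differences()
    return np.asarray(table, dtype=float)


def paired_t_one_tailed(table: PairedAnimalTable | np.ndarray,
                        direction: str = "greater", alpha: float = ALPHA) -> StatReport:
    """One-tailed paired t test on loaded - unloaded differences.

    ``direction="greater"`` tests for an increase under load. A zero-variance
    sample with nonzero mean yields a boundary p (0 or 1) with a warning.
    """
    d = _diffs(table)
    n = len(d)
    if n < 2:
        raise ValueError("paired t needs at least two animals")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if np.mean(d) == 0.0:
            return StatReport("paired t", 0.0, n - 1, 0.5, alpha=alpha)
        warnings.warn("zero variance with nonzero mean difference; boundary p reported",
                      stacklevel=2)
        p = 0.0 if (np.mean(d) > 0) == (direction == "greater") else 1.0
        return StatReport("paired t", np.inf if p == 0 else -np.inf, n - 1, p,
                          alpha=alpha, notes=["degenerate zero-variance sample"])
    res = sst.ttest_1samp(d, 0.0, alternative=direction)
    return StatReport("paired t", float(res.statistic), n - 1, float(res.pvalue),
                      alpha=alpha)


def cohens_d(table: PairedAnimalTable, variant: str = "pooled") -> float:
    """Cohen's d for the paired condition means.

    ``pooled`` (default): mean difference over sqrt((var_u + var_l)/2) of the
    per-animal condition means. ``dz``: mean difference over the SD of the
    differences. ``av`` is an alias of pooled retained for comparison work.
    """
    u, load = table.condition_means()
    d = float(np.mean(load - u))
    if variant in ("pooled", "av"):
        denom = np.sqrt((np.var(u, ddof=1) + np.var(load, ddof=1)) / 2.0)
    elif variant == "dz":
        denom = np.std(load - u, ddof=1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0:
        raise ValueError("zero pooled SD")
    return d / float(denom)


def shapiro_wilk(diffs: PairedAnimalTable | np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p on the paired differences (3 <= n <= 5000)."""
    d = _diffs(diffs)
    if not 3 <= len(d) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0:
        raise ValueError("constant sample")
    w, p = sst.shapiro(d)
    return float(w), float(p)


def _signed_midranks(d: np.ndarray) -> np.ndarray:
    ranks = sst.rankdata(np.abs(d))  # midranks on ties
    return ranks


def wilcoxon_signed_rank_exact(diffs: PairedAnimalTable | np.ndarray,
                               direction: str = "greater",
                               alpha: float = ALPHA) -> StatReport:
    """Exact one-tailed paired Wilcoxon signed-rank test.

    W is the sum of the ranks of the positive differences; the p value is
    computed by enumerating all 2^n sign assignments (midranks are used on
    tied magnitudes, keeping the enumeration exact; ties trigger a warning).
    Zero differences are dropped before ranking, per the standard
    signed-rank convention.
    """
    d = _diffs(diffs)
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if np.any(d == 0):
        warnings.warn("zero differences dropped before signed ranking", stacklevel=2)
        d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero differences")
    if n > 25:
        raise ValueError("exact enumeration limited to n <= 25")
    ranks = _signed_midranks(d)
    if len(np.unique(np.abs(d))) < n:
        warnings.warn("tied |differences|: midranks with exact enumeration", stacklevel=2)
    w = float(np.sum(ranks[d > 0]))
    # distribution of W over all 2^n sign assignments
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    w_all = signs @ ranks
    if direction == "greater":
        p = float(np.mean(w_all >= w))
    else:
        p = float(np.mean(w_all <= w))
    return StatReport("wilcoxon signed-rank (exact)", w, n, p, alpha=alpha)


def hotelling_t2_paired(*tables: PairedAnimalTable, alpha: float = ALPHA) -> StatReport:
    """Paired Hotelling's T² on p measures' difference vectors (p = 2 in the
    study's design; p = 1 reduces to the squared paired t).

    T² = n · d̄ᵀ S⁻¹ d̄ over the per-animal difference vectors;
    F = (n - p) / (p (n - 1)) · T² with (p, n - p) degrees of freedom.
    """
    D = np.column_stack([t.differences() for t in tables])
    n, p = D.shape
    if n <= p:
        raise ValueError(f"need more animals ({n}) than variables ({p})")
    dbar = D.mean(axis=0)
    S = np.atleast_2d(np.cov(D.T))
    if np.linalg.matrix_rank(S) < p:
        raise ValueError("singular covariance matrix of differences")
    t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    f = (n - p) / (p * (n - 1)) * t2
    pval = float(sst.f.sf(f, p, n - p))
    rep = StatReport("hotelling T2 (paired)", t2, (p, n - p), pval,
                     one_tailed=False, alpha=alpha)
    rep.notes.append(f"F({p},{n - p}) = {f:.6g}")
    return rep


def hotelling_f(report: StatReport) -> float:
    """The F statistic corresponding to a Hotelling report."""
    p, n_minus_p = report.df  # type: ignore[misc]
    n = n_minus_p + p
    return (n - p) / (p * (n - 1)) * report.statistic


def posthoc_bonferroni(reports: list[StatReport], alpha: float = ALPHA) -> list[StatReport]:
    """Flag significance at alpha/k for k post hoc tests; raw p unchanged."""
    k = len(reports)
    if k < 1:
        raise ValueError("need at least one post hoc test")
    out = []
    for r in reports:
        adj = StatReport(r.test, r.statistic, r.df, r.p, r.one_tailed,
                         r.effect_size, r.shapiro_w, r.shapiro_p,
                         alpha=alpha / k, notes=list(r.notes))
        adj.notes.append(f"bonferroni k={k}")
        out.append(adj)
    return out


def linregress_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """OLS coefficient of determination R², two-sided slope p, and n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs at least three points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sst.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue), len(x)


# ------------------------------------------------------------------ battery

def gated_paired_test(table: PairedAnimalTable, direction: str = "greater",
                      alpha: float = ALPHA) -> StatReport:
    """Shapiro-Wilk gate in front of the paired t: a significant deviation
    from normality (p < 0.05) routes to the exact Wilcoxon signed-rank.
    With n < 3 animals the gate cannot run and the t test is used directly."""
    if len(table.differences() if isinstance(table, PairedAnimalTable) else table) < 3:
        rep = paired_t_one_tailed(table, direction, alpha=alpha)
        rep.effect_size = cohens_d(table)
        rep.notes.append("n < 3: normality gate skipped")
        return rep
    w, p_norm = shapiro_wilk(table)
    if p_norm < ALPHA:
        rep = wilcoxon_signed_rank_exact(table, direction, alpha=alpha)
    else:
        rep = paired_t_one_tailed(table, direction, alpha=alpha)
    rep.shapiro_w, rep.shapiro_p = w, p_norm
    rep.effect_size = cohens_d(table)
    return rep


def analyze_battery(tables: dict[str, PairedAnimalTable],
                    plan: list[dict] | None = None) -> dict:
    """Run the full battery from a plan.

    Each plan entry is either ``{"kind": "univariate", "measure": m}`` or
    ``{"kind": "bivariate", "measures": [m1, m2]}`` (Hotelling at the group
    level, post hoc gated paired t tests at alpha/2 when significant). The
    default plan reproduces the study design for whatever recognized
    measures are present.
    """
    plan = plan if plan is not None else default_plan(tables)
    report: dict = {}
    for entry in plan:
        if entry["kind"] == "bivariate":
            m1, m2 = entry["measures"]
            group = entry.get("name", f"{m1} + {m2}")
            hot = hotelling_t2_paired(tables[m1], tables[m2])
            item: dict = {"hotelling": hot.to_dict(), "F": hotelling_f(hot)}
            if hot.significant:
                posthocs = [gated_paired_test(tables[m]) for m in (m1, m2)]
                adjusted = posthoc_bonferroni(posthocs)
                item["posthoc"] = {m: r.to_dict() for m, r in zip((m1, m2), adjusted)}
            else:
                item["posthoc"] = None
            report[group] = item
        elif entry["kind"] == "univariate":
            m = entry["measure"]
            alpha = entry.get("alpha", ALPHA)
            report[m] = gated_paired_test(tables[m], alpha=alpha).to_dict()
        else:
            raise ValueError(f"unknown plan entry kind {entry['kind']!r}")
    return report


def default_plan(tables: dict[str, PairedAnimalTable]) -> list[dict]:
    """The study's grouping: protraction pair (B38, I2), retraction pair
    (B8a/b, B3/B6/B9), univariate B4/B5 — applied separately to duration and
    frequency measures; behavioral durations are univariate."""
    plan: list[dict] = []
    for suffix in (" duration", " frequency"):
        for name, pair in ((f"protraction{suffix}s", [f"B38{suffix}", f"I2{suffix}"]),
                           (f"retraction{suffix}s", [f"B8a/b{suffix}", f"B3/B6/B9{suffix}"])):
            if not all(m in tables for m in pair):
                continue
            if tables[pair[0]].n_animals > 2:
                plan.append({"kind": "bivariate", "measures": pair, "name": name})
            else:  # too few animals for a bivariate test; fall back to univariate
                plan.extend({"kind": "univariate", "measure": m} for m in pair)
        if f"B4/B5{suffix}" in tables:
            plan.append({"kind": "univariate", "measure": f"B4/B5{suffix}"})
    for m in tables:
        if not any(m.endswith(s) for s in (" duration", " frequency")):
            plan.append({"kind": "univariate", "measure": m})
    return plan
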