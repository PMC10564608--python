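"""Method-comparison statistics between two dietary assessment tools.

Given per-participant Nova energy shares measured by two tools, this module
computes:

* paired group means with normal-theory 95 % confidence intervals and a
  paired t-test on the differences (Wilcoxon signed-rank available);
* the intraclass correlation coefficient from a two-way model with tools as
  raters — default ICC(3,1), two-way mixed effects, single measurement,
  consistency — with the F-distribution confidence interval and the
  conventional interpretation bands (poor < 0.50 <= moderate < 0.75 <=
  good <= 0.90 < excellent);
* quintile cross-classification with exact/adjacent agreement proportions
  and the prevalence-adjusted bias-adjusted kappa,
  PABAK = (c*Po - 1)/(c - 1) with c = 5 categories, banded on the
  modified Landis–Koch scale;
* the minimum number of subjects for a reliability study, by the
  Walter–Eliasziw–Donner approximation (note: one-sided alpha).

ICC forms follow the Shrout–Fleiss / McGraw–Wong ANOVA mean-squares
conventions; all formulas are computed from the two-way ANOVA decomposition
(subjects x raters) directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DegenerateDataError

NOVA_GROUPS = (1, 2, 3, 4)

ICC_FORMS = ("consistency", "absolute_agreement")

#: ICC interpretation thresholds (lower bounds of moderate/good; upper bound
#: of good): values greater than 0.90 are "excellent".
ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"))

PABAK_BAND_LABELS = ("none", "none_to_slight", "fair", "moderate",
                     "substantial", "almost_perfect")


def icc_band(icc: float) -> str:
    """Interpretation band for an ICC (poor/moderate/good/excellent)."""
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def pabak_band(value: float) -> str:
    """Modified Landis–Koch band for a (PABAK) kappa-type statistic."""
    if value <= 0:
        return "none"
    if value <= 0.20:
        return "none_to_slight"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "substantial"
    return "almost_perfect"


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    form: str
    band: str
    ms_rows: float
    ms_cols: float
    ms_error: float


def _mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares of an (n subjects x k raters) table:
    rows (between subjects), columns (between raters), residual."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_error)


def icc_two_way(
    pairs: np.ndarray | Sequence[Sequence[float]],
    form: str = "consistency",
    alpha: float = 0.05,
) -> ICCResult:
    """Intraclass correlation from a two-way model, single measurement.

    ``pairs`` is an (n, k) table of measurements (rows = subjects, columns =
    raters/tools; k = 2 for a two-tool comparison).  ``form="consistency"``
    gives ICC(3,1) (two-way mixed); ``form="absolute_agreement"`` gives
    ICC(2,1).  The 95 % confidence interval uses the F-distribution method.
    """
    y = np.asarray(pairs, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ContractError("pairs must be an (n, k>=2) table")
    if np.isnan(y).any():
        y = y[~np.isnan(y).any(axis=1)]
    n, k = y.shape
    if n < 3:
        raise ContractError("ICC requires at least 3 complete subject rows")
    if form not in ICC_FORMS:
        raise ContractError(f"form must be one of {ICC_FORMS}")

    msr, msc, mse = _mean_squares(y)
    if msr <= 0 and mse <= 0:
        raise DegenerateDataError(
            "zero between-subject and residual variance: ICC undefined")

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:  # perfect agreement: CI degenerates at 1
            ci_low = ci_high = 1.0
        else:
            df1, df2 = n - 1, (n - 1) * (k - 1)
            f_obs = msr / mse
            f_low = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            f_up = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci_low = (f_low - 1) / (f_low + k - 1)
            ci_high = (f_up - 1) / (f_up + k - 1)
    else:  # absolute agreement, ICC(2,1)
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        # Satterthwaite df for the denominator (McGraw & Wong 1996)
        a = k * icc / (n * (1 - icc)) if icc < 1 else math.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else math.inf
        if math.isinf(a):
            ci_low, ci_high = 1.0, 1.0
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            ci_low = (n * (msr - f_l * mse)
                      / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            ci_high = (n * (f_u * msr - mse)
                       / (k * msc + (k * n - k - n) * mse + n * f_u * msr))

    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(
        icc=float(icc), ci_low=float(ci_low), ci_high=float(min(ci_high, 1.0)),
        n=n, k=k, form=form, band=icc_band(float(icc)),
        ms_rows=msr, ms_cols=msc, ms_error=mse)


def stratified_icc(
    pairs: np.ndarray | Sequence[Sequence[float]],
    strata: Sequence,
    form: str = "consistency",
    alpha: float = 0.05,
) -> dict[str, ICCResult]:
    """ICC per stratum label; strata with fewer than 3 subjects are skipped
    with a warning."""
    y = np.asarray(pairs, dtype=float)
    labels = np.asarray(strata)
    if len(labels) != y.shape[0]:
        raise ContractError("one stratum label per subject row required")
    out: dict[str, ICCResult] = {}
    for label in pd.unique(labels):
        mask = labels == label
        if mask.sum() < 3:
            warnings.warn(
                f"stratum {label!r} has n={int(mask.sum())} < 3: skipped",
                stacklevel=2)
            continue
        out[str(label)] = icc_two_way(y[mask], form=form, alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# paired means
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeanComparison:
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    diff: float
    diff_ci: tuple[float, float]
    p_value: float
    significant: Optional[bool]
    degenerate: bool = False
    method: str = "paired_t"


def _t_ci(x: np.ndarray, alpha: float) -> tuple[float, float]:
    n = len(x)
    se = x.std(ddof=1) / math.sqrt(n)
    margin = stats.t.ppf(1 - alpha / 2, n - 1) * se
    m = x.mean()
    return (float(m - margin), float(m + margin))


def compare_means(
    pairs_by_group: Mapping[int, tuple[Sequence[float], Sequence[float]]],
    alpha: float = 0.05,
    method: str = "paired_t",
) -> dict[int, MeanComparison]:
    """Per-Nova-group paired comparison of the two tools' mean shares.

    Zero variance of the paired differences makes the test statistic
    undefined; the comparison is then flagged degenerate (p = NaN,
    significance undecided) rather than guessed.
    """
    if method not in ("paired_t", "wilcoxon"):
        raise ContractError(f"unknown method {method!r}")
    out: dict[int, MeanComparison] = {}
    for group, (a, b) in pairs_by_group.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
            raise ContractError("each group needs >=2 complete pairs")
        diff = a - b
        degenerate = bool(np.allclose(diff.std(ddof=1), 0.0))
        if degenerate:
            p = math.nan
            significant = None
            diff_ci = (float(diff.mean()), float(diff.mean()))
        elif method == "paired_t":
            p = float(stats.ttest_rel(a, b).pvalue)
            significant = p < alpha
            diff_ci = _t_ci(diff, alpha)
        else:
            p = float(stats.wilcoxon(a, b).pvalue)
            significant = p < alpha
            diff_ci = _t_ci(diff, alpha)
        out[group] = MeanComparison(
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            ci_a=_t_ci(a, alpha), ci_b=_t_ci(b, alpha),
            diff=float(diff.mean()), diff_ci=diff_ci,
            p_value=p, significant=significant, degenerate=degenerate,
            method=method)
    return out


# ---------------------------------------------------------------------------
# quintile cross-classification + PABAK
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuintileAgreement:
    cross_table: np.ndarray  # 5x5 counts, rows = tool A quintile
    p_same: float
    p_same_or_adjacent: float
    pabak: float
    band: str
    mode: str = "rank"


def _rank_quintiles(values: np.ndarray) -> np.ndarray:
    """Balanced rank-based quintiles; ties broken by stable input order."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    for q, chunk in enumerate(np.array_split(np.arange(n), 5)):
        labels[order[chunk]] = q
    return labels


def _quantile_quintiles(values: np.ndarray) -> Optional[np.ndarray]:
    """Sample-quantile-threshold quintiles; None if ties empty a quintile."""
    cuts = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    labels = np.searchsorted(cuts, values, side="right")
    if len(np.unique(labels)) < 5:
        return None
    return labels


def quintile_agreement(
    shares_a: Sequence[float],
    shares_b: Sequence[float],
    mode: str = "rank",
) -> QuintileAgreement:
    """Cross-classify participants into quintiles of each tool's own
    empirical distribution and summarize agreement with PABAK.

    ``mode="rank"`` (default) uses balanced rank splits; ``"quantile"``
    uses sample-quantile thresholds and falls back to rank splits (with a
    warning) when heavy ties leave a quintile empty.
    """
    a = np.asarray(shares_a, dtype=float)
    b = np.asarray(shares_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("paired share vectors of equal length required")
    n = len(a)
    if n < 5:
        raise ContractError("quintile agreement requires at least 5 pairs")
    if mode not in ("rank", "quantile"):
        raise ContractError(f"unknown quintile mode {mode!r}")

    used_mode = mode
    if mode == "quantile":
        qa, qb = _quantile_quintiles(a), _quantile_quintiles(b)
        if qa is None or qb is None:
            warnings.warn("ties left an empty quintile; falling back to "
                          "rank-based split", stacklevel=2)
            used_mode = "rank"
        else:
            labels_a, labels_b = qa, qb
    if used_mode == "rank":
        labels_a, labels_b = _rank_quintiles(a), _rank_quintiles(b)

    table = np.zeros((5, 5), dtype=int)
    np.add.at(table, (labels_a, labels_b), 1)
    p_same = float(np.trace(table)) / n
    adjacent = sum(
        int(table[i, j]) for i in range(5) for j in range(5) if abs(i - j) <= 1)
    pabak = (5.0 * p_same - 1.0) / 4.0
    return QuintileAgreement(
        cross_table=table, p_same=p_same,
        p_same_or_adjacent=adjacent / n,
        pabak=float(pabak), band=pabak_band(float(pabak)), mode=used_mode)


def pabak_from_table(table: np.ndarray) -> float:
    """PABAK of an arbitrary c x c agreement table: (c*Po - 1)/(c - 1)."""
    table = np.asarray(table, dtype=float)
    c = table.shape[0]
    if table.shape != (c, c) or c < 2:
        raise ContractError("square table with >=2 categories required")
    total = table.sum()
    if total <= 0:
        raise ContractError("empty table")
    po = np.trace(table) / total
    return float((c * po - 1.0) / (c - 1.0))


# ---------------------------------------------------------------------------
# reliability-study sample size
# ---------------------------------------------------------------------------


def icc_sample_size(
    rho0: float,
    rho1: float,
    k: int = 2,
    alpha: float = 0.05,
    power: float = 0.80,
) -> int:
    """Minimum subjects to detect ICC ``rho1`` against null ``rho0`` with
    ``k`` ratings per subject (Walter–Eliasziw–Donner approximation).

    With theta = rho/(1 - rho) and C0 = (1 + k*theta0)/(1 + k*theta1)::

        n = 1 + 2k (z_{1-alpha} + z_{1-beta})^2 / ((k-1) (ln C0)^2)

    ``alpha`` is one-sided; the result is rounded up.  At the defaults
    (rho0=0, rho1=0.2, k=2) this gives 152 subjects.
    """
    if not (0 <= rho0 < rho1 < 1):
        raise ContractError("need 0 <= rho0 < rho1 < 1")
    if k < 2:
        raise ContractError("need k >= 2 ratings per subject")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ContractError("alpha and power must lie in (0, 1)")
    theta0 = rho0 / (1 - rho0)
    theta1 = rho1 / (1 - rho1)
    c0 = (1 + k * theta0) / (1 + k * theta1)
    z = stats.norm.ppf(1 - alpha) + stats.norm.ppf(power)
    n = 1 + 2 * k * z ** 2 / ((k - 1) * math.log(c0) ** 2)
    return int(math.ceil(n))


# ---------------------------------------------------------------------------
# full agreement report
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    n: int
    tool_a: str
    tool_b: str
    means: dict[int, MeanComparison]
    icc: dict[int, ICCResult]
    quintiles: dict[int, QuintileAgreement]
    alpha: float = 0.05
    icc_form: str = "consistency"
    notes: list[str] = field(default_factory=list)

    def to_payload(self) -> dict:
        def mc(m: MeanComparison) -> dict:
            return {
                "mean_a": m.mean_a, "ci_a": list(m.ci_a),
                "mean_b": m.mean_b, "ci_b": list(m.ci_b),
                "paired_diff": m.diff, "diff_ci": list(m.diff_ci),
                "p_value": None if math.isnan(m.p_value) else m.p_value,
                "significant": m.significant, "degenerate": m.degenerate,
                "method": m.method,
            }

        return {
            "n": self.n,
            "tools": {"a": self.tool_a, "b": self.tool_b},
            "alpha": self.alpha,
            "icc_form": self.icc_form,
            "groups": {
                str(g): {
                    "means": mc(self.means[g]),
                    "icc": {
                        "icc": self.icc[g].icc,
                        "ci": [self.icc[g].ci_low, self.icc[g].ci_high],
                        "band": self.icc[g].band,
                    },
                    "quintiles": {
                        "cross_table": self.quintiles[g].cross_table.tolist(),
                        "p_same": self.quintiles[g].p_same,
                        "p_same_or_adjacent": self.quintiles[g].p_same_or_adjacent,
                        "pabak": self.quintiles[g].pabak,
                        "band": self.quintiles[g].band,
                    },
                }
                for g in sorted(self.means)
            },
            "notes": self.notes,
        }

    def render_text(self) -> str:
        lines = [
            f"Agreement report: {self.tool_a} vs {self.tool_b} (n={self.n}, "
            f"ICC form={self.icc_form})",
            "",
            f"{'Nova group':<11}{'mean A (95% CI)':>24}{'mean B (95% CI)':>24}"
            f"{'ICC (95% CI)':>24}  band",
        ]
        for g in sorted(self.means):
            m, r = self.means[g], self.icc[g]
            lines.append(
                f"{g:<11}"
                f"{m.mean_a:7.1f} ({m.ci_a[0]:5.1f},{m.ci_a[1]:5.1f})   "
                f"{m.mean_b:7.1f} ({m.ci_b[0]:5.1f},{m.ci_b[1]:5.1f})   "
                f"{r.icc:5.2f} ({r.ci_low:5.2f},{r.ci_high:5.2f})   {r.band}")
        lines.append("")
        for g in sorted(self.quintiles):
            q = self.quintiles[g]
            lines.append(
                f"Nova group {g}: same quintile {100 * q.p_same:.1f}%, same or "
                f"adjacent {100 * q.p_same_or_adjacent:.1f}%, PABAK "
                f"{q.pabak:.2f} ({q.band})")
            for row in q.cross_table:
                lines.append("    " + " ".join(f"{v:4d}" for v in row))
        if self.notes:
            lines.append("")
            lines.extend(f"note: {note}" for note in self.notes)
        return "\n".join(lines) + "\n"


def paired_shares_from_frame(
    frame: pd.DataFrame,
    tool_a: str,
    tool_b: str,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Pivot a long paired-shares table (participant_id, tool, nova_group,
    share_pct) into per-group paired arrays over complete participants."""
    required = {"participant_id", "tool", "nova_group", "share_pct"}
    if not required.issubset(frame.columns):
        raise ContractError(f"paired-shares table needs columns {sorted(required)}")
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for group, sub in frame.groupby("nova_group"):
        wide = sub.pivot_table(index="participant_id", columns="tool",
                               values="share_pct", aggfunc="first")
        if tool_a not in wide.columns or tool_b not in wide.columns:
            raise ContractError(
                f"tools {tool_a!r}/{tool_b!r} not both present for group {group}")
        wide = wide[[tool_a, tool_b]].dropna().sort_index()
        out[int(group)] = (wide[tool_a].to_numpy(), wide[tool_b].to_numpy())
    return out


def agreement_report(
    frame: pd.DataFrame,
    tool_a: str,
    tool_b: str,
    *,
    icc_form: str = "consistency",
    quintile_mode: str = "rank",
    alpha: float = 0.05,
    method: str = "paired_t",
) -> AgreementReport:
    """Full two-tool agreement analysis from a long paired-shares table."""
    pairs = paired_shares_from_frame(frame, tool_a, tool_b)
    means = compare_means(pairs, alpha=alpha, method=method)
    icc = {g: icc_two_way(np.column_stack(ab), form=icc_form, alpha=alpha)
           for g, ab in pairs.items()}
    quintiles = {g: quintile_agreement(ab[0], ab[1], mode=quintile_mode)
                 for g, ab in pairs.items()}
    n = len(next(iter(pairs.values()))[0]) if pairs else 0
    return AgreementReport(n=n, tool_a=tool_a, tool_b=tool_b, means=means,
                           icc=icc, quintiles=quintiles, alpha=alpha,
                           icc_form=icc_form)
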