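"""Per-individual ROH burden summaries, group tests and binned odds ratios."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .snp_tests import chi2_2x2, truncate

BURDEN_STATS = ("n_rohs", "total_kb", "mean_kb")


@dataclass
class BurdenSummary:
    sample_id: str
    n_rohs: int
    total_kb: float

    @property
    def mean_kb(self) -> float:
        return self.total_kb / self.n_rohs if self.n_rohs > 0 else math.nan

    def stat(self, name: str) -> float:
        if name == "n_rohs":
            return float(self.n_rohs)
        if name == "total_kb":
            return self.total_kb
        if name == "mean_kb":
            return self.mean_kb
        raise KeyError(name)


@dataclass
class BinnedAssoc:
    label: str
    n_cases: int
    n_controls: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    p_logistic: float = math.nan
    is_reference: bool = False
    zero_cell: bool = False
    odds_ratio_haldane: float = math.nan


def summarize_burden(segments: list, samples: list) -> list:
    """One BurdenSummary per sample; zero-segment individuals included."""
    totals = {s.id: [0, 0.0] for s in samples}
    for seg in segments:
        if seg.sample_id not in totals:
            raise KeyError(f"segment sample {seg.sample_id!r} not in sample list")
        totals[seg.sample_id][0] += 1
        totals[seg.sample_id][1] += seg.length_kb
    return [BurdenSummary(s.id, *[totals[s.id][0], totals[s.id][1]]) for s in samples]


def group_burden_test(
    summaries: list,
    samples: list,
    stat: str = "n_rohs",
    n_perm: int = 0,
    seed: int | None = None,
    welch: bool = True,
    case_subset: set | None = None,
) -> dict:
    """Two-sample t-test (and optional label-permutation test) of a burden
    statistic between cases and controls.

    *case_subset* restricts cases to the given sample ids (subgroup
    analysis) while keeping all controls.  The permutation p is two-sided on
    the absolute group-mean difference.  Undefined statistic values
    (mean_kb of zero-segment individuals) are dropped.
    """
    is_case = {s.id: s.is_case for s in samples}
    x_case, x_ctrl = [], []
    for b in summaries:
        v = b.stat(stat)
        if math.isnan(v):
            continue
        if is_case[b.sample_id]:
            if case_subset is None or b.sample_id in case_subset:
                x_case.append(v)
        else:
            x_ctrl.append(v)
    x_case, x_ctrl = np.asarray(x_case), np.asarray(x_ctrl)
    out = {
        "n_case": x_case.size,
        "n_control": x_ctrl.size,
        "mean_case": float(x_case.mean()) if x_case.size else math.nan,
        "mean_control": float(x_ctrl.mean()) if x_ctrl.size else math.nan,
        "t": math.nan,
        "p": math.nan,
        "p_perm": math.nan,
        "degenerate": False,
    }
    if x_case.size < 2 or x_ctrl.size < 2:
        out["degenerate"] = True
        return out
    if np.ptp(x_case) == 0 and np.ptp(x_ctrl) == 0 and x_case.mean() == x_ctrl.mean():
        out.update(t=0.0, p=1.0, p_perm=1.0)
        return out
    t, p = stats.ttest_ind(x_case, x_ctrl, equal_var=not welch)
    out.update(t=float(t), p=float(p))
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x_case, x_ctrl])
        n1 = x_case.size
        obs = abs(x_case.mean() - x_ctrl.mean())
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:n1].mean() - perm[n1:].mean()) >= obs:
                count += 1
        out["p_perm"] = (1 + count) / (n_perm + 1)
    return out


def median_split(summaries: list, by: str = "mean_kb") -> dict:
    """Split samples at the median of a burden statistic.

    Returns the cut value and the sample-id sets strictly below vs at-or-
    above the median; an empty lower set (all values equal) is flagged.
    """
    vals = [(b.sample_id, b.stat(by)) for b in summaries if not math.isnan(b.stat(by))]
    if not vals:
        raise ValueError("statistic undefined for every sample")
    cut = float(np.median([v for _, v in vals]))
    lower = {sid for sid, v in vals if v < cut}
    upper = {sid for sid, v in vals if v >= cut}
    return {"cut": cut, "lower": lower, "upper": upper, "degenerate": len(lower) == 0}


def odds_ratio_2x2(cases_bin: int, controls_bin: int, cases_ref: int, controls_ref: int) -> dict:
    """Crude OR of a bin against the reference bin with a Woolf 95% CI.

    OR = (cases_bin * controls_ref) / (controls_bin * cases_ref);
    CI = exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells)).  A zero cell
    flags the estimate and a Haldane (+0.5 to every cell) value is reported
    separately.
    """
    a, b, c, d = cases_bin, controls_bin, cases_ref, controls_ref
    zero = 0 in (a, b, c, d)
    out = {"zero_cell": zero, "or": math.nan, "ci_low": math.nan, "ci_high": math.nan,
           "or_haldane": math.nan}
    if not zero:
        orr = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        out.update(
            **{"or": orr, "ci_low": orr * math.exp(-1.96 * se), "ci_high": orr * math.exp(1.96 * se)}
        )
    ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    out["or_haldane"] = (ah * dh) / (bh * ch)
    chi2, p = chi2_2x2(float(a), float(b), float(c), float(d))
    out.update(chi2=chi2, p=p)
    return out


def binned_or(
    summaries: list,
    samples: list,
    stat: str = "total_kb",
    n_bins: int = 4,
    case_subset: set | None = None,
) -> list:
    """Bin individuals on control-distribution quantiles and compute per-bin
    ORs against the lowest bin.

    Bin edges are the ``i/n_bins`` quantiles of the control values; ties
    fall into the lower bin, so realized control counts need not be equal.
    The lowest bin is the reference (OR = 1).  A crude chi-square p and a
    logistic-regression Wald p are reported side by side.
    """
    is_case = {s.id: s.is_case for s in samples}
    vals, labels = [], []
    for b in summaries:
        v = b.stat(stat)
        if math.isnan(v):
            continue
        if is_case[b.sample_id] and case_subset is not None and b.sample_id not in case_subset:
            continue
        vals.append(v)
        labels.append(is_case[b.sample_id])
    vals = np.asarray(vals)
    labels = np.asarray(labels, dtype=bool)
    ctrl_vals = vals[~labels]
    if np.unique(ctrl_vals).size < n_bins:
        raise ValueError(f"need >= {n_bins} distinct control values")
    edges = np.quantile(ctrl_vals, np.arange(1, n_bins) / n_bins)
    bins = np.searchsorted(edges, vals, side="left")
    counts = [
        (int((labels & (bins == k)).sum()), int((~labels & (bins == k)).sum()))
        for k in range(n_bins)
    ]
    a_ref, b_ref = counts[0]
    results = []
    for k in range(n_bins):
        a, b = counts[k]
        lo = edges[k - 1] if k > 0 else None
        hi = edges[k] if k < n_bins - 1 else None
        if lo is None:
            label = f"<={hi:.1f}"
        elif hi is None:
            label = f">{lo:.1f}"
        else:
            label = f"{lo:.1f}-{hi:.1f}"
        if k == 0:
            results.append(
                BinnedAssoc(label, a, b, 1.0, math.nan, math.nan, math.nan, math.nan,
                            is_reference=True)
            )
            continue
        res = odds_ratio_2x2(a, b, a_ref, b_ref)
        p_log = _logistic_bin_p(a, b, a_ref, b_ref)
        results.append(
            BinnedAssoc(
                label, a, b, res["or"], res["ci_low"], res["ci_high"], res["chi2"], res["p"],
                p_logistic=p_log, zero_cell=res["zero_cell"], odds_ratio_haldane=res["or_haldane"],
            )
        )
    return results


def _logistic_bin_p(a: int, b: int, c: int, d: int) -> float:
    """Wald p for the bin indicator in a bin-vs-reference logistic model."""
    from .glm import fit_logistic

    y = np.concatenate([np.ones(a + c), np.zeros(b + d)])
    x = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
    X = np.column_stack([np.ones_like(x), x])
    try:
        fit = fit_logistic(X, y)
    except (ValueError, np.linalg.LinAlgError):
        return math.nan
    return float(fit["p"][1]) if fit["converged"] else math.nan


def write_burden(summaries: list, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample\tn_rohs\ttotal_kb\tmean_kb\n")
        for b in summaries:
            mean = "NA" if math.isnan(b.mean_kb) else f"{b.mean_kb:.3f}"
            fh.write(f"{b.sample_id}\t{b.n_rohs}\t{b.total_kb:.3f}\t{mean}\n")
    return path


def write_binned(results: list, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("bin\tcases\tcontrols\tor\tci95\tchi2\tp\tp_logistic\n")
        for r in results:
            if r.is_reference:
                fh.write(f"{r.label}\t{r.n_cases}\t{r.n_controls}\t1.00\tRef.\t\t\t\n")
            else:
                orr = "NA" if math.isnan(r.odds_ratio) else f"{truncate(r.odds_ratio, 2):.2f}"
                ci = (
                    "NA"
                    if math.isnan(r.ci_low)
                    else f"{truncate(r.ci_low, 2):.2f}-{truncate(r.ci_high, 2):.2f}"
                )
                fh.write(
                    f"{r.label}\t{r.n_cases}\t{r.n_controls}\t{orr}\t{ci}"
                    f"\t{truncate(r.chi2, 2):.2f}\t{r.p:.3g}\t{r.p_logistic:.3g}\n"
                )
    return path
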