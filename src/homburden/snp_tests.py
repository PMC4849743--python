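"""SNP-by-SNP homozygosity vs case-status association with FDR control."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort import MISSING, GenotypeMatrix


@dataclass
class SnpTestResult:
    marker_id: str
    chrom: int
    pos_bp: int
    hom_cases: int
    het_cases: int
    hom_controls: int
    het_controls: int
    chi2: float
    p: float
    p_adj: float = float("nan")
    fdr_reject: bool = False
    degenerate: bool = False


def chi2_2x2(a: float, b: float, c: float, d: float) -> tuple:
    """Uncorrected Pearson chi-square for the table [[a, b], [c, d]].

    Returns ``(chi2, p)``; a zero margin yields ``(nan, 1.0)``.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return float("nan"), 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def snp_homozygosity_chi2(gm: GenotypeMatrix) -> list:
    """Per-SNP 2x2 chi-square of homozygous-vs-heterozygous by case-control.

    Homozygosity counts either allele ("major or minor"); missing calls are
    excluded per SNP.  SNPs with a zero margin (e.g. no heterozygote at all)
    are flagged degenerate with ``p = 1``.
    """
    case = gm.case_mask
    if case.all() or not case.any():
        raise ValueError("need at least one case and one control")
    calls = gm.calls
    obs = calls != MISSING
    hom = ((calls == 0) | (calls == 2)) & obs
    het = (calls == 1) & obs
    hom_ca = hom[case].sum(axis=0)
    het_ca = het[case].sum(axis=0)
    hom_co = hom[~case].sum(axis=0)
    het_co = het[~case].sum(axis=0)

    results = []
    for j, mk in enumerate(gm.markers):
        chi2, p = chi2_2x2(
            float(hom_ca[j]), float(het_ca[j]), float(hom_co[j]), float(het_co[j])
        )
        results.append(
            SnpTestResult(
                marker_id=mk.id,
                chrom=mk.chrom,
                pos_bp=mk.pos_bp,
                hom_cases=int(hom_ca[j]),
                het_cases=int(het_ca[j]),
                hom_controls=int(hom_co[j]),
                het_controls=int(het_co[j]),
                chi2=chi2,
                p=p,
                degenerate=not np.isfinite(chi2),
            )
        )
    return results


def bh_fdr(pvalues, q: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up procedure.

    Rejects the k smallest p-values where ``k = max{i: p(i) <= i*q/m}``;
    adjusted values are the usual step-up monotonized ``m*p(i)/i`` capped
    at 1.  Returns ``(reject, p_adj)`` arrays in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    k = below[-1] + 1 if below.size else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.empty(m, dtype=bool)
    p_adj = np.empty(m)
    reject[order] = reject_sorted
    p_adj[order] = adj_sorted
    return reject, p_adj


def annotate_fdr(results: list, q: float = 0.05) -> list:
    reject, p_adj = bh_fdr([r.p for r in results], q)
    for r, rej, pa in zip(results, reject, p_adj):
        r.fdr_reject = bool(rej)
        r.p_adj = float(pa)
    return results


def write_snp_results(results: list, path) -> Path:
    """TSV: marker, chrom, pos, counts, chi2 (truncated 2 dp), p, p_adj, reject."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            "marker\tchrom\tpos\thom_cases\thet_cases\thom_controls\thet_controls"
            "\tchi2\tp\tp_adj\treject\n"
        )
        for r in results:
            chi2_s = "NA" if not np.isfinite(r.chi2) else f"{truncate(r.chi2, 2):.2f}"
            fh.write(
                f"{r.marker_id}\t{r.chrom}\t{r.pos_bp}\t{r.hom_cases}\t{r.het_cases}"
                f"\t{r.hom_controls}\t{r.het_controls}\t{chi2_s}\t{r.p:.4g}"
                f"\t{r.p_adj:.4g}\t{int(r.fdr_reject)}\n"
            )
    return path


def truncate(x: float, digits: int = 2) -> float:
    """Truncate (not round) toward zero at *digits* decimals, as in report tables."""
    factor = 10.0 ** digits
    return float(np.trunc(x * factor) / factor)
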