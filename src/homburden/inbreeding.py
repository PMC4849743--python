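"""SNP-wise genomic inbreeding estimators and segment-based F_ROH.

Three per-SNP estimators (averaged over a sample's non-missing eligible
SNPs, with x the allele-b count, p the allele-b frequency, h = 2p(1-p)):

    F1 = ((x - 2p)^2 / h) - 1          # variance of additive values
    F2 = 1 - x(2 - x) / h              # excess homozygosity
    F3 = (x^2 - (1 + 2p)x + 2p^2) / h  # correlation of uniting gametes

plus F_ROH = sum of per-individual ROH bp above a length criterion divided
by the mappable autosomal genome length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from pathlib import Path
from scipy import stats

from .cohort import MISSING, GenomeLayout, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class InbreedingProfile:
    sample_id: str
    f1: float
    f2: float
    f3: float
    f_roh: float = math.nan
    per_chrom_f1: np.ndarray | None = None


def _per_snp_terms(calls: np.ndarray, p: np.ndarray, miss: np.ndarray):
    """Per-SNP F1/F2/F3 terms with missing entries masked to 0 weight."""
    x = calls.astype(float)
    x[miss] = 0.0
    h = 2.0 * p * (1.0 - p)
    t1 = (x - 2.0 * p) ** 2 / h - 1.0
    t2 = 1.0 - x * (2.0 - x) / h
    t3 = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / h
    return t1, t2, t3


def fhat_estimators(
    gm: GenotypeMatrix,
    marker_index: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
):
    """Per-sample (f1, f2, f3): mean per-SNP term over eligible SNPs.

    Eligible SNPs have 0 < freq_b < 1; missing calls are skipped per sample.
    A sample with no eligible non-missing call gets nan (flagged via log).
    *freqs* overrides the cached sample-estimated frequencies (e.g. with
    known simulation truth).  Returns three arrays aligned to ``gm.samples``.
    """
    p = gm.freqs if freqs is None else np.asarray(freqs, dtype=float)
    eligible = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if marker_index is not None:
        chosen = np.zeros(gm.n_markers, dtype=bool)
        chosen[marker_index] = True
        eligible &= chosen
    n_skip = int((~eligible).sum())
    if n_skip and marker_index is None:
        log.info("fhat: skipping %d markers with p outside (0,1)", n_skip)
    if not eligible.any():
        raise ValueError("no eligible markers (all frequencies outside (0,1))")
    idx = np.where(eligible)[0]
    calls = gm.calls[:, idx]
    miss = calls == MISSING
    t1, t2, t3 = _per_snp_terms(calls, p[idx], miss)
    w = (~miss).astype(float)
    denom = w.sum(axis=1)
    if (denom == 0).any():
        log.warning("fhat: %d samples have zero eligible calls", int((denom == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, (t1 * w).sum(axis=1) / denom, np.nan)
        f2 = np.where(denom > 0, (t2 * w).sum(axis=1) / denom, np.nan)
        f3 = np.where(denom > 0, (t3 * w).sum(axis=1) / denom, np.nan)
    return f1, f2, f3


def f_roh(
    segments: list,
    samples: list,
    layout: GenomeLayout | None = None,
    min_kb: float = 1000.0,
) -> np.ndarray:
    """Per-sample fraction of the autosomal genome inside ROHs >= *min_kb*."""
    layout = layout or GenomeLayout.default()
    l_auto = layout.total_autosomal_bp
    if l_auto <= 0:
        raise ValueError("layout.total_autosomal_bp must be positive")
    total_bp = {s.id: 0 for s in samples}
    for seg in segments:
        if seg.end_bp > layout.length_of(seg.chrom):
            raise ValueError(
                f"segment {seg.sample_id} chr{seg.chrom}:{seg.start_bp}-{seg.end_bp} "
                f"exceeds chromosome length {layout.length_of(seg.chrom)}"
            )
        if seg.length_kb >= min_kb:
            total_bp[seg.sample_id] += seg.length_bp
    return np.array([total_bp[s.id] / l_auto for s in samples], dtype=float)


def per_chromosome_f(gm: GenotypeMatrix, layout: GenomeLayout | None = None) -> dict:
    """F1 per sample restricted to each autosome.

    Returns a dict with the samples x 22 matrix (nan for chromosomes with no
    eligible SNP), per-chromosome across-sample SDs and, when a layout is
    given, the Pearson correlation of those SDs with chromosome bp length.
    """
    chroms = gm.chroms
    mat = np.full((gm.n_samples, 22), np.nan)
    for c in range(1, 23):
        idx = np.where(chroms == c)[0]
        if idx.size == 0:
            continue
        p = gm.freqs[idx]
        ok = idx[np.isfinite(p) & (p > 0) & (p < 1)]
        if ok.size == 0:
            continue
        f1, _, _ = fhat_estimators(gm, marker_index=ok)
        mat[:, c - 1] = f1
    with np.errstate(invalid="ignore"):
        sds = np.nanstd(mat, axis=0, ddof=1)
    out = {"f1_matrix": mat, "sd": sds}
    if layout is not None:
        present = np.isfinite(sds)
        if present.sum() >= 3:
            lengths = np.asarray(layout.chrom_lengths_bp, dtype=float)[present]
            r, p_r = stats.pearsonr(sds[present], lengths)
            out["sd_length_r"] = float(r)
            out["sd_length_p"] = float(p_r)
    return out


def build_profiles(
    gm: GenotypeMatrix,
    segments: list,
    layout: GenomeLayout | None = None,
    min_kb: float = 1000.0,
    with_per_chrom: bool = False,
) -> list:
    f1, f2, f3 = fhat_estimators(gm)
    froh = f_roh(segments, gm.samples, layout=layout, min_kb=min_kb)
    per_chrom = per_chromosome_f(gm)["f1_matrix"] if with_per_chrom else None
    return [
        InbreedingProfile(
            sample_id=s.id,
            f1=float(f1[i]),
            f2=float(f2[i]),
            f3=float(f3[i]),
            f_roh=float(froh[i]),
            per_chrom_f1=None if per_chrom is None else per_chrom[i],
        )
        for i, s in enumerate(gm.samples)
    ]


def measure_correlations(profiles: list, burdens: list) -> dict:
    """Pearson r (and p) between all pairs of consanguinity measures."""
    if len(profiles) < 3:
        raise ValueError("need >= 3 samples")
    by_id = {b.sample_id: b for b in burdens}
    names = ("n_rohs", "total_kb", "f1", "f2", "f3", "f_roh")
    cols = {
        "n_rohs": [by_id[p.sample_id].n_rohs for p in profiles],
        "total_kb": [by_id[p.sample_id].total_kb for p in profiles],
        "f1": [p.f1 for p in profiles],
        "f2": [p.f2 for p in profiles],
        "f3": [p.f3 for p in profiles],
        "f_roh": [p.f_roh for p in profiles],
    }
    r = np.eye(len(names))
    pmat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            x, y = np.asarray(cols[a], float), np.asarray(cols[b], float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij = math.nan, math.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            pmat[i, j] = pmat[j, i] = pij
    return {"names": names, "r": r, "p": pmat}


def write_profiles(profiles: list, burdens: list, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    by_id = {b.sample_id: b for b in burdens}
    with open(path, "w") as fh:
        fh.write("sample\tf1\tf2\tf3\tf_roh\tn_rohs\ttotal_kb\n")
        for p in profiles:
            b = by_id[p.sample_id]
            fh.write(
                f"{p.sample_id}\t{p.f1:.6g}\t{p.f2:.6g}\t{p.f3:.6g}\t{p.f_roh:.6g}"
                f"\t{b.n_rohs}\t{b.total_kb:.3f}\n"
            )
    return path


def write_per_chrom(mat: np.ndarray, sample_ids: list, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"chr{c}" for c in range(1, 23)) + "\n")
        for sid, row in zip(sample_ids, mat):
            fh.write(sid + "\t" + "\t".join("NA" if not np.isfinite(v) else f"{v:.6g}" for v in row) + "\n")
    return path
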