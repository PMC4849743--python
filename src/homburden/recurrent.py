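"""Pooling of overlapping ROH segments into recurrent consensus regions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort import MISSING, GenotypeMatrix
from .snp_tests import chi2_2x2, truncate


@dataclass
class RecurrentPool:
    pool_id: int
    chrom: int
    consensus_start_bp: int
    consensus_end_bp: int
    members: list = field(default_factory=list)  # ROHSegment
    n_case_carriers: int = 0
    n_control_carriers: int = 0
    n_snps: int = -1  # genotyped SNPs inside the consensus; -1 if unchecked
    chi2: float = float("nan")
    p_carrier: float = float("nan")
    p_carrier_perm: float = float("nan")
    p_homozygosity_t: float = float("nan")

    @property
    def consensus_kb(self) -> float:
        return (self.consensus_end_bp - self.consensus_start_bp) / 1000.0

    @property
    def carrier_ids(self) -> set:
        return {s.sample_id for s in self.members}


def _cluster_single_linkage(segments: list) -> list:
    """Single-linkage overlap clusters of 1-based inclusive intervals."""
    clusters = []
    for seg in sorted(segments, key=lambda s: (s.start_bp, s.end_bp)):
        if clusters and seg.start_bp <= clusters[-1][0]:
            clusters[-1][0] = max(clusters[-1][0], seg.end_bp)
            clusters[-1][1].append(seg)
        else:
            clusters.append([seg.end_bp, [seg]])
    return [c[1] for c in clusters]


def pool_rohs(
    segments: list,
    min_members: int = 6,
    min_consensus_kb: float = 500.0,
    gm: GenotypeMatrix | None = None,
    min_consensus_snps: int = 75,
) -> list:
    """Cluster segments per chromosome and keep recurrent consensus regions.

    Two segments link when their bp intervals intersect; the consensus is
    the intersection of every member interval.  A cluster is recurrent when
    it spans more than five distinct individuals (``min_members = 6``), the
    consensus is at least *min_consensus_kb* long, and — when a genotype
    matrix is supplied — the consensus covers at least *min_consensus_snps*
    genotyped markers.
    """
    pools: list = []
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    pid = 0
    for chrom in sorted(by_chrom):
        for members in _cluster_single_linkage(by_chrom[chrom]):
            start = max(s.start_bp for s in members)
            end = min(s.end_bp for s in members)
            if end < start:
                continue
            carriers = {s.sample_id for s in members}
            if len(carriers) < min_members:
                continue
            if (end - start) / 1000.0 < min_consensus_kb:
                continue
            n_snps = -1
            if gm is not None:
                inside = (gm.chroms == chrom) & (gm.positions >= start) & (gm.positions <= end)
                n_snps = int(inside.sum())
                if n_snps < min_consensus_snps:
                    continue
            pid += 1
            pools.append(
                RecurrentPool(
                    pool_id=pid,
                    chrom=chrom,
                    consensus_start_bp=int(start),
                    consensus_end_bp=int(end),
                    members=list(members),
                    n_snps=n_snps,
                )
            )
    return pools


def count_carriers(pool: RecurrentPool, case_ids: set) -> tuple:
    carriers = pool.carrier_ids
    n_case = sum(1 for cid in carriers if cid in case_ids)
    pool.n_case_carriers = n_case
    pool.n_control_carriers = len(carriers) - n_case
    return pool.n_case_carriers, pool.n_control_carriers


def carrier_chi2(
    case_carriers: int,
    control_carriers: int,
    n_cases: int,
    n_controls: int,
    n_perm: int = 0,
    seed: int | None = None,
) -> dict:
    """Uncorrected 2x2 chi-square of carrier status by case status.

    Optionally adds a label-permutation p-value (``n_perm`` shuffles of the
    case/control labels over carriers).  Zero total carriers is degenerate:
    ``chi2 = 0`` and flagged.
    """
    if case_carriers > n_cases or control_carriers > n_controls:
        raise ValueError("carrier counts cannot exceed group sizes")
    total = case_carriers + control_carriers
    if total == 0:
        return {"chi2": 0.0, "p": 1.0, "p_perm": float("nan"), "degenerate": True}
    chi2, p = chi2_2x2(
        float(case_carriers),
        float(n_cases - case_carriers),
        float(control_carriers),
        float(n_controls - control_carriers),
    )
    out = {"chi2": chi2, "p": p, "p_perm": float("nan"), "degenerate": not np.isfinite(chi2)}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        labels = np.zeros(n_cases + n_controls, dtype=bool)
        labels[:n_cases] = True
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            ca = int(perm[:total].sum())
            stat, _ = chi2_2x2(
                float(ca), float(n_cases - ca), float(total - ca), float(n_controls - total + ca)
            )
            if np.isfinite(stat) and np.isfinite(chi2) and stat >= chi2:
                count += 1
        out["p_perm"] = (1 + count) / (n_perm + 1)
    return out


def homozygosity_proportion_test(pool: RecurrentPool, gm: GenotypeMatrix) -> dict:
    """One-tailed Welch t-test on per-SNP homozygote proportions.

    For every genotyped SNP in the consensus region the homozygote
    proportion is computed among all cases and among all controls; the two
    per-SNP proportion vectors are compared with a one-tailed two-sample
    Welch t-test whose direction follows the carrier majority (more case
    carriers => H1: cases more homozygous).
    """
    inside = np.where(
        (gm.chroms == pool.chrom)
        & (gm.positions >= pool.consensus_start_bp)
        & (gm.positions <= pool.consensus_end_bp)
    )[0]
    if inside.size < 2:
        return {"t": float("nan"), "p": float("nan"), "direction": "undefined", "degenerate": True}
    case = gm.case_mask
    calls = gm.calls[:, inside]
    obs = calls != MISSING
    hom = ((calls == 0) | (calls == 2)) & obs

    def props(mask):
        n_obs = obs[mask].sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, hom[mask].sum(axis=0) / np.maximum(n_obs, 1), np.nan)

    pc, pco = props(case), props(~case)
    ok = np.isfinite(pc) & np.isfinite(pco)
    pc, pco = pc[ok], pco[ok]
    direction = "cases>controls" if pool.n_case_carriers >= pool.n_control_carriers else "cases<controls"
    alternative = "greater" if direction == "cases>controls" else "less"
    if pc.size < 2 or (pc.std() == 0 and pco.std() == 0):
        if pc.size >= 2 and np.allclose(pc, pco):
            return {"t": 0.0, "p": 0.5, "direction": direction, "degenerate": False}
        return {"t": float("nan"), "p": float("nan"), "direction": direction, "degenerate": True}
    t, p = stats.ttest_ind(pc, pco, equal_var=False, alternative=alternative)
    return {"t": float(t), "p": float(p), "direction": direction, "degenerate": False}


def analyze_pools(
    pools: list,
    gm: GenotypeMatrix,
    n_perm: int = 0,
    seed: int | None = None,
) -> list:
    """Fill carrier counts and all pool-level statistics in place."""
    case_ids = {s.id for s in gm.samples if s.is_case}
    n_cases = len(case_ids)
    n_controls = gm.n_samples - n_cases
    for k, pool in enumerate(pools):
        count_carriers(pool, case_ids)
        res = carrier_chi2(
            pool.n_case_carriers,
            pool.n_control_carriers,
            n_cases,
            n_controls,
            n_perm=n_perm,
            seed=None if seed is None else seed + k,
        )
        pool.chi2 = res["chi2"]
        pool.p_carrier = res["p"]
        pool.p_carrier_perm = res["p_perm"]
        pool.p_homozygosity_t = homozygosity_proportion_test(pool, gm)["p"]
    return pools


def write_pools(pools: list, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            "pool\tchrom\tstart\tend\tkb\tnsnp\tcase_carriers\tcontrol_carriers"
            "\tchi2\tp\tp_perm\tp_t\n"
        )
        for p in pools:
            fh.write(
                f"{p.pool_id}\t{p.chrom}\t{p.consensus_start_bp}\t{p.consensus_end_bp}"
                f"\t{p.consensus_kb:.3f}\t{p.n_snps}\t{p.n_case_carriers}"
                f"\t{p.n_control_carriers}\t{truncate(p.chi2, 2):.2f}\t{p.p_carrier:.4g}"
                f"\t{p.p_carrier_perm:.4g}\t{p.p_homozygosity_t:.4g}\n"
            )
    return path


def write_consensus_bed(pools: list, path) -> Path:
    """BED export of consensus regions (1-based inclusive -> 0-based half-open)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for p in pools:
            fh.write(f"chr{p.chrom}\t{p.consensus_start_bp - 1}\t{p.consensus_end_bp}\tpool{p.pool_id}\n")
    return path
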