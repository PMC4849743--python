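"""Windowed run-of-homozygosity (ROH) detection and length criteria.

The caller scans each individual/chromosome with sliding windows of
``window_snps`` consecutive SNPs.  A window is homozygous when it holds at
most ``window_het_max`` heterozygous and ``window_miss_max`` missing calls.
A SNP becomes run-eligible when the fraction of homozygous windows among the
windows containing it reaches ``snp_window_frac`` *or* it sits in at least
one fully homozygous window — the latter keeps the first/last SNPs of a true
homozygous tract, which only ever belong to a single all-homozygous window,
inside the emitted segment.  Maximal runs of eligible SNPs are split at
large inter-SNP gaps and then filtered on SNP count, length and density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class RohParams:
    window_snps: int = 50
    window_het_max: int = 0
    window_miss_max: int = 5
    snp_window_frac: float = 0.05
    min_snps: int = 75
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("window_snps and min_snps must be positive")
        if self.window_het_max < 0 or self.window_miss_max < 0:
            raise ValueError("window het/miss maxima must be >= 0")
        if min(self.snp_window_frac, self.min_kb, self.max_gap_kb, self.min_density_kb_per_snp) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    start_marker: str = ""
    end_marker: str = ""

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0

    def overlaps(self, other: "ROHSegment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def min_roh_snps(
    mean_het: float,
    n_snps: int,
    n_individuals: int,
    max_expected: float = 0.05,
) -> tuple:
    """Smallest run length L whose expected chance count falls below target.

    Returns ``(L, expected_count_at_L)`` where the expected number of
    length-L all-homozygous runs arising by chance across the whole data set
    is ``(1 - mean_het)^L * n_snps * n_individuals``.
    """
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean_het must be in (0, 1)")
    if max_expected <= 0:
        raise ValueError("max_expected must be positive")
    total = float(n_snps) * float(n_individuals)
    if total <= 0:
        raise ValueError("n_snps and n_individuals must be positive")
    # (1-h)^L * total < max_expected  =>  L > log(max_expected/total)/log(1-h)
    l_min = math.log(max_expected / total) / math.log(1.0 - mean_het)
    L = max(int(math.floor(l_min)) + 1, 1)
    while (1.0 - mean_het) ** L * total >= max_expected:  # guard fp edge
        L += 1
    return L, (1.0 - mean_het) ** L * total


def expected_chance_rohs(mean_het: float, L: int, n_snps: int, n_individuals: int) -> float:
    return (1.0 - mean_het) ** L * n_snps * n_individuals


def ld_tag_groups(gm: GenotypeMatrix, r2_threshold: float = 0.8, window_kb: float = 250.0):
    """Greedy left-to-right tagging of SNPs into LD groups.

    Scanning markers in map order per chromosome, a SNP joins the group of
    the nearest previous tag within *window_kb* whose composite genotype
    r-squared (over pairwise-complete calls) exceeds *r2_threshold*;
    otherwise it founds a new group and becomes a tag.  Returns
    ``(n_groups, assignment)`` with assignment aligned to ``gm.markers``.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    window_bp = window_kb * 1000.0
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    chroms = gm.chroms
    positions = gm.positions
    assignment = np.full(gm.n_markers, -1, dtype=np.int64)
    next_group = 0
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        tags: list = []  # (marker_index, group) in scan order
        for j in idx:
            joined = False
            for tj, grp in reversed(tags):
                if positions[j] - positions[tj] > window_bp:
                    break
                if _pairwise_r2(calls[:, tj], calls[:, j]) > r2_threshold:
                    assignment[j] = grp
                    joined = True
                    break
            if not joined:
                assignment[j] = next_group
                tags.append((j, next_group))
                next_group += 1
    return next_group, assignment


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def adjust_min_snps(L: int, n_snps: int, n_groups: int) -> int:
    """Scale the independent-call criterion L up for LD redundancy."""
    if n_groups <= 0:
        raise ValueError("n_groups must be positive")
    if n_groups > n_snps:
        raise ValueError("n_groups cannot exceed n_snps")
    return int(math.ceil(L * n_snps / n_groups))


def call_rohs(gm: GenotypeMatrix, params: RohParams | None = None) -> list:
    """Detect ROH segments for every individual; see module docstring.

    ``n_snps`` counts genotyped (non-missing) SNPs in the run; the bp span
    uses the first/last SNP positions of the run and ``length_kb = span/1000``.
    """
    params = params or RohParams()
    W = params.window_snps
    segments: list = []
    chroms = gm.chroms
    positions = gm.positions
    for c in sorted(np.unique(chroms)):
        idx = np.where(chroms == c)[0]
        m = idx.size
        if m < W:
            log.info("chrom %d: %d SNPs < window of %d; skipped", c, m, W)
            continue
        pos = positions[idx]
        gap_break = np.nonzero(np.diff(pos) > params.max_gap_kb * 1000.0)[0]
        sub = gm.calls[:, idx]
        het = (sub == 1).astype(np.int32)
        mis = (sub == MISSING).astype(np.int32)
        # rolling window counts via cumulative sums: shape (n, m - W + 1)
        het_c = np.concatenate([np.zeros((gm.n_samples, 1), np.int32), het.cumsum(axis=1)], axis=1)
        mis_c = np.concatenate([np.zeros((gm.n_samples, 1), np.int32), mis.cumsum(axis=1)], axis=1)
        het_w = het_c[:, W:] - het_c[:, :-W]
        mis_w = mis_c[:, W:] - mis_c[:, :-W]
        hom_w = (het_w <= params.window_het_max) & (mis_w <= params.window_miss_max)
        n_win = hom_w.shape[1]
        # per-SNP counts of (homozygous) windows containing it
        hom_cum = np.concatenate(
            [np.zeros((gm.n_samples, 1), np.int32), hom_w.cumsum(axis=1)], axis=1
        )
        snp_i = np.arange(m)
        lo = np.maximum(snp_i - W + 1, 0)
        hi = np.minimum(snp_i, n_win - 1)
        tot_cnt = (hi - lo + 1).astype(float)
        hom_cnt = hom_cum[:, hi + 1] - hom_cum[:, lo]
        eligible = (hom_cnt >= 1) | (hom_cnt / tot_cnt >= params.snp_window_frac)
        nonmiss = sub != MISSING
        for i in range(gm.n_samples):
            for s, e in _eligible_runs(eligible[i], gap_break):
                n_geno = int(nonmiss[i, s : e + 1].sum())
                seg = ROHSegment(
                    sample_id=gm.samples[i].id,
                    chrom=int(c),
                    start_bp=int(pos[s]),
                    end_bp=int(pos[e]),
                    n_snps=n_geno,
                    start_marker=gm.markers[idx[s]].id,
                    end_marker=gm.markers[idx[e]].id,
                )
                if (
                    n_geno >= params.min_snps
                    and seg.length_kb >= params.min_kb
                    and seg.length_kb / n_geno <= params.min_density_kb_per_snp
                ):
                    segments.append(seg)
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return segments


def _eligible_runs(eligible: np.ndarray, gap_break: np.ndarray):
    """Maximal runs of True, split wherever a gap break falls inside a run."""
    padded = np.concatenate([[False], eligible, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0] - 1
    for s, e in zip(starts, ends):
        cut = s
        for g in gap_break[(gap_break >= s) & (gap_break < e)]:
            yield cut, int(g)
            cut = int(g) + 1
        yield cut, int(e)


def write_segments(segments: list, path) -> Path:
    """TSV mirroring the .hom layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tsnp1\tsnp2\tpos1\tpos2\tkb\tnsnp\tdensity\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start_marker}\t{s.end_marker}"
                f"\t{s.start_bp}\t{s.end_bp}\t{s.length_kb:.3f}\t{s.n_snps}"
                f"\t{s.length_kb / s.n_snps:.3f}\n"
            )
    return path


def read_segments(path) -> list:
    segs = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        segs.append(
            ROHSegment(
                sample_id=f[0],
                chrom=int(f[1]),
                start_marker=f[2],
                end_marker=f[3],
                start_bp=int(f[4]),
                end_bp=int(f[5]),
                n_snps=int(f[7]),
            )
        )
    return segs
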