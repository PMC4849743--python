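"""Synthetic case-control cohort generator with known inbreeding ground truth.

Genotypes follow the inbreeding-inflated Hardy-Weinberg law for an individual
with inbreeding coefficient F at a SNP with allele-b frequency p:

    P(2) = p^2 + F p (1 - p)
    P(1) = 2 p (1 - p) (1 - F)
    P(0) = (1 - p)^2 + F p (1 - p)

Autozygous tracts of configurable length / SNP count can be planted on top,
missingness is applied last, and the exact ground truth (per-individual F,
planted tracts, disease-model parameters) is returned and written alongside
the PLINK files.  All randomness flows through a single seed: a fixed seed
yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cohort import (
    MISSING,
    GenomeLayout,
    GenotypeMatrix,
    Marker,
    Sample,
    compute_freqs,
    write_plink_binary,
    write_plink_text,
    write_sample_table,
)


class SimConfigError(ValueError):
    pass


@dataclass
class PlantedSegmentSpec:
    """Autozygous tracts to plant: *count* per individual of *group*."""

    group: str = "case"  # "case" | "control" | "all"
    count: int = 1
    length_kb: float = 1500.0
    length_kb_sd: float = 0.0
    min_snps: int = 75


@dataclass
class SimConfig:
    n_cases: int = 50
    n_controls: int = 50
    chrom_lengths_bp: tuple = field(default_factory=lambda: GenomeLayout.default().chrom_lengths_bp)
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    # (mean, sd) of per-individual F, clamped to [0, 1]
    f_case: tuple = (0.0, 0.0)
    f_control: tuple = (0.0, 0.0)
    planted_segments: list = field(default_factory=list)
    missing_rate: float = 0.0
    disease_model: str = "label_driven"  # | "logistic_on_f" | "recessive_locus"
    disease_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimConfigError("n_snps must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimConfigError("missing_rate must be in [0,1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise SimConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for mean, sd in (self.f_case, self.f_control):
            if not 0.0 <= mean <= 1.0 or sd < 0.0:
                raise SimConfigError("f model mean must be in [0,1], sd >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["planted_segments"] = [dataclasses.asdict(s) if not isinstance(s, dict) else s
                                 for s in self.planted_segments]
        return json.dumps(d, indent=2, default=list)


@dataclass
class TruthSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass
class SimTruth:
    sample_ids: list
    planted_f: np.ndarray
    segments: list
    disease_params: dict
    allele_freq: np.ndarray | None = None  # true per-SNP allele-b frequency

    def segments_of(self, sample_id: str) -> list:
        return [t for t in self.segments if t.sample_id == sample_id]

    def write_tsv(self, path) -> Path:
        path = Path(path)
        per_sample = {sid: [] for sid in self.sample_ids}
        for t in self.segments:
            per_sample[t.sample_id].append(t)
        with open(path, "w") as fh:
            fh.write("sample_id\tplanted_f\tn_tracts\ttotal_tract_kb\n")
            for sid, f in zip(self.sample_ids, self.planted_f):
                tr = per_sample[sid]
                fh.write(f"{sid}\t{f:.6g}\t{len(tr)}\t{sum(t.length_kb for t in tr):.3f}\n")
        return path


def _draw_positions(rng, length_bp: int, count: int) -> np.ndarray:
    """Sorted, strictly increasing 1-based positions uniform on a chromosome."""
    pos = np.empty(0, dtype=np.int64)
    while pos.size < count:
        draw = rng.integers(1, length_bp + 1, size=2 * (count - pos.size) + 8)
        pos = np.unique(np.concatenate([pos, draw]))
    return np.sort(rng.choice(pos, size=count, replace=False))


def _sample_genotypes(rng, p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Draw the n x m call matrix from the stated trinomial law."""
    f = f[:, None]
    pq = (p * (1.0 - p))[None, :]
    p0 = (1.0 - p[None, :]) ** 2 + f * pq
    p1 = 2.0 * pq * (1.0 - f)
    u = rng.random((f.shape[0], p.size))
    return ((u >= p0).astype(np.int8) + (u >= p0 + p1)).astype(np.int8)


def _merge_intervals(iv: list) -> list:
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def simulate_cohort(cfg: SimConfig, out_dir=None, fmt: str = "text"):
    """Generate a cohort; returns ``(GenotypeMatrix, SimTruth)`` and, when
    *out_dir* is given, writes PLINK files, the truth TSV, the sample table
    and a JSON echo of the config."""
    rng = np.random.default_rng(cfg.seed)
    lengths = np.asarray(cfg.chrom_lengths_bp, dtype=np.int64)
    n_chrom = lengths.size
    n = cfg.n_cases + cfg.n_controls

    # --- markers ----------------------------------------------------------
    per_chrom = np.maximum(
        np.round(lengths / lengths.sum() * cfg.n_snps).astype(int), 1
    )
    while per_chrom.sum() != cfg.n_snps:  # fix rounding drift on largest chrom
        per_chrom[int(np.argmax(per_chrom))] += int(np.sign(cfg.n_snps - per_chrom.sum()))
    markers, chrom_slices = [], {}
    idx = 0
    for c in range(1, n_chrom + 1):
        k = int(per_chrom[c - 1])
        pos = _draw_positions(rng, int(lengths[c - 1]), k)
        for j, pb in enumerate(pos):
            markers.append(Marker(id=f"rs{c}_{j + 1}", chrom=c, pos_bp=int(pb)))
        chrom_slices[c] = slice(idx, idx + k)
        idx += k
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)

    # --- inbreeding + genotypes ------------------------------------------
    if cfg.disease_model == "label_driven":
        status = np.array([True] * cfg.n_cases + [False] * cfg.n_controls)
        f = np.where(
            status,
            rng.normal(cfg.f_case[0], cfg.f_case[1], size=n),
            rng.normal(cfg.f_control[0], cfg.f_control[1], size=n),
        )
        f = np.clip(f, 0.0, 1.0)
        calls = _sample_genotypes(rng, p, f)
    else:
        f = np.clip(rng.normal(cfg.f_control[0], cfg.f_control[1], size=n), 0.0, 1.0)
        calls = _sample_genotypes(rng, p, f)
        if cfg.disease_model == "logistic_on_f":
            b0 = float(cfg.disease_params.get("beta0", 0.0))
            bf = float(cfg.disease_params.get("beta_f", 0.0))
            status = rng.random(n) < expit(b0 + bf * f)
        elif cfg.disease_model == "recessive_locus":
            mi = int(cfg.disease_params.get("marker_index", 0))
            pen = cfg.disease_params.get("penetrances", (0.1, 0.1, 0.8))
            g = np.clip(calls[:, mi], 0, 2)
            status = rng.random(n) < np.asarray(pen, dtype=float)[g]
        else:
            raise SimConfigError(f"unknown disease_model {cfg.disease_model!r}")

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    histology = rng.choice(["mixed", "nodular_sclerosis", "undefined"], size=n)
    age_group = rng.choice(["lt42", "ge42"], size=n)
    mono = rng.choice(["positive", "negative", "unknown"], size=n)

    # --- planted tracts ---------------------------------------------------
    positions = np.array([mk.pos_bp for mk in markers], dtype=np.int64)
    chrom_of = np.array([mk.chrom for mk in markers], dtype=np.int16)
    planted: dict = {}
    specs = [
        PlantedSegmentSpec(**s) if isinstance(s, dict) else s for s in cfg.planted_segments
    ]
    for spec in specs:
        if spec.group == "case":
            targets = np.where(status)[0]
        elif spec.group == "control":
            targets = np.where(~status)[0]
        elif spec.group == "all":
            targets = np.arange(n)
        else:
            raise SimConfigError(f"unknown planted-segment group {spec.group!r}")
        for i in targets:
            for _ in range(spec.count):
                planted.setdefault(i, []).append(
                    _place_tract(rng, spec, lengths, positions, chrom_of, chrom_slices)
                )

    truth_segments = []
    for i, tracts in sorted(planted.items()):
        by_chrom: dict = {}
        for chrom, s, e in tracts:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, iv in by_chrom.items():
            for s, e in _merge_intervals(iv):
                sl = chrom_slices[chrom]
                inside = np.where((positions[sl] >= s) & (positions[sl] <= e))[0] + sl.start
                hom_b = rng.random(inside.size) < p[inside]
                calls[i, inside] = np.where(hom_b, 2, 0).astype(np.int8)
                truth_segments.append(
                    TruthSegment(
                        sample_id=sample_ids[i],
                        chrom=int(chrom),
                        start_bp=int(positions[inside[0]]),
                        end_bp=int(positions[inside[-1]]),
                        n_snps=int(inside.size),
                    )
                )

    # --- missingness (last) ----------------------------------------------
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    samples = [
        Sample(
            id=sample_ids[i],
            sex=str(sexes[i]),
            status="case" if status[i] else "control",
            subgroup_labels={
                "histology": str(histology[i]),
                "age_group": str(age_group[i]),
                "mononucleosis": str(mono[i]),
            },
        )
        for i in range(n)
    ]
    gm = GenotypeMatrix(samples, markers, calls)
    compute_freqs(gm)
    truth = SimTruth(
        sample_ids=sample_ids,
        planted_f=f,
        segments=truth_segments,
        disease_params={"model": cfg.disease_model, **cfg.disease_params},
        allele_freq=p,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = out_dir / "cohort"
        if fmt == "text":
            write_plink_text(gm, prefix)
        elif fmt == "binary":
            write_plink_binary(gm, prefix)
        else:
            raise SimConfigError(f"unknown output format {fmt!r}")
        truth.write_tsv(out_dir / "truth.tsv")
        write_sample_table(gm, out_dir / "samples.tsv")
        (out_dir / "sim_config.json").write_text(cfg.to_json())
    return gm, truth


def _place_tract(rng, spec: PlantedSegmentSpec, lengths, positions, chrom_of, chrom_slices):
    """Pick (chrom, start_bp, end_bp) for one tract; retries until the span
    holds at least ``spec.min_snps`` markers."""
    length_bp = max(int(round((spec.length_kb + rng.normal(0, spec.length_kb_sd)) * 1000)), 1000)
    eligible = np.where(lengths > length_bp + 2000)[0]
    if eligible.size == 0:
        raise SimConfigError(
            f"planted tract of {length_bp / 1000:.0f} kb exceeds every chromosome"
        )
    for _ in range(200):
        c = int(rng.choice(eligible)) + 1
        start = int(rng.integers(1000, lengths[c - 1] - length_bp - 1000))
        end = start + length_bp
        sl = chrom_slices[c]
        k = int(((positions[sl] >= start) & (positions[sl] <= end)).sum())
        if k >= spec.min_snps:
            return c, start, end
    raise SimConfigError(
        f"could not place a {length_bp / 1000:.0f} kb tract holding >= {spec.min_snps} SNPs; "
        "increase SNP density"
    )


# ---------------------------------------------------------------------------
# Canned fixtures
# ---------------------------------------------------------------------------

def _fixture_null_cohort() -> SimConfig:
    return SimConfig(n_cases=25, n_controls=25, n_snps=500, seed=101)


def _fixture_inbred_cases() -> SimConfig:
    return SimConfig(
        n_cases=25, n_controls=25, n_snps=500, f_case=(0.05, 0.01), seed=202
    )


def _fixture_clean_roh() -> SimConfig:
    # dense panel on a short genome so 1,500 kb tracts hold >= 100 SNPs
    lengths = (2_500_000, 2_500_000)
    return SimConfig(
        n_cases=10,
        n_controls=10,
        chrom_lengths_bp=lengths,
        n_snps=500,
        planted_segments=[PlantedSegmentSpec(group="case", count=1, length_kb=1500.0, min_snps=100)],
        seed=303,
    )


FIXTURES = {
    "null_cohort": _fixture_null_cohort,
    "inbred_cases": _fixture_inbred_cases,
    "clean_roh": _fixture_clean_roh,
}


def make_fixture(name: str, out_dir=None, fmt: str = "text"):
    """Deterministic tiny cohorts for tests; see :data:`FIXTURES`."""
    try:
        cfg = FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None
    return simulate_cohort(cfg, out_dir=out_dir, fmt=fmt)
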