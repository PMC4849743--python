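"""Core cohort data model and PLINK 1 text/binary I/O.

Genotypes are stored as an ``n_samples x n_markers`` int8 matrix counting
copies of allele *b* (the second allele column of a BIM/extended MAP file);
missing calls are coded :data:`MISSING`.  Coordinates are 1-based inclusive
base pairs, markers sorted by (chromosome, position), autosomes 1-22 only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

MISSING: int = -1

#: Total SNP-mappable autosomal genome length (bp), excluding centromeres.
DEFAULT_L_AUTO: int = 2_676_172_944

# hg18 / build-36 autosome lengths used only to apportion the mappable total.
_B36_AUTOSOME_BP = (
    247_249_719, 242_951_149, 199_501_827, 191_273_063, 180_857_866,
    170_899_992, 158_821_424, 146_274_826, 140_273_252, 135_374_737,
    134_452_384, 132_349_534, 114_142_980, 106_368_585, 100_338_915,
    88_827_254, 78_774_742, 76_117_153, 63_811_651, 62_435_964,
    46_944_323, 49_691_432,
)

_SEX_TO_CODE = {"unknown": 0, "male": 1, "female": 2}
_CODE_TO_SEX = {v: k for k, v in _SEX_TO_CODE.items()}


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK input."""


@dataclass
class Marker:
    """A biallelic autosomal SNP."""

    id: str
    chrom: int
    pos_bp: int
    allele_a: str = "A"
    allele_b: str = "B"
    freq_b: float = math.nan

    def __post_init__(self) -> None:
        if not 1 <= self.chrom <= 22:
            raise ValueError(f"marker {self.id}: chrom {self.chrom} not in 1..22")
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1")


@dataclass
class Sample:
    """One genotyped individual with phenotype and subgroup labels."""

    id: str
    sex: str = "unknown"
    status: str = "control"
    subgroup_labels: dict = field(default_factory=dict)
    missing_rate: float = math.nan

    def __post_init__(self) -> None:
        if self.sex not in _SEX_TO_CODE:
            raise ValueError(f"sample {self.id}: bad sex {self.sex!r}")
        if self.status not in ("case", "control"):
            raise ValueError(f"sample {self.id}: bad status {self.status!r}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class GenomeLayout:
    """Per-autosome mappable lengths in bp (index 0 = chromosome 1)."""

    chrom_lengths_bp: tuple

    def __post_init__(self) -> None:
        self.chrom_lengths_bp = tuple(int(x) for x in self.chrom_lengths_bp)
        if not 1 <= len(self.chrom_lengths_bp) <= 22:
            raise ValueError("expected 1..22 autosome lengths")
        if self.total_autosomal_bp <= 0:
            raise ValueError("total autosomal length must be positive")

    @property
    def total_autosomal_bp(self) -> int:
        return sum(self.chrom_lengths_bp)

    def length_of(self, chrom: int) -> int:
        return self.chrom_lengths_bp[chrom - 1]

    @classmethod
    def default(cls, total_bp: int = DEFAULT_L_AUTO) -> "GenomeLayout":
        """Build-36-proportional layout rescaled so lengths sum to *total_bp*."""
        raw = np.asarray(_B36_AUTOSOME_BP, dtype=float)
        scaled = np.floor(raw * (total_bp / raw.sum())).astype(np.int64)
        scaled[-1] += total_bp - scaled.sum()
        return cls(tuple(int(x) for x in scaled))


class GenotypeMatrix:
    """Samples x markers diploid genotypes counting copies of allele b."""

    def __init__(self, samples, markers, calls, validate: bool = True):
        self.samples: list = list(samples)
        self.markers: list = list(markers)
        self.calls: np.ndarray = np.asarray(calls, dtype=np.int8)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,missing}")
        key = [(mk.chrom, mk.pos_bp) for mk in self.markers]
        if key != sorted(key):
            raise ValueError("markers must be sorted by (chrom, pos_bp)")
        for c in range(1, 23):
            pos = [mk.pos_bp for mk in self.markers if mk.chrom == c]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"chrom {c}: positions not strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.is_case for s in self.samples], dtype=bool)

    @property
    def positions(self) -> np.ndarray:
        return np.array([mk.pos_bp for mk in self.markers], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([mk.chrom for mk in self.markers], dtype=np.int16)

    @property
    def freqs(self) -> np.ndarray:
        return np.array([mk.freq_b for mk in self.markers], dtype=float)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        markers = [self.markers[i] for i in np.atleast_1d(index)]
        return GenotypeMatrix(self.samples, markers, self.calls[:, index])

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        samples = [self.samples[i] for i in np.atleast_1d(index)]
        return GenotypeMatrix(samples, self.markers, self.calls[index, :])


# ---------------------------------------------------------------------------
# Frequencies / missingness
# ---------------------------------------------------------------------------

def compute_freqs(gm: GenotypeMatrix):
    """Recompute per-marker allele-b frequency and per-sample missing rate.

    Missing calls are excluded from the allele count.  Markers where every
    call is missing get ``freq_b = nan`` (callers should exclude them
    downstream).  Results are cached on the Marker/Sample objects and also
    returned as ``(freq_b, missing_rate)`` arrays.
    """
    calls = gm.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    ssum = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, ssum / (2.0 * np.maximum(n_obs, 1)), np.nan)
    freq[n_obs == 0] = np.nan
    miss_rate = (~obs).sum(axis=1) / max(gm.n_markers, 1)
    for mk, f in zip(gm.markers, freq):
        mk.freq_b = float(f)
    for s, r in zip(gm.samples, miss_rate):
        s.missing_rate = float(r)
    return freq, miss_rate


def apply_maf_filter(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop markers whose minor allele frequency is not > *maf_min*.

    Markers with undefined frequency (all calls missing) are also dropped.
    """
    freq, _ = compute_freqs(gm)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(np.isfinite(maf) & (maf > maf_min))[0]
    dropped = gm.n_markers - keep.size
    if dropped:
        log.info("MAF filter (>%g): dropped %d of %d markers", maf_min, dropped, gm.n_markers)
    return gm.subset_markers(keep)


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def _parse_map(map_path) -> tuple:
    """Parse MAP rows; returns (kept_markers, keep_flags_per_row).

    Accepts the standard 4-column layout and an extended 6-column layout
    carrying allele_a/allele_b (which this package's writer emits so that
    text round-trips are exact).  Non-autosomal rows are skipped.
    """
    markers, keep = [], []
    n_skipped = 0
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (4, 6):
            raise PlinkFormatError(f"{map_path}: line {ln}: expected 4 or 6 columns")
        try:
            chrom = int(parts[0])
        except ValueError:
            chrom = -1
        if not 1 <= chrom <= 22:
            n_skipped += 1
            keep.append(False)
            continue
        a, b = (parts[4], parts[5]) if len(parts) == 6 else (None, None)
        markers.append((chrom, parts[1], int(parts[3]), a, b))
        keep.append(True)
    if n_skipped:
        log.warning("%s: skipped %d non-autosomal markers", map_path, n_skipped)
    return markers, np.asarray(keep, dtype=bool)


def _infer_alleles(col_a: np.ndarray, col_b: np.ndarray):
    """Allele labels in order of first observation within a genotype column."""
    seq = np.empty(col_a.size * 2, dtype=col_a.dtype)
    seq[0::2] = col_a
    seq[1::2] = col_b
    seen = seq[seq != "0"]
    if seen.size == 0:
        return "0", "0"
    first = seen[0]
    rest = seen[seen != first]
    second = rest[0] if rest.size else "0"
    return str(first), str(second)


def read_plink_text(ped_path, map_path, maf_min: float | None = None) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Calls count copies of allele b.  With a 4-column MAP, allele b is the
    second distinct allele observed for the marker (first-observed is allele
    a); the extended 6-column MAP written by :func:`write_plink_text` makes
    the assignment explicit.  ``0 0`` (or half-missing) pairs become missing.
    Phenotype 2 maps to case, anything else to control.
    """
    raw_markers, keep = _parse_map(map_path)
    m_total = keep.size
    samples, rows = [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6 + 2 * m_total:
            raise PlinkFormatError(
                f"{ped_path}: line {ln}: expected {6 + 2 * m_total} fields "
                f"({m_total} markers), got {len(parts)}"
            )
        sex = _CODE_TO_SEX.get(int(parts[4]) if parts[4].isdigit() else 0, "unknown")
        status = "case" if parts[5] == "2" else "control"
        samples.append(Sample(id=parts[1], sex=sex, status=status))
        rows.append(np.array(parts[6:], dtype="U8"))
    n = len(samples)
    geno = (
        np.stack(rows).reshape(n, m_total, 2)[:, keep, :]
        if n
        else np.empty((0, int(keep.sum()), 2), dtype="U8")
    )
    markers, calls = [], np.full((n, len(raw_markers)), MISSING, dtype=np.int8)
    for j, (chrom, mid, pos, a, b) in enumerate(raw_markers):
        col_a, col_b = geno[:, j, 0], geno[:, j, 1]
        if a is None:
            a, b = _infer_alleles(col_a, col_b)
        alleles = set(np.unique(np.concatenate([col_a, col_b]))) - {"0"}
        if not alleles <= {a, b} - {"0"} and not alleles <= {a, b}:
            raise PlinkFormatError(f"marker {mid}: more than two alleles observed")
        miss = (col_a == "0") | (col_b == "0")
        calls[:, j] = np.where(miss, MISSING, (col_a == b).astype(np.int8) + (col_b == b))
        markers.append(Marker(id=mid, chrom=chrom, pos_bp=pos, allele_a=a, allele_b=b))
    gm = GenotypeMatrix(samples, markers, calls)
    compute_freqs(gm)
    return gm if maf_min is None else apply_maf_filter(gm, maf_min)


def write_plink_text(gm: GenotypeMatrix, prefix) -> tuple:
    """Write ``prefix.ped`` / ``prefix.map`` (extended 6-column MAP)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for mk in gm.markers:
            fh.write(f"{mk.chrom}\t{mk.id}\t0\t{mk.pos_bp}\t{mk.allele_a}\t{mk.allele_b}\n")
    geno_strs = np.empty((gm.n_markers, 4), dtype=object)
    for j, mk in enumerate(gm.markers):
        geno_strs[j] = [
            f"{mk.allele_a} {mk.allele_a}",
            f"{mk.allele_a} {mk.allele_b}",
            f"{mk.allele_b} {mk.allele_b}",
            "0 0",
        ]
    with open(ped_path, "w") as fh:
        for i, s in enumerate(gm.samples):
            lead = f"FAM{i + 1} {s.id} 0 0 {_SEX_TO_CODE[s.sex]} {2 if s.is_case else 1}"
            row = gm.calls[i]
            cells = [geno_strs[j][row[j] if row[j] != MISSING else 3] for j in range(gm.n_markers)]
            fh.write(" ".join([lead, *cells]).rstrip() + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM, SNP-major)
# ---------------------------------------------------------------------------

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit PLINK code -> call: 00 hom a1, 01 missing, 10 het, 11 hom a2
_DECODE_2BIT = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BYTE_TABLE = np.zeros((256, 4), dtype=np.int8)
for _byte in range(256):
    for _i in range(4):
        _BYTE_TABLE[_byte, _i] = _DECODE_2BIT[(_byte >> (2 * _i)) & 0b11]

_ENCODE_CALL = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


def read_plink_binary(bed_path, bim_path, fam_path, maf_min: float | None = None) -> GenotypeMatrix:
    """Read a BED/BIM/FAM trio (SNP-major) into a :class:`GenotypeMatrix`."""
    samples = []
    for ln, line in enumerate(Path(fam_path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 6:
            raise PlinkFormatError(f"{fam_path}: line {ln}: expected 6 columns")
        sex = _CODE_TO_SEX.get(int(parts[4]) if parts[4].lstrip("-").isdigit() else 0, "unknown")
        samples.append(
            Sample(id=parts[1], sex=sex, status="case" if parts[5] == "2" else "control")
        )
    raw_markers, keep = [], []
    n_skipped = 0
    for ln, line in enumerate(Path(bim_path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise PlinkFormatError(f"{bim_path}: line {ln}: expected 6 columns")
        try:
            chrom = int(parts[0])
        except ValueError:
            chrom = -1
        if not 1 <= chrom <= 22:
            n_skipped += 1
            keep.append(False)
            continue
        raw_markers.append(
            Marker(id=parts[1], chrom=chrom, pos_bp=int(parts[3]), allele_a=parts[4], allele_b=parts[5])
        )
        keep.append(True)
    if n_skipped:
        log.warning("%s: skipped %d non-autosomal markers", bim_path, n_skipped)
    keep = np.asarray(keep, dtype=bool)
    n, m_total = len(samples), keep.size

    data = Path(bed_path).read_bytes()
    if data[:2] != _MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK 1 BED file)")
    if data[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m_total
    if len(data) != expected:
        raise PlinkFormatError(
            f"{bed_path}: expected {expected} bytes for {n} samples x {m_total} SNPs, "
            f"got {len(data)}"
        )
    body = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m_total, bytes_per_snp)
    decoded = _BYTE_TABLE[body].reshape(m_total, bytes_per_snp * 4)[:, :n]  # (m, n)
    calls = decoded[keep].T.copy()
    gm = GenotypeMatrix(samples, raw_markers, calls)
    compute_freqs(gm)
    return gm if maf_min is None else apply_maf_filter(gm, maf_min)


def write_plink_binary(gm: GenotypeMatrix, prefix) -> tuple:
    """Write ``prefix.bed/.bim/.fam`` (SNP-major, deterministic bytes)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    with open(fam_path, "w") as fh:
        for i, s in enumerate(gm.samples):
            fh.write(f"FAM{i + 1}\t{s.id}\t0\t0\t{_SEX_TO_CODE[s.sex]}\t{2 if s.is_case else 1}\n")
    with open(bim_path, "w") as fh:
        for mk in gm.markers:
            fh.write(f"{mk.chrom}\t{mk.id}\t0\t{mk.pos_bp}\t{mk.allele_a}\t{mk.allele_b}\n")
    n, m = gm.n_samples, gm.n_markers
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((n,), dtype=np.uint8)
    out = bytearray(_MAGIC + _SNP_MAJOR)
    lut = np.zeros(256, dtype=np.uint8)
    for call, code in _ENCODE_CALL.items():
        lut[np.uint8(np.int8(call))] = code
    for j in range(m):
        codes[:] = lut[gm.calls[:, j].astype(np.uint8)]
        padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
        # pad slots beyond n are 00 (hom a1) per the PLINK convention
        padded[:n] = codes
        quads = padded.reshape(bytes_per_snp, 4)
        packed = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
        out.extend(packed.tobytes())
    bed_path.write_bytes(bytes(out))
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Sample covariate table
# ---------------------------------------------------------------------------

_TABLE_COLS = ("id", "sex", "status", "histology", "age_group", "mononucleosis")


def write_sample_table(gm: GenotypeMatrix, path) -> Path:
    """TSV with header (id, sex, status, histology, age_group, mononucleosis)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLS) + "\n")
        for s in gm.samples:
            labels = s.subgroup_labels
            fh.write(
                "\t".join(
                    [
                        s.id,
                        s.sex,
                        s.status,
                        str(labels.get("histology", "undefined")),
                        str(labels.get("age_group", "lt42")),
                        str(labels.get("mononucleosis", "unknown")),
                    ]
                )
                + "\n"
            )
    return path


def read_sample_table(path) -> dict:
    """Parse the covariate TSV into {sample_id: {column: value}}."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        out[row["id"]] = row
    return out
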