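import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homburden.cohort import (
    GenomeLayout,
    GenotypeMatrix,
    Marker,
    MISSING,
    PlinkFormatError,
    Sample,
    apply_maf_filter,
    compute_freqs,
    read_plink_binary,
    read_plink_text,
    write_plink_binary,
    write_plink_text,
)

from conftest import build_gm


# ---------------------------------------------------------------------- types

def test_marker_rejects_non_autosome():
    with pytest.raises(ValueError):
        Marker(id="rsX", chrom=23, pos_bp=100)
    with pytest.raises(ValueError):
        Marker(id="rs0", chrom=1, pos_bp=0)


def test_matrix_requires_sorted_markers():
    markers = [Marker(id="a", chrom=1, pos_bp=200), Marker(id="b", chrom=1, pos_bp=100)]
    with pytest.raises(ValueError, match="sorted"):
        GenotypeMatrix([Sample(id="s")], markers, np.zeros((1, 2), dtype=np.int8))


def test_genome_layout_default_sums_to_l_auto():
    layout = GenomeLayout.default()
    assert layout.total_autosomal_bp == 2_676_172_944
    assert len(layout.chrom_lengths_bp) == 22
    assert all(x > 0 for x in layout.chrom_lengths_bp)


# ------------------------------------------------------------------ text I/O

def test_read_minimal_ped(tmp_path):
    (tmp_path / "x.map").write_text("1 rs1 0 1000\n")
    (tmp_path / "x.ped").write_text("FAM1 S1 0 0 1 2 A A\n")
    gm = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert gm.n_samples == 1 and gm.n_markers == 1
    assert gm.calls[0, 0] in (0, 2)  # hom for the single observed allele
    assert gm.samples[0].status == "case"
    assert gm.samples[0].sex == "male"


def test_zero_zero_is_missing(tmp_path):
    (tmp_path / "x.map").write_text("1 rs1 0 1000\n1 rs2 0 2000\n")
    (tmp_path / "x.ped").write_text("F S1 0 0 2 1 0 0 A G\nF S2 0 0 0 1 A A A A\n")
    gm = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert gm.calls[0, 0] == MISSING
    # rs2: first observed allele A -> allele_a, second distinct G -> allele_b
    assert gm.markers[1].allele_a == "A" and gm.markers[1].allele_b == "G"
    assert gm.calls[0, 1] == 1 and gm.calls[1, 1] == 0


def test_ragged_ped_row_errors_with_line(tmp_path):
    (tmp_path / "x.map").write_text("1 rs1 0 1000\n")
    (tmp_path / "x.ped").write_text("F S1 0 0 1 1 A A\nF S2 0 0 1 1 A\n")
    with pytest.raises(PlinkFormatError, match="line 2"):
        read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")


def test_non_autosomal_markers_dropped(tmp_path):
    (tmp_path / "x.map").write_text("1 rs1 0 1000\nX rs2 0 500\n23 rs3 0 600\n")
    (tmp_path / "x.ped").write_text("F S1 0 0 1 1 A A C C G G\n")
    gm = read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
    assert [m.id for m in gm.markers] == ["rs1"]


def test_text_round_trip_random_matrix(tmp_path, rng):
    calls = rng.integers(-1, 3, size=(5, 10)).astype(np.int8)
    gm = build_gm(calls)
    write_plink_text(gm, tmp_path / "rt")
    back = read_plink_text(tmp_path / "rt.ped", tmp_path / "rt.map")
    np.testing.assert_array_equal(back.calls, gm.calls)
    assert [s.status for s in back.samples] == [s.status for s in gm.samples]
    assert [(m.chrom, m.pos_bp) for m in back.markers] == [
        (m.chrom, m.pos_bp) for m in gm.markers
    ]


def test_write_empty_cohort(tmp_path):
    gm = GenotypeMatrix([], [Marker(id="rs1", chrom=1, pos_bp=5)], np.zeros((0, 1), np.int8))
    ped, mp = write_plink_text(gm, tmp_path / "e")
    assert ped.read_text() == ""
    assert len(mp.read_text().splitlines()) == 1
    back = read_plink_text(ped, mp)
    assert back.n_samples == 0 and back.n_markers == 1


# ---------------------------------------------------------------- binary I/O

def test_binary_round_trip(tmp_path, rng):
    calls = rng.integers(-1, 3, size=(7, 13)).astype(np.int8)
    gm = build_gm(calls)
    write_plink_binary(gm, tmp_path / "b")
    back = read_plink_binary(tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam")
    np.testing.assert_array_equal(back.calls, gm.calls)
    assert [s.id for s in back.samples] == [s.id for s in gm.samples]


def test_text_and_binary_readers_agree(tmp_path, rng):
    calls = rng.integers(-1, 3, size=(9, 21)).astype(np.int8)
    gm = build_gm(calls)
    write_plink_text(gm, tmp_path / "t")
    write_plink_binary(gm, tmp_path / "t")
    a = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
    b = read_plink_binary(tmp_path / "t.bed", tmp_path / "t.bim", tmp_path / "t.fam")
    np.testing.assert_array_equal(a.calls, b.calls)


def test_byte_ff_is_four_hom_a2(tmp_path):
    (tmp_path / "m.bim").write_text("1\trs1\t0\t1000\tA\tG\n")
    (tmp_path / "m.fam").write_text(
        "".join(f"F\tS{i}\t0\t0\t1\t1\n" for i in range(1, 5))
    )
    (tmp_path / "m.bed").write_bytes(b"\x6c\x1b\x01\xff")
    gm = read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
    np.testing.assert_array_equal(gm.calls[:, 0], [2, 2, 2, 2])


def test_binary_2bit_codes(tmp_path):
    # codes 00,01,10,11 for samples 1..4 -> byte 0b11100100 = 0xE4
    (tmp_path / "m.bim").write_text("1\trs1\t0\t1000\tA\tG\n")
    (tmp_path / "m.fam").write_text(
        "".join(f"F\tS{i}\t0\t0\t1\t1\n" for i in range(1, 5))
    )
    (tmp_path / "m.bed").write_bytes(b"\x6c\x1b\x01\xe4")
    gm = read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
    np.testing.assert_array_equal(gm.calls[:, 0], [0, MISSING, 1, 2])


def test_truncated_bed_names_expected_bytes(tmp_path):
    (tmp_path / "m.bim").write_text("1\trs1\t0\t1000\tA\tG\n1\trs2\t0\t2000\tA\tG\n")
    (tmp_path / "m.fam").write_text("F\tS1\t0\t0\t1\t1\n")
    (tmp_path / "m.bed").write_bytes(b"\x6c\x1b\x01\x00")  # 1 SNP byte, need 2
    with pytest.raises(PlinkFormatError, match="expected 5 bytes"):
        read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")


def test_bad_magic_and_mode(tmp_path):
    (tmp_path / "m.bim").write_text("1\trs1\t0\t1000\tA\tG\n")
    (tmp_path / "m.fam").write_text("F\tS1\t0\t0\t1\t1\n")
    (tmp_path / "m.bed").write_bytes(b"\x00\x00\x01\x00")
    with pytest.raises(PlinkFormatError, match="magic"):
        read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
    (tmp_path / "m.bed").write_bytes(b"\x6c\x1b\x00\x00")
    with pytest.raises(PlinkFormatError, match="SNP-major"):
        read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")


def test_binary_write_is_deterministic(tmp_path, rng):
    calls = rng.integers(-1, 3, size=(6, 11)).astype(np.int8)
    gm = build_gm(calls)
    write_plink_binary(gm, tmp_path / "a")
    write_plink_binary(gm, tmp_path / "b")
    assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


@settings(max_examples=25, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=9),
    m=st.integers(min_value=1, max_value=15),
    seed=st.integers(min_value=0, max_value=2**32 - 1),
)
def test_round_trip_property(tmp_path_factory, n, m, seed):
    rng = np.random.default_rng(seed)
    calls = rng.integers(-1, 3, size=(n, m)).astype(np.int8)
    gm = build_gm(calls)
    tmp = tmp_path_factory.mktemp("rt")
    write_plink_text(gm, tmp / "x")
    write_plink_binary(gm, tmp / "x")
    t = read_plink_text(tmp / "x.ped", tmp / "x.map")
    b = read_plink_binary(tmp / "x.bed", tmp / "x.bim", tmp / "x.fam")
    np.testing.assert_array_equal(t.calls, gm.calls)
    np.testing.assert_array_equal(b.calls, gm.calls)


# ------------------------------------------------------------------- freqs

def test_compute_freqs_basic():
    gm = build_gm(np.array([[0], [1], [2]]))
    freq, miss = compute_freqs(gm)
    assert freq[0] == pytest.approx(0.5)
    assert miss.tolist() == [0.0, 0.0, 0.0]


def test_all_missing_column_flagged():
    gm = build_gm(np.array([[MISSING, 1], [MISSING, 2]]))
    freq, _ = compute_freqs(gm)
    assert np.isnan(freq[0]) and np.isfinite(freq[1])
    filtered = apply_maf_filter(gm, 0.05)
    assert filtered.n_markers <= 1  # undefined-freq marker excluded


def test_freq_missing_excluded():
    gm = build_gm(np.array([[0], [2], [MISSING]]))
    freq, miss = compute_freqs(gm)
    assert freq[0] == pytest.approx(0.5)
    assert miss[2] == pytest.approx(1.0)


def test_freq_binomial_bound(rng):
    p = 0.3
    n = 1000
    calls = rng.binomial(2, p, size=(n, 1)).astype(np.int8)
    gm = build_gm(calls)
    freq, _ = compute_freqs(gm)
    assert abs(freq[0] - p) < 3 * np.sqrt(p * (1 - p) / (2 * n))


def test_freqs_invariant_to_sample_order(random_gm, rng):
    f0, m0 = compute_freqs(random_gm)
    perm = rng.permutation(random_gm.n_samples)
    shuffled = random_gm.subset_samples(perm)
    f1, m1 = compute_freqs(shuffled)
    np.testing.assert_allclose(f0, f1)
    np.testing.assert_allclose(m0[perm], m1)


def test_maf_filter_drops_rare():
    calls = np.zeros((20, 2), dtype=np.int8)
    calls[:10, 0] = 1  # freq 0.25
    calls[0, 1] = 1    # freq 0.025
    gm = build_gm(calls)
    filtered = apply_maf_filter(gm, 0.05)
    assert [m.id for m in filtered.markers] == ["rs1"]
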