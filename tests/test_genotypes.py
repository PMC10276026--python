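"""Genotype I/O, allele frequencies, quality control and imputation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gblupad import (
    GenotypeMatrix,
    QCReport,
    SimulationConfig,
    allele_frequency,
    impute_missing,
    qc_filter,
    read_genotypes,
    simulate_dataset,
    write_genotypes,
)


def _gm(columns: dict[str, list[float]]) -> GenotypeMatrix:
    df = pd.DataFrame(columns, dtype=float)
    df.index = [f"I{i}" for i in range(len(df))]
    return GenotypeMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy())


def test_csv_round_trip(tmp_path, small_dataset):
    path = tmp_path / "geno.csv"
    write_genotypes(small_dataset.genotypes, path)
    back = read_genotypes(path, dialect="csv")
    np.testing.assert_array_equal(back.dosages, small_dataset.genotypes.dosages)
    np.testing.assert_array_equal(back.individual_ids, small_dataset.genotypes.individual_ids)
    np.testing.assert_array_equal(back.marker_ids, small_dataset.genotypes.marker_ids)


def test_vcf_dialect(tmp_path):
    vcf = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\tm1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\tm2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\n"
        "1\t300\tm3\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n"
    )
    path = tmp_path / "panel.vcf"
    path.write_text(vcf)
    gm = read_genotypes(path, dialect="vcf")
    # multiallelic m3 skipped; missing ID falls back to chrom:pos
    assert list(gm.marker_ids) == ["m1", "m2", "1:400"]
    np.testing.assert_array_equal(gm.dosages[:, 0], [0, 1, 2])
    assert np.isnan(gm.dosages[0, 1]) and gm.dosages[1, 1] == 1
    np.testing.assert_array_equal(gm.dosages[:, 2], [2, 2, 1])


def test_missing_file_and_bad_cells(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_genotypes(tmp_path / "nope.csv")
    with pytest.raises(ValueError):
        _gm({"m1": [0, 3, 1]})  # dosage 3 out of range
    with pytest.raises(ValueError):
        _gm({"m1": [0, 0.5, 1]})  # fractional without imputed flag


@pytest.mark.parametrize(
    "column, expected",
    [([0, 1, 2], 0.5), ([0, 1, 2, 2], 0.625), ([2, 2, 2], 1.0)],
)
def test_allele_frequency_counting(column, expected):
    gm = _gm({"m1": column})
    assert allele_frequency(gm)[0] == pytest.approx(expected)


def test_allele_frequency_ignores_missing():
    gm = _gm({"m1": [0, 2, np.nan]})
    assert allele_frequency(gm)[0] == pytest.approx(0.5)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=3, max_size=12), st.randoms())
def test_allele_frequency_invariant_to_individual_order(column, rnd):
    gm = _gm({"m1": column})
    perm = list(range(len(column)))
    rnd.shuffle(perm)
    shuffled = GenotypeMatrix(
        gm.individual_ids[perm], gm.marker_ids, gm.dosages[perm]
    )
    assert allele_frequency(gm)[0] == allele_frequency(shuffled)[0]


def test_qc_call_rate_boundary_is_inclusive():
    # 8/10 calls fails the 90% threshold, 9/10 passes (>= is kept)
    col_8 = [0, 1, 2, 1, 0, 1, 2, 1, np.nan, np.nan]
    col_9 = [0, 1, 2, 1, 0, 1, 2, 1, 1, np.nan]
    gm = _gm({"m8": col_8, "m9": col_9})
    out, rep = qc_filter(gm, call_rate_min=0.90, maf_min=0.05)
    assert list(out.marker_ids) == ["m9"]
    assert rep.n_markers_in == 2 and rep.n_markers_out == 1


def test_qc_removes_monomorphic_markers():
    gm = _gm({"mono": [2, 2, 2, 2], "poly": [0, 1, 2, 1]})
    out, _ = qc_filter(gm)
    assert list(out.marker_ids) == ["poly"]


def test_qc_is_idempotent(small_dataset):
    once, rep1 = qc_filter(small_dataset.genotypes)
    twice, rep2 = qc_filter(once)
    np.testing.assert_array_equal(once.dosages, twice.dosages)
    assert rep2.n_markers_out == rep2.n_markers_in == rep1.n_markers_out


def test_percent_reduction_matches_reference_counts():
    # the reference panel: 44,457 markers in, 8,112 out
    rep = QCReport(n_markers_in=44_457, n_markers_out=8_112,
                   call_rate_min=0.9, maf_min=0.05)
    assert rep.percent_reduction == pytest.approx(81.75, abs=0.005)


def test_percent_reduction_consistent_with_counts(small_dataset):
    _, rep = qc_filter(small_dataset.genotypes)
    expected = 100.0 * (1 - rep.n_markers_out / rep.n_markers_in)
    assert rep.percent_reduction == pytest.approx(expected, abs=1e-10)


def test_impute_mean_dosage():
    gm = _gm({"m1": [0, 2, np.nan]})
    out = impute_missing(gm)
    np.testing.assert_allclose(out.dosages[:, 0], [0, 2, 1.0])


def test_impute_is_identity_without_missing():
    gm = _gm({"m1": [0, 1, 2]})
    np.testing.assert_array_equal(impute_missing(gm).dosages, gm.dosages)


def test_impute_leaves_no_missing(small_dataset):
    post, _ = qc_filter(small_dataset.genotypes)
    out = impute_missing(post)
    assert out.n_missing == 0
    observed = ~np.isnan(post.dosages)
    np.testing.assert_array_equal(out.dosages[observed], post.dosages[observed])


def test_impute_undefined_frequency_errors():
    gm = _gm({"m1": [np.nan, np.nan, np.nan]})
    with pytest.raises(ValueError, match="undefined frequency"):
        impute_missing(gm)
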