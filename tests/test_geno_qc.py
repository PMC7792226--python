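"""Genotype I/O, QC filtering, allele frequencies, concordance."""

import numpy as np
import pytest

from xfert import geno_qc, landrace
from xfert.geno_qc import (GenotypeMatrix, MarkerPanel, allele_frequency,
                           concordance_table, qc_filter)


def small_matrix():
    """6 samples (2 boars) x 4 markers (2 autosomal, 2 X), with missing."""
    panel = MarkerPanel(
        ids=["m1", "m2", "x1", "x2"],
        chrom=["1", "1", "X", "X"],
        pos=[100, 200, 150, 900],
        ref=["A", "C", "C", "G"],
        alt=["G", "T", "T", "T"],
    )
    codes = np.array([
        [0, 1, 0, 2],
        [2, 0, 2, 0],     # boar: X codes in {0, 2}
        [1, -1, 1, 1],
        [0, 2, 0, 2],
        [1, 1, 2, -1],
        [2, 0, 0, 0],
    ], dtype=np.int8)
    sex = np.array(["M", "M", "F", "F", "F", "F"])
    samples = [f"s{i}" for i in range(6)]
    return GenotypeMatrix(samples, sex, panel, codes)


# ---------------------------------------------------------------------------
# I/O round-trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["vcf", "ped"])
def test_write_read_round_trip_preserves_codes_and_panel(tmp_path, fmt):
    gm = small_matrix()
    path = str(tmp_path / ("geno.vcf" if fmt == "vcf" else "geno"))
    geno_qc.write_genotypes(gm, path, fmt)
    back = geno_qc.read_genotypes(
        path if fmt == "vcf" else path + ".ped",
        sex={s: x for s, x in zip(gm.samples, gm.sex)})
    assert back.samples == gm.samples
    assert np.array_equal(back.codes, gm.codes)
    assert list(back.panel.ids) == list(gm.panel.ids)
    assert np.array_equal(back.panel.pos, gm.panel.pos)
    assert list(back.sex) == list(gm.sex)


def test_empty_sample_set_round_trips_to_empty_matrix(tmp_path):
    gm = small_matrix()
    empty = gm.subset_samples([])
    path = str(tmp_path / "empty.vcf")
    geno_qc.write_vcf(empty, path)
    back = geno_qc.read_vcf(path)
    assert back.n_samples == 0
    assert back.panel.n_markers == 4


def test_half_missing_vcf_genotype_counts_as_missing_call(tmp_path):
    vcf = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/1\t./1\t1/1
1\t200\tsnp2\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t./.
"""
    path = tmp_path / "half.vcf"
    path.write_text(vcf)
    gm = geno_qc.read_vcf(str(path))
    # snp1: one half-missing of three -> call rate 2/3
    assert np.allclose(gm.call_rate(), [2 / 3, 2 / 3])
    assert gm.codes[1, 0] == geno_qc.MISSING


def test_duplicate_sample_ids_rejected():
    gm = small_matrix()
    with pytest.raises(geno_qc.GenotypeError, match="duplicated"):
        GenotypeMatrix(["a"] * 6, gm.sex, gm.panel, gm.codes)


def test_male_het_on_x_violates_dialect():
    gm = small_matrix()
    codes = gm.codes.copy()
    codes[0, 2] = 1            # boar heterozygous on X
    with pytest.raises(geno_qc.GenotypeError, match="dialect"):
        GenotypeMatrix(gm.samples, gm.sex, gm.panel, codes)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def crafted_qc_panel():
    """10 markers, 10 female samples; 3 crafted failures."""
    rng = np.random.default_rng(42)
    codes = rng.integers(0, 2, size=(10, 10), dtype=np.int8)
    codes[:, 1] += 1                     # keep marker 1 polymorphic, MAF high
    codes[0:2, 3] = 1
    codes[:, 4] = 0                      # fail: monomorphic (MAF 0)
    codes[2:, 5] = geno_qc.MISSING       # fail: call rate 0.2
    codes[:, 7] = 0
    codes[0, 7] = geno_qc.MISSING        # fail: MAF 0 and call rate 0.9 (not >)
    panel = MarkerPanel([f"m{i}" for i in range(10)], ["1"] * 10,
                        np.arange(1, 11) * 100, ["A"] * 10, ["B"] * 10)
    return GenotypeMatrix([f"s{i}" for i in range(10)], ["F"] * 10, panel,
                          codes)


def test_crafted_failures_are_removed_and_counted():
    gm = crafted_qc_panel()
    kept, report = qc_filter(gm)
    assert report.n_retained == kept.n_markers == 7
    assert report.n_fail_call_rate == 2      # markers 5 and 7
    assert report.n_fail_maf == 1            # marker 4
    assert "m4" not in kept.panel.ids and "m5" not in kept.panel.ids


def test_maf_half_percent_is_below_the_one_percent_threshold():
    # 100 females, one het -> MAF 1/200 = 0.005
    codes = np.zeros((100, 2), dtype=np.int8)
    codes[0, 0] = 1
    codes[:50, 1] = 1                       # companion marker passes
    panel = MarkerPanel(["rare", "common"], ["1", "1"], [1, 2],
                        ["A", "A"], ["B", "B"])
    gm = GenotypeMatrix([f"s{i}" for i in range(100)], ["F"] * 100, panel,
                        codes)
    kept, report = qc_filter(gm)
    assert list(kept.panel.ids) == ["common"]
    assert report.n_fail_maf == 1


def test_clean_panel_passes_unchanged_and_filter_is_idempotent():
    codes = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (1, 5))
    panel = MarkerPanel([f"m{i}" for i in range(5)], ["1"] * 5,
                        np.arange(1, 6), ["A"] * 5, ["B"] * 5)
    gm = GenotypeMatrix(["a", "b", "c", "d"], ["F"] * 4, panel, codes)
    kept, _ = qc_filter(gm)
    assert np.array_equal(kept.codes, gm.codes)
    kept2, rep2 = qc_filter(kept)
    assert np.array_equal(kept2.codes, kept.codes)
    assert rep2.n_retained == rep2.n_input


def test_all_markers_removed_is_an_explicit_error():
    codes = np.zeros((4, 2), dtype=np.int8)
    panel = MarkerPanel(["a", "b"], ["1", "1"], [1, 2], ["A", "A"],
                        ["B", "B"])
    gm = GenotypeMatrix(["s1", "s2", "s3", "s4"], ["F"] * 4, panel, codes)
    with pytest.raises(geno_qc.QcError):
        qc_filter(gm)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def test_fertile_sow_frequency_reproduces_reported_value():
    f = allele_frequency(landrace.CONCORDANCE_COUNTS["fertile"])
    assert round(f, 3) == 0.062


def test_hemizygous_boar_frequency_reproduces_reported_value():
    f = allele_frequency((0, 0, 0),
                         (landrace.PARENT_COUNTS["boar_C"],
                          landrace.PARENT_COUNTS["boar_T"]))
    assert round(f, 3) == 0.069


def test_all_wildtype_frequency_is_zero_and_negatives_rejected():
    assert allele_frequency((10, 0, 0)) == 0.0
    with pytest.raises(ValueError):
        allele_frequency((1, -1, 0))


def test_pooled_frequency_is_allele_weighted_mean_of_groups():
    g1, g2 = (12, 5, 3), (100, 30, 1)
    m1, m2 = (9, 2), (50, 4)
    pooled = allele_frequency(tuple(np.add(g1, g2)), tuple(np.add(m1, m2)))
    n1 = 2 * sum(g1) + sum(m1)
    n2 = 2 * sum(g2) + sum(m2)
    weighted = (allele_frequency(g1, m1) * n1
                + allele_frequency(g2, m2) * n2) / (n1 + n2)
    assert pooled == pytest.approx(weighted, abs=1e-12)


def test_sex_aware_x_frequency_counts_one_allele_per_boar():
    gm = small_matrix()
    # marker x1: boars codes (0, 2) -> alleles (0, 1); females 1,0,2,0 of 8
    assert gm.alt_freq()[2] == pytest.approx((1 + 3) / (2 + 8))


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_survey_fixture_reproduces_published_concordance():
    gm, classes = landrace.concordance_fixture()
    table = concordance_table(gm, f"X:{landrace.CAUSAL_POS}", classes)
    assert table["alt/alt"]["small_vulvae"] == 36
    assert table["alt/alt"]["fertile"] == 0
    assert table["ref/alt"]["fertile"] == 606
    assert dict(table.margins()) == {"small_vulvae": 43,
                                     "normal_siblings": 29, "fertile": 4869}


def test_single_sample_concordance_and_missing_row():
    panel = MarkerPanel(["m"], ["1"], [5], ["A"], ["B"])
    gm = GenotypeMatrix(["only"], ["F"], panel,
                        np.array([[1]], dtype=np.int8))
    t = concordance_table(gm, "m", {"only": "case"})
    assert t["ref/alt"]["case"] == 1
    assert int(t.counts.to_numpy().sum()) == 1
    gm2 = GenotypeMatrix(["only"], ["F"], panel,
                         np.array([[-1]], dtype=np.int8))
    t2 = concordance_table(gm2, "m", {"only": "case"})
    assert t2["missing"]["case"] == 1


def test_concordance_is_invariant_to_sample_order(rng):
    gm = small_matrix()
    classes = {s: ("case" if i % 2 else "control")
               for i, s in enumerate(gm.samples)}
    perm = rng.permutation(gm.n_samples)
    gm_p = gm.subset_samples([gm.samples[i] for i in perm])
    t1 = concordance_table(gm, "m1", classes)
    t2 = concordance_table(gm_p, "m1", classes)
    assert t1.counts.equals(t2.counts)
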