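"""Summary-statistic I/O and exposure–outcome harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrbiome.errors import ConfigurationError, SummaryStatParseError
from mrbiome.gwas_io import (
    SUMMARY_COLUMNS,
    SummaryStatSet,
    harmonize,
    read_summary_stats,
    write_summary_stats,
)
from mrbiome.synthetic import GeneratorConfig, TruthRecord, generate_pair

from conftest import make_set


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def test_read_back_identity(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(
        "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-8\t5000\n"
        "rs2\t2\t200\tC\tT\t0.4\t-0.2\t0.02\t1e-5\t5000\n"
        "rs3\t3\t300\tG\tT\t0.5\t0.05\t0.01\t0.2\t5000\n"
    )
    sset = read_summary_stats(p, trait_name="toy")
    assert len(sset) == 3
    assert list(sset.records["snp_id"]) == ["rs1", "rs2", "rs3"]
    assert sset.records.loc[1, "beta"] == -0.2


def test_lowercase_alleles_normalized(tmp_path):
    p = tmp_path / "lower.tsv"
    p.write_text(
        "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
        "rs1\t1\t100\ta\tg\t0.3\t0.1\t0.01\t1e-8\t5000\n"
    )
    sset = read_summary_stats(p)
    assert sset.records.loc[0, "effect_allele"] == "A"
    assert sset.records.loc[0, "other_allele"] == "G"


def test_dialect_column_mapping(tmp_path):
    p = tmp_path / "dialect.tsv"
    p.write_text(
        "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN\n"
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-8\t5000\n"
    )
    dialect = dict(
        snp_id="SNP", chrom="CHR", pos="BP", effect_allele="A1", other_allele="A2",
        eaf="FREQ", beta="BETA", se="SE", pvalue="P", n="N",
    )
    sset = read_summary_stats(p, dialect=dialect)
    assert list(sset.records.columns) == SUMMARY_COLUMNS


def test_missing_column_is_configuration_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("snp_id\tchrom\n" "rs1\t1\n")
    with pytest.raises(ConfigurationError):
        read_summary_stats(p)


def test_non_numeric_beta_names_the_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-8\t5000\n"
        "rs2\t1\t200\tA\tG\t0.3\tnot_a_number\t0.01\t1e-8\t5000\n"
    )
    with pytest.raises(SummaryStatParseError, match="line 3"):
        read_summary_stats(p)


def test_write_empty_set_errors(tmp_path):
    sset = make_set([{}])
    empty = sset.replace_records(sset.records.iloc[0:0])
    with pytest.raises(ConfigurationError):
        write_summary_stats(empty, tmp_path / "empty.tsv")


def test_write_one_record_two_lines(tmp_path):
    p = tmp_path / "one.tsv"
    write_summary_stats(make_set([{}]), p)
    assert len(p.read_text().strip().splitlines()) == 2


def test_round_trip_100_random_records(tmp_path):
    config = GeneratorConfig(n_snps=100, n_strong=5)
    exposure, _, _ = generate_pair(config, TruthRecord(), seed=13)
    p = tmp_path / "round.tsv"
    write_summary_stats(exposure, p)
    back = read_summary_stats(p, trait_name=exposure.trait_name)
    a = exposure.records.sort_values("snp_id").reset_index(drop=True)
    b = back.records.sort_values("snp_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b, check_dtype=False, rtol=0, atol=1e-12)


def test_gzip_transparent(tmp_path):
    p = tmp_path / "z.tsv.gz"
    write_summary_stats(make_set([{}, {}]), p)
    assert len(read_summary_stats(p)) == 2


# ---------------------------------------------------------------------------
# harmonization rules
# ---------------------------------------------------------------------------

def test_matching_alleles_retained_unchanged():
    exp = make_set([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
    out = make_set([{"effect_allele": "A", "other_allele": "G", "beta": 0.05}], role="outcome")
    ht = harmonize(exp, out)
    assert len(ht) == 1
    assert ht.table.loc[0, "beta_out"] == 0.05


def test_swapped_alleles_flip_beta_and_eaf():
    exp = make_set([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
    out = make_set(
        [{"effect_allele": "G", "other_allele": "A", "beta": 0.05, "eaf": 0.3}],
        role="outcome",
    )
    ht = harmonize(exp, out)
    assert ht.table.loc[0, "beta_out"] == -0.05
    assert ht.table.loc[0, "eaf_out"] == pytest.approx(0.7)


def test_strand_flip_resolved_by_complement():
    exp = make_set([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
    # outcome reported on the other strand: T/C complements A/G
    out = make_set(
        [{"effect_allele": "T", "other_allele": "C", "beta": 0.05}], role="outcome"
    )
    ht = harmonize(exp, out)
    assert len(ht) == 1
    assert ht.table.loc[0, "beta_out"] == 0.05


def test_palindromic_ambiguous_dropped():
    exp = make_set([{"effect_allele": "A", "other_allele": "T", "eaf": 0.5}])
    out = make_set([{"effect_allele": "A", "other_allele": "T", "eaf": 0.5}], role="outcome")
    ht = harmonize(exp, out, palindrome_policy="drop_ambiguous")
    assert len(ht) == 0
    assert list(ht.dropped["reason"]) == ["palindromic_ambiguous"]


def test_palindromic_oriented_by_frequency():
    exp = make_set([{"effect_allele": "A", "other_allele": "T", "eaf": 0.1, "beta": 0.2}])
    # same letters but discordant frequency: outcome is on the other strand
    out = make_set(
        [{"effect_allele": "A", "other_allele": "T", "eaf": 0.9, "beta": 0.07}],
        role="outcome",
    )
    ht = harmonize(exp, out)
    assert len(ht) == 1
    assert ht.table.loc[0, "beta_out"] == pytest.approx(-0.07)
    assert ht.table.loc[0, "eaf_out"] == pytest.approx(0.1)


def test_palindromic_policies():
    exp = make_set([{"effect_allele": "C", "other_allele": "G", "eaf": 0.2}])
    out = make_set([{"effect_allele": "C", "other_allele": "G", "eaf": 0.2}], role="outcome")
    assert len(harmonize(exp, out, palindrome_policy="keep")) == 1
    assert len(harmonize(exp, out, palindrome_policy="drop_all")) == 0
    assert len(harmonize(exp, out, palindrome_policy="drop_ambiguous")) == 1


def test_allele_mismatch_and_missing_dropped_with_reason():
    exp = make_set(
        [
            {"effect_allele": "A", "other_allele": "G"},
            {"effect_allele": "A", "other_allele": "C"},
        ]
    )
    out_records = exp.records.copy()
    out_records.loc[1, "other_allele"] = "T"  # A/T vs A/C: mismatch
    out = SummaryStatSet("out", out_records.iloc[[1]], trait_role="outcome")
    with pytest.warns(UserWarning):
        # rs1 not in outcome, rs2 mismatched -> nothing retained, warn not raise
        ht = harmonize(exp, out)
    reasons = dict(zip(ht.dropped["snp_id"], ht.dropped["reason"]))
    assert reasons == {"rs1": "not_in_outcome", "rs2": "allele_mismatch"}


# ---------------------------------------------------------------------------
# harmonization invariants (seeded random panels)
# ---------------------------------------------------------------------------

def _random_pair(seed):
    config = GeneratorConfig(n_snps=40, n_strong=4)
    return generate_pair(config, TruthRecord(true_theta=0.2), seed=seed)


def _sets_from_table(ht, template_exp, template_out):
    """Rebuild exposure/outcome sets from a harmonized table (exposure alleles)."""
    exp_recs = template_exp.records[template_exp.records["snp_id"].isin(ht.snp_ids)].copy()
    out_recs = exp_recs.copy()
    merged = out_recs.merge(ht.table[["snp_id", "beta_out", "se_out", "eaf_out", "n_out"]])
    out_recs["beta"] = merged["beta_out"].to_numpy()
    out_recs["se"] = merged["se_out"].to_numpy()
    out_recs["eaf"] = merged["eaf_out"].to_numpy()
    out_recs["n"] = merged["n_out"].astype(int).to_numpy()
    return (
        template_exp.replace_records(exp_recs),
        SummaryStatSet("out2", out_recs, trait_role="outcome"),
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_harmonize_idempotent(seed):
    exp, out, _ = _random_pair(seed)
    ht1 = harmonize(exp, out)
    exp2, out2 = _sets_from_table(ht1, exp, out)
    ht2 = harmonize(exp2, out2)
    assert ht2.snp_ids == ht1.snp_ids
    np.testing.assert_allclose(
        ht2.table["beta_out"].to_numpy(), ht1.table["beta_out"].to_numpy()
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_allele_swap_involution(seed):
    exp, out, _ = _random_pair(seed)
    swapped = out.records.copy()
    swapped[["effect_allele", "other_allele"]] = swapped[
        ["other_allele", "effect_allele"]
    ].to_numpy()
    swapped["beta"] = -swapped["beta"]
    swapped["eaf"] = 1.0 - swapped["eaf"]
    out_sw = SummaryStatSet("out", swapped, trait_role="outcome")
    ht_orig = harmonize(exp, out)
    ht_sw = harmonize(exp, out_sw)
    assert ht_sw.snp_ids == ht_orig.snp_ids
    np.testing.assert_allclose(
        ht_sw.table["beta_out"].to_numpy(),
        ht_orig.table["beta_out"].to_numpy(),
        atol=1e-14,
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_retained_plus_dropped_equals_shared(seed):
    exp, out, _ = _random_pair(seed)
    # perturb: remove some outcome SNPs so not_in_outcome is exercised
    rng = np.random.default_rng(seed)
    keep = rng.random(len(out)) > 0.2
    out = out.replace_records(out.records.loc[keep])
    ht = harmonize(exp, out)
    assert len(ht) + len(ht.dropped) == len(exp)
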