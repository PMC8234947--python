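"""Reading, validation, allele flipping, harmonization and proxy substitution."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from clustmr.exceptions import ConfigurationError, TableValidationError
from clustmr.sumstats import (
    AssociationRecord,
    HarmonizationAction,
    VariantPanelEntry,
    complement_record,
    flip_record,
    harmonize_to_panel,
    read_association_table,
    substitute_proxies,
    write_association_table,
)


def rec(vid="rs1", ea="A", oa="G", beta=0.3, se=0.1, pval=0.01, eaf=0.2, n=1000.0):
    return AssociationRecord(
        variant_id=vid, effect_allele=ea, other_allele=oa, beta=beta, se=se, pval=pval,
        eaf=eaf, n=n,
    )


def entry(vid="rs1", risk="A", alt="G", **kw):
    return VariantPanelEntry(variant_id=vid, risk_allele=risk, alt_allele=alt, **kw)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def write_table(tmp_path, rows, header="variant_id\teffect_allele\tother_allele\tbeta\tse\tpval"):
    p = tmp_path / "t.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def test_read_wellformed_uppercases_alleles(tmp_path):
    p = write_table(
        tmp_path,
        ["rs1\ta\tg\t0.1\t0.05\t0.04", "rs2\tC\tT\t-0.2\t0.1\t0.5", "rs3\tg\tc\t0\t0.2\t1"],
    )
    records = read_association_table(p)
    assert len(records) == 3
    assert records[0].effect_allele == "A" and records[0].other_allele == "G"
    assert records[2].effect_allele == "G"


def test_read_rejects_bad_rows_with_row_numbers(tmp_path):
    p = write_table(
        tmp_path,
        ["rs1\tA\tG\t0.1\t0.05\t0.04", "rs2\tC\tT\t-0.2\t0\t0.5", "rs3\tAT\tG\t0.0\t0.1\t0.9"],
    )
    with pytest.raises(TableValidationError) as exc:
        read_association_table(p)
    rows = [r for r, _ in exc.value.errors]
    assert rows == [2, 3]  # se=0 on row 2, indel alleles on row 3


def test_read_missing_mandatory_column_is_config_error(tmp_path):
    p = write_table(tmp_path, ["rs1\tA\tG\t0.1\t0.05"], header="variant_id\teffect_allele\tother_allele\tbeta\tse")
    with pytest.raises(ConfigurationError):
        read_association_table(p)


def test_read_custom_column_map(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("SNP\tA1\tA2\tb\tstderr\tp\nrs1\tA\tG\t0.1\t0.05\t0.04\n")
    records = read_association_table(
        p,
        {"variant_id": "SNP", "effect_allele": "A1", "other_allele": "A2",
         "beta": "b", "se": "stderr", "pval": "p"},
    )
    assert records[0].variant_id == "rs1" and records[0].se == 0.05


def test_roundtrip_write_read(tmp_path):
    records = [rec(), rec(vid="rs2", ea="T", oa="C", beta=-0.1, eaf=None, n=None)]
    p = tmp_path / "out.tsv"
    write_association_table(records, p)
    back = read_association_table(p)
    assert back == records


# ---------------------------------------------------------------------------
# flipping
# ---------------------------------------------------------------------------


def test_flip_definition():
    r = flip_record(rec(ea="A", oa="G", beta=0.3, eaf=0.2))
    assert (r.effect_allele, r.other_allele) == ("G", "A")
    assert r.beta == -0.3 and r.eaf == 0.8 and r.se == 0.1


def test_flip_zero_beta_fixed_point():
    r = flip_record(rec(beta=0.0, eaf=0.5))
    assert r.beta == 0.0 and r.eaf == 0.5
    assert (r.effect_allele, r.other_allele) == ("G", "A")


@given(
    beta=st.floats(-5, 5, allow_nan=False),
    se=st.floats(1e-6, 10, allow_nan=False),
    eaf=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    pval=st.floats(1e-300, 1, exclude_min=False, allow_nan=False),
)
def test_flip_is_involution(beta, se, eaf, pval):
    r = rec(beta=beta, se=se, eaf=eaf, pval=max(pval, 1e-300))
    rr = flip_record(flip_record(r))
    assert rr.beta == r.beta and rr.se == r.se and rr.pval == r.pval
    assert (rr.effect_allele, rr.other_allele) == (r.effect_allele, r.other_allele)
    if eaf is None:
        assert rr.eaf is None
    else:
        assert math.isclose(rr.eaf, r.eaf, abs_tol=1e-15)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def test_harmonize_kept_and_flipped():
    panel = [entry("rs1", "A", "G"), entry("rs2", "A", "G")]
    records = [rec("rs1", "A", "G", beta=0.3), rec("rs2", "G", "A", beta=0.3)]
    out, actions = harmonize_to_panel(records, panel)
    assert [a.action for a in actions] == ["kept", "allele_flipped"]
    assert out[0].beta == 0.3 and out[1].beta == -0.3
    assert all(r.effect_allele == "A" for r in out)


def test_harmonize_strand_flip():
    # record reported on the other strand: panel A/G vs record T/C
    panel = [entry("rs1", "A", "G")]
    out, actions = harmonize_to_panel([rec("rs1", "T", "C", beta=0.4)], panel)
    assert actions[0].action == "strand_flipped"
    assert out[0].effect_allele == "A" and out[0].beta == 0.4


def test_harmonize_mismatch_and_missing():
    panel = [entry("rs1", "A", "G"), entry("rs2", "A", "G")]
    out, actions = harmonize_to_panel([rec("rs1", "A", "C")], panel)
    assert out == []
    assert {a.variant_id: a.action for a in actions} == {
        "rs1": "dropped_mismatch",
        "rs2": "dropped_missing",
    }


def test_palindromic_ambiguous_eaf_dropped():
    panel = [entry("rs1", "A", "T")]
    out, actions = harmonize_to_panel(
        [rec("rs1", "A", "T", eaf=0.49)], panel, palindrome_policy="infer_by_eaf",
        eaf_window=0.08,
    )
    assert out == [] and actions[0].action == "dropped_palindromic"


def test_palindromic_informative_eaf_kept_nominal():
    panel = [entry("rs1", "A", "T")]
    out, actions = harmonize_to_panel([rec("rs1", "A", "T", eaf=0.2)], panel)
    assert actions[0].action == "kept" and out[0].beta == 0.3


def test_palindromic_reference_frequency_resolves_strand():
    # record eaf 0.2 but the risk allele is common (0.8): labels refer to the
    # opposite strand, so the nominal orientation must be reversed
    panel = [entry("rs1", "A", "T", risk_af=0.8)]
    out, actions = harmonize_to_panel([rec("rs1", "A", "T", beta=0.3, eaf=0.2)], panel)
    assert actions[0].action == "strand_flipped"
    assert out[0].beta == -0.3


def test_palindromic_policy_drop_and_missing_eaf():
    panel = [entry("rs1", "C", "G")]
    out, actions = harmonize_to_panel(
        [rec("rs1", "C", "G", eaf=0.2)], panel, palindrome_policy="drop"
    )
    assert actions[0].action == "dropped_palindromic"
    out, actions = harmonize_to_panel([rec("rs1", "C", "G", eaf=None)], panel)
    assert actions[0].action == "dropped_palindromic"


def test_unknown_policy_is_config_error():
    with pytest.raises(ConfigurationError):
        harmonize_to_panel([rec()], [entry()], palindrome_policy="bogus")


def test_one_action_per_panel_variant(planted_dataset):
    tables, panel, _ = planted_dataset
    for records in tables.values():
        _, actions = harmonize_to_panel(records, panel)
        assert len(actions) == len(panel)
        assert [a.variant_id for a in actions] == [e.variant_id for e in panel]


def test_harmonization_invariant_to_input_orientation(planted_dataset):
    """Re-encoding every input row with swapped alleles and negated beta must
    give identical harmonized output."""
    tables, panel, _ = planted_dataset
    records = tables["BMI"]
    out1, _ = harmonize_to_panel(records, panel)
    out2, _ = harmonize_to_panel([flip_record(r) for r in records], panel)
    assert [(r.variant_id, r.beta, r.effect_allele) for r in out1] == [
        (r.variant_id, r.beta, r.effect_allele) for r in out2
    ]


# ---------------------------------------------------------------------------
# proxies
# ---------------------------------------------------------------------------


def proxy_entry(r2=0.9, proxy_risk="T", proxy_alt="C"):
    return entry(
        "rs1", "A", "G", proxy_id="rs99", proxy_r2=r2,
        proxy_risk_allele=proxy_risk, proxy_alt_allele=proxy_alt,
    )


def test_proxy_substituted_when_index_variant_absent():
    records = [rec("rs99", "T", "C", beta=0.25)]
    out, actions = substitute_proxies(records, [proxy_entry()])
    assert actions[0].action == "proxy_substituted" and "rs99" in actions[0].detail
    sub = [r for r in out if r.variant_id == "rs1"]
    assert len(sub) == 1 and sub[0].beta == 0.25
    assert sub[0].effect_allele == "A"  # relabelled to panel alleles


def test_proxy_orientation_from_panel_declaration():
    # proxy record reports the non-risk allele: beta must be negated
    records = [rec("rs99", "C", "T", beta=0.25)]
    out, actions = substitute_proxies(records, [proxy_entry()])
    sub = [r for r in out if r.variant_id == "rs1"][0]
    assert sub.beta == -0.25


def test_proxy_below_r2_threshold_refused():
    records = [rec("rs99", "T", "C")]
    _, actions = substitute_proxies(records, [proxy_entry(r2=0.4)], r2_min=0.5)
    assert actions[0].action == "dropped_missing" and "0.4" in actions[0].detail


def test_both_absent_is_dropped_missing():
    _, actions = substitute_proxies([], [proxy_entry()])
    assert actions[0].action == "dropped_missing"


def test_action_vocabulary():
    assert HarmonizationAction("rs1", "kept").action == "kept"


def test_builtin_panel_fixture_structure():
    from clustmr.datasets import synthetic_variant_panel

    panel = synthetic_variant_panel()
    assert len(panel) == 26
    proxies = {e.variant_id: e.proxy_id for e in panel if e.proxy_id}
    assert proxies == {"rs10993397": "rs7865239", "rs8043701": "rs11075468"}
    genes = [e.gene_label for e in panel]
    assert genes.count("DENND1A") == 3 and genes.count("THADA") == 3
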