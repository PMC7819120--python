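import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonbias.cds_io import CodingSequence
from codonbias.metrics import (
    count_codons,
    counts_from_mapping,
    effective_number_of_codons,
    pool_counts,
    positional_gc,
    round_half_up,
    rscu,
    synonymous_third_position,
)

from .conftest import random_count_table
from .oracles import enc_oracle, x3s_oracle


def test_count_codons_excludes_stop_from_n(table):
    t = count_codons(CodingSequence("g", "ATGTTATAA"), table)
    assert t.counts == {"ATG": 1, "TTA": 1, "TAA": 1}
    assert t.n_codons == 2


def test_count_codons_empty_sequence(table):
    t = count_codons(CodingSequence("g", ""), table)
    assert t.n_codons == 0


def test_count_codons_rejects_partial_frame(table):
    with pytest.raises(ValueError):
        count_codons(CodingSequence("g", "ATGTT"), table)


def test_pooling_commutes_with_counting(table):
    seqs = ["ATGGCT" * 10, "TTACAT" * 7, "GGGAAA" * 3]
    parts = [count_codons(CodingSequence(f"g{i}", s), table) for i, s in enumerate(seqs)]
    whole = count_codons(CodingSequence("cat", "".join(seqs)), table)
    pooled = pool_counts(parts)
    assert pooled.counts == whole.counts
    assert pool_counts([parts[0]]).counts == parts[0].counts


def test_rscu_study_leucine_and_alanine(table):
    # pooled counts published for the study genome's Leu and Ala families
    leu = {"TTA": 673, "TTG": 458, "CTT": 456, "CTC": 135, "CTA": 288, "CTG": 135}
    ala = {"GCT": 482, "GCC": 186, "GCA": 326, "GCG": 136}
    r = rscu(counts_from_mapping({**leu, **ala}, table))
    assert round_half_up(r.get("TTA"), 2) == 1.88
    assert round_half_up(r.get("GCT"), 2) == 1.71


def test_rscu_uniform_usage_is_one(table):
    counts = counts_from_mapping({c: 7 for c in table.sense_codons}, table)
    r = rscu(counts)
    assert all(abs(r.get(c) - 1) < 1e-12 for c in table.sense_codons)


def test_rscu_unobserved_family_is_nan_not_zero(table):
    r = rscu(counts_from_mapping({"TTA": 3}, table))
    assert math.isnan(r.get("TGT"))
    assert r.get("TTA") == 6.0


def test_rscu_met_trp_are_one_when_observed(table):
    r = rscu(counts_from_mapping({"ATG": 5, "TGG": 2}, table))
    assert r.get("ATG") == 1.0 and r.get("TGG") == 1.0


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=40), min_size=61, max_size=61))
def test_rscu_family_sum_equals_degeneracy(counts_list):
    table = _table()
    counts = counts_from_mapping(dict(zip(table.sense_codons, counts_list)), table)
    r = rscu(counts)
    for aa, family in table.families.items():
        total = sum(counts.get(c) for c in family)
        fam_sum = sum(r.get(c) for c in family)
        if total > 0:
            assert abs(fam_sum - len(family)) < 1e-9
        else:
            assert math.isnan(fam_sum)


def _table():
    from codonbias.codon_model import standard_table

    return standard_table()


def test_positional_gc_examples(table):
    assert positional_gc(CodingSequence("g", "GCGCGC"), table) == (1, 1, 1, 1, 1)
    at = positional_gc(CodingSequence("g", "ATTAAA" * 5), table)
    assert at.gc == at.gc1 == at.gc2 == at.gc3 == 0
    # stops are excluded entirely
    with_stop = positional_gc(CodingSequence("g", "GCGTAA"), table)
    assert with_stop.gc == 1.0


def test_positional_gc_gc12_identity(table):
    rng = np.random.default_rng(7)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=3 * rng.integers(5, 60)))
        pos = positional_gc(CodingSequence("g", seq), table)
        if not math.isnan(pos.gc12):
            assert pos.gc12 == (pos.gc1 + pos.gc2) / 2


def test_positional_gc_empty_is_nan(table):
    pos = positional_gc(CodingSequence("g", "TAA"), table)
    assert all(math.isnan(v) for v in pos)


def test_gc3s_all_gc_ending(table):
    counts = counts_from_mapping(
        {c: 3 for c in table.sense_codons if c[2] in "GC"}, table
    )
    syn = synonymous_third_position(counts)
    assert syn.gc3s == 1.0


def test_x3s_hand_table_matches_enumeration(table):
    # three two-fold families with counts {2,1}, {1,1}, {4,0}
    counts = {"AAA": 2, "AAG": 1, "GAT": 1, "GAC": 1, "CAA": 4, "CAG": 0}
    ct = counts_from_mapping(counts, table)
    syn = synonymous_third_position(ct)
    want = x3s_oracle(counts, table)
    # A-ending members exist in Lys and Gln families only: denom = 3 + 4
    assert syn.a3s == pytest.approx(6 / 7)
    for key in ("gc3s", "a3s", "t3s", "g3s", "c3s"):
        got = getattr(syn, key)
        if math.isnan(want[key]):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want[key], abs=1e-12)


def test_x3s_all_denominator_mode(table):
    counts = counts_from_mapping({"AAA": 2, "AAG": 2, "GAT": 4}, table)
    syn = synonymous_third_position(counts, denominator="all")
    assert syn.a3s == pytest.approx(2 / 8)
    with pytest.raises(ValueError):
        synonymous_third_position(counts, denominator="bogus")


def test_x3s_matches_oracle_on_random_tables(table):
    rng = np.random.default_rng(11)
    for _ in range(30):
        ct = random_count_table(rng, table, mean=3.0)
        got = synonymous_third_position(ct)
        want = x3s_oracle(dict(ct.counts), table)
        for key in ("gc3s", "a3s", "t3s", "g3s", "c3s"):
            assert getattr(got, key) == pytest.approx(want[key], abs=1e-9)


def test_enc_uniform_usage_caps_at_61(table):
    counts = counts_from_mapping({c: 50 for c in table.sense_codons}, table)
    assert effective_number_of_codons(counts) == 61.0


def test_enc_single_codon_per_family_floors_at_20(table):
    chosen = {fam[0]: 30 for fam in table.families.values()}
    assert effective_number_of_codons(counts_from_mapping(chosen, table)) == 20.0


def test_enc_matches_oracle_on_fixed_random_gene(table):
    rng = np.random.default_rng(42)
    seq_codons = rng.choice(list(table.sense_codons), size=200)
    counts: dict[str, int] = {}
    for c in seq_codons:
        counts[c] = counts.get(c, 0) + 1
    ct = counts_from_mapping(counts, table)
    got = effective_number_of_codons(ct)
    assert got == pytest.approx(enc_oracle(counts, table), abs=1e-9)
    assert 20 <= got <= 61


def test_enc_undefined_when_classes_missing(table):
    assert math.isnan(
        effective_number_of_codons(counts_from_mapping({"AAA": 9}, table))
    )


def test_enc_ile_imputation(table):
    # every class populated except the threefold (Ile absent): still defined
    counts = {c: 5 for c in table.sense_codons if table.codon_to_aa[c] != "Ile"}
    got = effective_number_of_codons(counts_from_mapping(counts, table))
    assert not math.isnan(got)
    assert got == pytest.approx(enc_oracle(counts, table), abs=1e-9)


def test_round_half_up():
    assert round_half_up(1.875, 2) == 1.88
    assert round_half_up(-1.875, 2) == -1.88
    assert round_half_up(0.4449, 2) == 0.44
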