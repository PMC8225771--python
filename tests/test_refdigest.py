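"""Reference digestion: reading, dedup, primer tagging, site finding and
terminal fragments, with brute-force and disambiguation oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trflp.iupac import IUPAC_SETS, disambiguations, reverse_complement
from trflp.refdigest import (
    Enzyme,
    Primer,
    ReferenceRecord,
    TaggedAmplicon,
    dedup_records,
    digest_dataset,
    find_sites,
    insilico_pcr,
    read_reference,
    tag_with_primers,
    terminal_fragment,
)
from trflp.taxonomy import NA_LINEAGE, Lineage


def _write_reference(tmp_path, entries, tax_rows):
    fasta = tmp_path / "ref.fasta"
    fasta.write_text("".join(f">{i}\n{s}\n" for i, s in entries))
    tax = tmp_path / "tax.tsv"
    tax.write_text("id\tlineage\n" + "".join(f"{i}\t{l}\n" for i, l in tax_rows))
    return fasta, tax


# ---------------------------------------------------------------- reading


def test_read_reference_round_trip_and_uppercasing(tmp_path):
    fasta, tax = _write_reference(
        tmp_path,
        [("r1", "acgt"), ("r2", "GGGG")],
        [("r1", "Bacteria;Firmicutes"), ("r2", "Bacteria")],
    )
    records = read_reference(fasta, tax)
    assert [r.id for r in records] == ["r1", "r2"]
    assert records[0].seq == "ACGT"
    assert records[0].lineage.phylum == "Firmicutes"
    assert records[1].lineage.phylum is None


def test_read_reference_permissive_assigns_na_lineage(tmp_path):
    fasta, tax = _write_reference(tmp_path, [("r1", "ACGT")], [("other", "Bacteria")])
    with pytest.raises(ValueError, match="r1"):
        read_reference(fasta, tax)
    records = read_reference(fasta, tax, permissive=True)
    assert records[0].lineage == NA_LINEAGE


def test_read_reference_rejects_duplicate_ids_and_bad_characters(tmp_path):
    fasta, tax = _write_reference(
        tmp_path, [("r1", "ACGT"), ("r1", "ACGT")], [("r1", "Bacteria")]
    )
    with pytest.raises(ValueError, match="r1"):
        read_reference(fasta, tax)
    fasta2, tax2 = _write_reference(tmp_path, [("rX", "ACXT")], [("rX", "Bacteria")])
    with pytest.raises(ValueError, match="position 3"):
        read_reference(fasta2, tax2)


@pytest.mark.parametrize(
    "seqs, kept_ids, removed",
    [
        ([("A", "ACGT"), ("B", "ACGT"), ("C", "ACGA")], ["A", "C"], {"B": "A"}),
        ([("A", "AC"), ("B", "AG")], ["A", "B"], {}),
        ([("A", "AC"), ("B", "AC"), ("C", "AC")], ["A"], {"B": "A", "C": "A"}),
    ],
)
def test_dedup_removes_exact_duplicates_keeping_first(seqs, kept_ids, removed):
    records = [ReferenceRecord(id=i, lineage=NA_LINEAGE, seq=s) for i, s in seqs]
    kept, report = dedup_records(records)
    assert [r.id for r in kept] == kept_ids
    assert report == removed


# ---------------------------------------------------------------- tagging


def test_tag_with_primers_reproduces_amplicon_arithmetic(fwd_primer, rev_primer):
    insert = "A" * 588
    tagged = tag_with_primers(insert, fwd_primer, rev_primer)
    assert len(tagged.seq) == 588 + 23 + 23 == 634
    assert tagged.insert_len == 588
    # removing both flanks recovers the insert
    assert tagged.seq[23:-23] == insert


def test_tag_with_primers_one_base_case():
    # fwd + insert + rc(rev): "C" + "A" + rc("G") = "CAC"
    fwd, rev = Primer("f", "C"), Primer("r", "G")
    assert tag_with_primers("A", fwd, rev).seq == "CAC"


def test_insilico_pcr_exact_embedding_and_failure():
    fwd, rev = Primer("f", "ACGTAC"), Primer("r", "GGTACC")
    template = fwd.seq + "AAAA" + reverse_complement(rev.seq)
    rec = ReferenceRecord(id="t", lineage=NA_LINEAGE, seq=template)
    amp = insilico_pcr(rec, fwd, rev)
    assert amp is not None and len(amp.seq) == 6 + 4 + 6
    assert amp.insert_len == 4
    no = insilico_pcr(
        ReferenceRecord(id="n", lineage=NA_LINEAGE, seq="T" * 40), fwd, rev
    )
    assert no is None


def test_insilico_pcr_uses_iupac_compatibility():
    fwd, rev = Primer("f", "ACN"), Primer("r", "TTT")
    template = "ACG" + "CCCC" + "AAA"  # rc(TTT) = AAA
    rec = ReferenceRecord(id="t", lineage=NA_LINEAGE, seq=template)
    amp = insilico_pcr(rec, fwd, rev)
    assert amp is not None and amp.insert_len == 4
    assert amp.seq == "ACN" + "CCCC" + "AAA"


# ---------------------------------------------------------------- sites


@pytest.mark.parametrize(
    "seq, enzyme_name, semantics, expected",
    [
        ("GGGAGCTGGG", "AluI", "guaranteed", [3]),
        ("AATCGTGATT", "Hpy188III", "guaranteed", [2]),
        ("AANCTAGCTAA", "AluI", "guaranteed", [5]),
        ("AANCTAGCTAA", "AluI", "possible", [1, 5]),
        ("AGCTAGCT", "AluI", "guaranteed", [0, 4]),
    ],
)
def test_find_sites_worked_examples(alu, hpy, seq, enzyme_name, semantics, expected):
    enzyme = {"AluI": alu, "Hpy188III": hpy}[enzyme_name]
    assert find_sites(seq, enzyme, semantics) == expected


def test_find_sites_rejects_unknown_semantics(alu):
    with pytest.raises(ValueError, match="semantics"):
        find_sites("AGCT", alu, "maybe")


def test_both_default_enzymes_are_palindromic(alu, hpy):
    assert alu.is_palindromic and hpy.is_palindromic


def test_non_palindromic_pattern_scans_bottom_strand():
    bsa = Enzyme(name="BsaI-like", site="GGTCTC", cut_offset=1)
    seq = "AA" + reverse_complement("GGTCTC") + "AA"  # site only on bottom strand
    assert find_sites(seq, bsa) == [2]


def _brute_sites(seq, enzyme):
    """Independent window-by-window scan for concrete sequences."""
    patterns = {enzyme.site, reverse_complement(enzyme.site)}
    hits = set()
    for pat in patterns:
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] in IUPAC_SETS[pat[j]] for j in range(len(pat))):
                hits.add(i)
    return sorted(hits)


def test_find_sites_matches_bruteforce_on_random_concrete_sequences(alu, hpy):
    rng = random.Random(42)
    for _ in range(200):
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 200)))
        for enz in (alu, hpy):
            expected = _brute_sites(seq, enz)
            assert find_sites(seq, enz, "guaranteed") == expected
            assert find_sites(seq, enz, "possible") == expected


def test_degeneracy_semantics_are_intersection_and_union(alu, hpy):
    """guaranteed = sites present in every disambiguation; possible = in any."""
    rng = random.Random(7)
    codes = sorted(IUPAC_SETS)
    for _ in range(60):
        length = rng.randint(8, 18)
        seq = [rng.choice("ACGT") for _ in range(length)]
        for pos in rng.sample(range(length), k=rng.randint(0, min(5, length))):
            seq[pos] = rng.choice(codes)
        seq = "".join(seq)
        for enz in (alu, hpy):
            concrete = [set(_brute_sites(v, enz)) for v in disambiguations(seq)]
            expected_g = sorted(set.intersection(*concrete))
            expected_p = sorted(set.union(*concrete))
            assert find_sites(seq, enz, "guaranteed") == expected_g
            assert find_sites(seq, enz, "possible") == expected_p


# ---------------------------------------------------------------- fragments


def _tagged(seq):
    return TaggedAmplicon(record_id="x", seq=seq, insert_len=len(seq))


def test_terminal_fragment_first_site_plus_cut_offset(alu):
    frag = terminal_fragment(_tagged("GGGAGCTGGG"), alu)
    assert (frag.length, frag.unrestricted) == (5, False)
    frag = terminal_fragment(_tagged("AGCTAGCT"), alu)
    assert frag.length == 2  # leftmost site wins


def test_terminal_fragment_unrestricted_is_full_length(alu):
    seq = "GGAA" * 160  # no AluI site, 640 bp
    frag = terminal_fragment(_tagged(seq), alu)
    assert frag.unrestricted and frag.length == len(seq) == 640


@given(st.text(alphabet="ACGT", min_size=4, max_size=120))
def test_terminal_fragment_length_bounds(seq):
    from trflp.configio import DEFAULT_ENZYMES

    enz = DEFAULT_ENZYMES["AluI"]
    frag = terminal_fragment(_tagged(seq), enz)
    assert 1 <= frag.length <= len(seq)
    assert frag.unrestricted == (frag.length == len(seq) and not find_sites(seq, enz))


def test_digest_dataset_preserves_cardinality_and_lineage(fwd_primer, rev_primer, alu):
    lin = Lineage("Bacteria", "Firmicutes", genus="Clostridium")
    records = [
        ReferenceRecord(id=f"r{i}", lineage=lin, seq="GGAA" * 50) for i in range(3)
    ]
    profile = digest_dataset(records, fwd_primer, rev_primer, alu)
    assert len(profile.fragments) == 3
    assert all(f.unrestricted for f in profile.fragments)
    assert all(f.lineage.genus == "Clostridium" for f in profile.fragments)


def test_digest_dataset_planted_site_gives_expected_length(fwd_primer, rev_primer, alu):
    # AluI site starting at tagged position 100 -> fragment 100 + 2
    insert = "GGAA" * 100
    pos_in_insert = 100 - len(fwd_primer.seq)
    insert = insert[:pos_in_insert] + "AGCT" + insert[pos_in_insert + 4:]
    rec = ReferenceRecord(id="r", lineage=NA_LINEAGE, seq=insert)
    profile = digest_dataset([rec], fwd_primer, rev_primer, alu)
    assert profile.fragments[0].length == 102


def test_digest_dataset_is_order_independent(fwd_primer, rev_primer, alu):
    rng = random.Random(5)
    records = [
        ReferenceRecord(
            id=f"r{i}", lineage=NA_LINEAGE,
            seq="".join(rng.choice("ACGT") for _ in range(200)),
        )
        for i in range(8)
    ]
    fwd_order = digest_dataset(records, fwd_primer, rev_primer, alu)
    rev_order = digest_dataset(records[::-1], fwd_primer, rev_primer, alu)
    by_id = {f.record_id: f.length for f in fwd_order.fragments}
    assert {f.record_id: f.length for f in rev_order.fragments} == by_id
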