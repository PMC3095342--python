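"""In-silico PCR, progressive alignment and supermatrix concatenation."""
import numpy as np
import pytest

from plastidmark import marker_extraction as mx
from plastidmark.core_io import (
    FormatError,
    MultipleAlignment,
    PlastomeRecord,
    PrimerPair,
    reverse_complement,
)


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def template():
    return PlastomeRecord("t", _random_seq(0, 3000), circular=True)


# ------------------------------------------------------------- primer sites

def test_planted_sites_found_on_both_strands(template):
    seq = template.sequence
    fwd = seq[500:520]
    hits = mx.find_primer_sites(template, fwd)
    assert (500, "+", 0) in hits
    rev = reverse_complement(seq[700:720])
    hits = mx.find_primer_sites(template, rev)
    assert (700, "-", 0) in hits


def test_mismatch_threshold_and_terminal_rule(template):
    seq = template.sequence
    site = list(seq[500:520])
    for i in (3, 8, 13):  # three internal mismatches
        site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
    assert all(h[0] != 500 or h[1] != "+"
               for h in mx.find_primer_sites(template, "".join(site), max_mismatch=2))
    # two mismatches pass
    two = list(seq[500:520])
    for i in (3, 8):
        two[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two[i]]
    assert (500, "+", 2) in mx.find_primer_sites(template, "".join(two))
    # a single 3'-terminal mismatch disqualifies
    term = list(seq[500:520])
    term[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[term[-1]]
    assert all(h[0] != 500 or h[1] != "+"
               for h in mx.find_primer_sites(template, "".join(term)))


def test_origin_spanning_site_on_circular_template(template):
    seq = template.sequence
    primer = seq[-10:] + seq[:10]
    hits = mx.find_primer_sites(template, primer)
    assert (len(seq) - 10, "+", 0) in hits
    linear = PlastomeRecord("l", seq, circular=False)
    assert all(h[0] != len(seq) - 10 for h in mx.find_primer_sites(linear, primer))


def test_degenerate_primer_bases_match_expansion(template):
    seq = template.sequence
    primer = list(seq[100:120])
    primer[5] = "N"
    primer[10] = {"A": "R", "G": "R", "C": "Y", "T": "Y"}[primer[10]]
    assert (100, "+", 0) in mx.find_primer_sites(template, "".join(primer))


# ---------------------------------------------------------------- extraction

def _pair_for(seq, start, end, name="reg"):
    return PrimerPair(name, seq[start:start + 20],
                      reverse_complement(seq[end - 20:end]), end - start)


def test_planted_product_has_expected_length(template):
    seq = template.sequence
    pair = _pair_for(seq, 100, 900)
    amp = mx.extract_amplicon(template, pair)
    assert len(amp) == 800
    assert amp.sequence == seq[100:900]
    assert amp.primer_mismatches == (0, 0)


def test_extraction_is_rotation_invariant(template):
    seq = template.sequence
    pair = _pair_for(seq, 100, 900)
    for offset in (250, 950, 2700):
        rotated = template.rotated(offset)
        assert mx.extract_amplicon(rotated, pair).sequence == seq[100:900]


def test_duplicated_site_is_ambiguous():
    core = _random_seq(3, 900)
    cassette = core[:500]
    genome = PlastomeRecord(
        "ir", cassette + _random_seq(4, 700) + cassette + _random_seq(5, 700),
        circular=True,
    )
    pair = PrimerPair("dup", cassette[:20], reverse_complement(cassette[-20:]), 500)
    with pytest.raises(mx.AmbiguousAmplification) as err:
        mx.extract_amplicon(genome, pair)
    assert len(err.value.candidates) >= 2


def test_missing_reverse_site_fails_amplification(template):
    pair = PrimerPair("none", template.sequence[100:120], "ACGTACGTACGTACGTACGT")
    with pytest.raises(mx.NoAmplification):
        mx.extract_amplicon(template, pair)


def test_extract_regions_marks_failures(template):
    seq = template.sequence
    panel = [
        _pair_for(seq, 100, 900, "ok"),
        PrimerPair("bad", seq[100:120], "ACGTACGTACGTACGTACGT"),
    ]
    regions = mx.extract_regions([template], panel)
    assert regions["ok"]["t"] == seq[100:900]
    assert regions["bad"]["t"] is None


# ----------------------------------------------------------------- alignment

def test_identical_sequences_align_without_gaps():
    s = _random_seq(7, 300)
    aln = mx.align_region({"a": s, "b": s, "c": s})
    assert aln.width == 300
    assert all("-" not in r for r in aln.rows)


def test_single_sequence_passthrough():
    aln = mx.align_region({"only": "ACGTACGT"}, region_name="r")
    assert aln.rows == ["ACGTACGT"] and aln.partition_map == {"r": (0, 8)}


def test_three_bp_insertion_yields_one_gap_run():
    s = _random_seq(8, 400)
    t = s[:200] + "CCC" + s[200:]
    aln = mx.align_region({"a": s, "b": t})
    row_a = aln.row("a")
    assert aln.width == 403
    assert row_a.count("-") == 3
    first = row_a.index("-")
    assert row_a[first : first + 3] == "---"  # contiguous gap run
    assert "-" not in aln.row("b")


def test_guide_tree_joins_similar_sequences_first():
    s = _random_seq(9, 300)
    rng = np.random.default_rng(10)
    similar = list(s)
    for i in rng.choice(300, 3, replace=False):
        similar[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[similar[i]]
    divergent = _random_seq(11, 300)
    aln = mx.align_region({"a": s, "b": "".join(similar), "c": divergent})
    # the similar pair must stay gap-free against each other
    pa, pb = aln.row("a"), aln.row("b")
    shared = [(x, y) for x, y in zip(pa, pb) if not (x == "-" and y == "-")]
    mism = sum(1 for x, y in shared if x != y)
    assert mism <= 3


def test_preserved_order_and_determinism():
    seqs = {"z": _random_seq(12, 200), "a": _random_seq(13, 200)}
    a1 = mx.align_region(seqs)
    a2 = mx.align_region(seqs)
    assert a1.taxa == ["z", "a"]  # input order kept
    assert a1.rows == a2.rows


# --------------------------------------------------------------- supermatrix

def _aln(name, taxa, width, seed):
    rng = np.random.default_rng(seed)
    rows = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, width)]) for _ in taxa]
    return MultipleAlignment(list(taxa), rows, {name: (0, width)})


def test_concatenation_matches_marker_combination_width():
    a = _aln("trnH-psbA", ["x", "y"], 1000, 1)
    b = _aln("trnF-ndhJ", ["x", "y"], 846, 2)
    sm = mx.concatenate_supermatrix([a, b])
    assert sm.width == 1846
    assert sm.partition_map == {"trnH-psbA": (0, 1000), "trnF-ndhJ": (1000, 1846)}


def test_deconcatenation_recovers_inputs():
    parts = [_aln(f"r{i}", ["x", "y", "z"], 50 + 10 * i, i) for i in range(4)]
    sm = mx.concatenate_supermatrix(parts)
    assert sm.width == sum(p.width for p in parts)
    for p in parts:
        name = next(iter(p.partition_map))
        assert sm.region(name).rows == p.rows


def test_single_alignment_concatenation_is_identity():
    a = _aln("solo", ["x", "y"], 120, 5)
    sm = mx.concatenate_supermatrix([a])
    assert sm.rows == a.rows and sm.partition_map == a.partition_map


def test_missing_taxon_rows_are_gap_filled():
    a = _aln("r1", ["x", "y"], 40, 6)
    b = _aln("r2", ["x"], 30, 7)
    sm = mx.concatenate_supermatrix([a, b])
    assert sm.row("y")[40:] == "-" * 30


def test_duplicate_region_names_rejected():
    a = _aln("same", ["x"], 10, 8)
    b = _aln("same", ["x"], 10, 9)
    with pytest.raises(FormatError):
        mx.concatenate_supermatrix([a, b])
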