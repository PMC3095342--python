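"""Round trips and validation for the shared formats and domain types."""
import json

import pytest

from plastidmark import core_io as io


# ---------------------------------------------------------------------- FASTA

def test_fasta_reading_normalizes_and_parses_flags(tmp_path):
    p = tmp_path / "in.fasta"
    p.write_text(">x\nacgu\n>g circular=true\nAAAA\n>h\nACGTN\n")
    records = io.read_fasta(p)
    assert [r.id for r in records] == ["x", "g", "h"]
    assert records[0].sequence == "ACGT" and not records[0].circular
    assert records[1].circular and len(records[1]) == 4
    assert records[2].sequence.endswith("N")


def test_fasta_ambiguity_codes_kept_but_flagged(tmp_path):
    p = tmp_path / "amb.fasta"
    p.write_text(">a\nACGR\n")
    with pytest.warns(UserWarning, match="ambiguity"):
        (rec,) = io.read_fasta(p)
    assert rec.sequence == "ACGR"


@pytest.mark.parametrize("content", ["", ">a\nAC1T\n"])
def test_fasta_errors(tmp_path, content):
    p = tmp_path / "bad.fasta"
    p.write_text(content)
    with pytest.raises(io.FormatError):
        io.read_fasta(p)


def test_fasta_round_trip(tmp_path):
    records = [
        io.PlastomeRecord("r1", "ACGTACGT", circular=True),
        io.PlastomeRecord("r2", "TTTTCCCC"),
    ]
    p = tmp_path / "rt.fasta"
    io.write_fasta(records, p)
    back = io.read_fasta(p)
    assert [(r.id, r.sequence, r.circular) for r in back] == [
        (r.id, r.sequence, r.circular) for r in records
    ]


def test_circular_fetch_wraps():
    rec = io.PlastomeRecord("c", "ACGTTT", circular=True)
    assert rec.fetch(4, 8) == "TTAC"
    assert rec.fetch(-2, 2) == "TTAC"
    linear = io.PlastomeRecord("l", "ACGTTT")
    with pytest.raises(ValueError):
        linear.fetch(4, 8)


# ---------------------------------------------------------------- annotations

GFF = """##gff-version 3
chr\tsrc\tCDS\t1\t90\t.\t+\t.\tID=g1;gene=ndhC
chr\tsrc\tCDS\t121\t180\t.\t+\t.\tID=g2a;Parent=p2;gene=ndhA
chr\tsrc\tCDS\t241\t300\t.\t+\t.\tID=g2b;Parent=p2;gene=ndhA
chr\tsrc\ttRNA\t400\t470\t.\t-\t.\tID=t1;gene=trnH
"""


def test_gff3_coordinates_and_exon_grouping(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF)
    anns = io.read_annotation_table(p)
    assert anns[0].exons == [(0, 90)]  # 1-based inclusive -> 0-based half-open
    multi = next(a for a in anns if a.gene == "ndhA")
    assert multi.exons == [(120, 180), (240, 300)]
    assert multi.spliced_length == 120
    trna = next(a for a in anns if a.gene == "trnH")
    assert trna.feature_type == "tRNA" and trna.strand == "-"


@pytest.mark.parametrize(
    "line",
    [
        "chr\tsrc\tCDS\t10\t5\t.\t+\t.\tID=x",      # end < start
        "chr\tsrc\tCDS\t1\t9\t.\t.\t.\tID=x",       # missing strand
        "chr\tsrc\tpromoter\t1\t9\t.\t+\t.\tID=x",  # unknown feature type
    ],
)
def test_gff3_rejects_bad_rows(tmp_path, line):
    p = tmp_path / "bad.gff3"
    p.write_text(line + "\n")
    with pytest.raises(io.FormatError):
        io.read_annotation_table(p)


def test_annotation_tsv_dialect(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text(
        "gene\ttype\tstrand\tstart\tend\tcopy\n"
        "ndhE\tCDS\t-\t10\t316\tsingle\n"
        "rrn16\trRNA\t+\t400\t500\tIR_duplicate\n"
    )
    anns = io.read_annotation_table(p)
    assert anns[0].exons == [(10, 316)]
    assert anns[1].copy == "IR_duplicate"


def test_gff3_round_trip_is_identity(tmp_path):
    anns = [
        io.GeneAnnotation("ndhA", "CDS", "+", [(120, 180), (240, 300)]),
        io.GeneAnnotation("trnH", "tRNA", "-", [(399, 470)], "IR_duplicate"),
    ]
    p = tmp_path / "rt.gff3"
    io.write_annotation_gff3(anns, p, "chr")
    back = io.read_annotation_table(p)
    assert [(a.gene, a.feature_type, a.strand, a.exons, a.copy) for a in back] == [
        (a.gene, a.feature_type, a.strand, a.exons, a.copy) for a in anns
    ]


# -------------------------------------------------------------------- primers

def test_primer_table_parsing(tmp_path):
    p = tmp_path / "p.tsv"
    p.write_text(
        "region_name\tforward\treverse\texpected_size\n"
        "trnH-psbA\tacgtacgtacgt\tTTGGCCAATTGG\t800\n"
        "matK\tACGTACGTACGTN\tGGCCGGCCAAGG\t\n"
    )
    pairs = io.read_primer_table(p)
    assert pairs[0].expected_size == 800
    assert pairs[0].forward == "ACGTACGTACGT"  # uppercased
    assert pairs[1].expected_size is None


@pytest.mark.parametrize(
    "rows",
    [
        "r1\tACGTACGTAC\tACGTACGTAC\t10\nr1\tACGTACGTAC\tACGTACGTAC\t10\n",  # dup name
        "r1\tACGTACGTA!\tACGTACGTAC\t10\n",  # non-IUPAC
        "r1\tACGTACG\tACGTACGTAC\t10\n",     # too short
    ],
)
def test_primer_table_rejects(tmp_path, rows):
    p = tmp_path / "bad.tsv"
    p.write_text("region_name\tforward\treverse\texpected_size\n" + rows)
    with pytest.raises(io.FormatError):
        io.read_primer_table(p)


# ------------------------------------------------------------------- pedigree

def test_pedigree_maternal_chains(tmp_path):
    p = tmp_path / "ped.tsv"
    p.write_text(
        "variety\tfemale_parent\tmale_parent\n"
        "A\tF\tM\nB\tF\tM2\nC\tUNKNOWN\tUNKNOWN\n"
    )
    ped = io.read_pedigree(p)
    assert ped.maternal_founder("A") == "F" == ped.maternal_founder("B")
    assert ped.maternal_founder("C") == "C"  # founder-less entry is its own line


def test_pedigree_json_input(tmp_path):
    p = tmp_path / "ped.json"
    p.write_text(json.dumps([
        {"variety": "A", "female_parent": "F", "male_parent": "M"},
        {"variety": "F"},
    ]))
    ped = io.read_pedigree(p)
    assert ped.maternal_founder("A") == "F"


@pytest.mark.parametrize(
    "entries",
    [
        [("A", "A", "M")],                      # self-cycle
        [("A", "B", "X"), ("B", "A", "X")],     # two-cycle
        [("A", "F", "M"), ("A", "F", "M")],     # duplicate variety
    ],
)
def test_pedigree_rejects(entries):
    with pytest.raises(io.FormatError):
        io.Pedigree([io.PedigreeEntry(*e) for e in entries])


# --------------------------------------------------------------------- newick

def test_newick_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1)87:0.5,C:2);\n")
    tree = io.read_newick(p)
    out = tmp_path / "out.nwk"
    io.write_newick(tree, out)
    back = io.read_newick(out)
    leaves = sorted(l.taxon.label for l in back.leaf_node_iter())
    assert leaves == ["A", "B", "C"]
    lengths = {l.taxon.label: l.edge.length for l in back.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0}, abs=1e-6)
    internal = [n.label for n in back.preorder_node_iter()
                if not n.is_leaf() and n.label]
    assert "87" in internal  # support survives as internal label


@pytest.mark.parametrize("text", ["(A,(B,C);", "((A,A),B);"])
def test_newick_rejects_malformed_or_duplicate(tmp_path, text):
    p = tmp_path / "bad.nwk"
    p.write_text(text)
    with pytest.raises(io.FormatError):
        io.read_newick(p)


# ---------------------------------------------------------- MultipleAlignment

def test_alignment_partition_map_must_tile():
    with pytest.raises(io.FormatError):
        io.MultipleAlignment(["a", "b"], ["ACGT", "ACGT"], {"r1": (0, 3)})
    aln = io.MultipleAlignment(
        ["a", "b"], ["ACGTAC", "ACGTAC"], {"r1": (0, 4), "r2": (4, 6)}
    )
    assert aln.region("r2").rows == ["AC", "AC"]


def test_alignment_rejects_ragged_rows():
    with pytest.raises(io.FormatError):
        io.MultipleAlignment(["a", "b"], ["ACGT", "ACG"])
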