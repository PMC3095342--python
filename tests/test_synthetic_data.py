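"""Generator ground truth: structure, lesions, maternal inheritance, fixtures."""
import json
import warnings

import pytest

from plastidmark import congruence as cg
from plastidmark import core_io as io
from plastidmark import genome_structure as st
from plastidmark import phylogeny as ph
from plastidmark import synthetic_data as sd


def test_default_plastome_has_study_dimensions():
    rec, anns = sd.simulate_plastome(sd.SimConfig(seed=1))
    assert len(rec) == 146484 and rec.circular
    part = st.detect_inverted_repeats(rec, min_len=1000)
    assert st.partition_lengths(part) == (82324, 25755, 12650, 25755, 146484)
    assert {a.gene for a in anns} == set(f"ndh{c}" for c in "ABCDEFGHIJK")


def test_realized_gc_tracks_parameter():
    rec, _ = sd.simulate_plastome(sd.SimConfig(seed=2))
    stats = st.genome_stats(rec, None, [])
    assert abs(stats.gc_fraction - 37.32) < 0.5


def test_seed_changes_sequence_not_structure(structure_cfg):
    r1, _ = sd.simulate_plastome(structure_cfg(1))
    r2, _ = sd.simulate_plastome(structure_cfg(2))
    assert r1.sequence != r2.sequence
    assert len(r1) == len(r2)
    r1b, _ = sd.simulate_plastome(structure_cfg(1))
    assert r1.sequence == r1b.sequence


def test_simulated_genes_are_valid_orfs():
    rec, anns = sd.simulate_plastome(sd.SimConfig(seed=3))
    for ann in anns:
        cds = ann.spliced_sequence(rec)
        assert len(cds) % 3 == 0
        assert cds[:3] == "ATG" and cds[-3:] in ("TAA", "TAG", "TGA")
        codons = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in codons)


# ------------------------------------------------------------------- lesions

def test_lesion_truth_labels_match_precedence_rules():
    rec, anns = sd.simulate_plastome(sd.SimConfig(seed=4))
    spec = [
        sd.Lesion("v", "ndhC", "delete_internal", 17),
        sd.Lesion("v", "ndhG", "point_stop", 3),
        sd.Lesion("v", "ndhK", "remove_gene"),
        sd.Lesion("v", "ndhJ", "delete_terminal_3p", 190),
        sd.Lesion("v", "ndhE", "insert", 4),
    ]
    mutated, new_anns, truth = sd.inject_lesions(rec, anns, spec, seed=4)
    expect = {
        "ndhC": "frame_disrupted", "ndhG": "internal_stop", "ndhK": "absent",
        "ndhJ": "truncated", "ndhE": "frame_disrupted", "ndhA": "functional",
    }
    for gene, category in expect.items():
        assert truth.expected_category("v", gene) == category
    assert len(mutated) == len(rec) - 17 - (anns_len := next(
        a.end - a.start for a in anns if a.gene == "ndhK")) - 190 + 4
    assert not any(a.gene == "ndhK" for a in new_anns)


def test_lesions_shift_downstream_annotations_consistently():
    rec, anns = sd.simulate_plastome(sd.SimConfig(seed=5))
    spec = [sd.Lesion("v", "ndhB", "delete_internal", 33)]
    mutated, new_anns, _ = sd.inject_lesions(rec, anns, spec, seed=5)
    for ann in new_anns:
        if ann.gene == "ndhB":
            continue
        old = next(a for a in anns if a.gene == ann.gene)
        assert ann.spliced_sequence(mutated) == old.spliced_sequence(rec)


def test_composite_lesions_rejected():
    rec, anns = sd.simulate_plastome(sd.SimConfig(seed=6))
    spec = [
        sd.Lesion("v", "ndhC", "delete_internal", 17),
        sd.Lesion("v", "ndhC", "point_stop", 1),
    ]
    with pytest.raises(io.FormatError, match="multiple lesions"):
        sd.inject_lesions(rec, anns, spec, seed=6)


def test_point_stop_preserves_length():
    rec, anns = sd.simulate_plastome(sd.SimConfig(seed=7))
    spec = [sd.Lesion("v", "ndhD", "point_stop", 3)]  # minus-strand gene
    mutated, new_anns, _ = sd.inject_lesions(rec, anns, spec, seed=7)
    assert len(mutated) == len(rec)
    cds = next(a for a in new_anns if a.gene == "ndhD").spliced_sequence(mutated)
    internal = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
    assert internal.count("TAA") >= 3


# ---------------------------------------------------------- maternal pedigree

def test_sibling_distance_matches_two_generations_of_drift():
    cfg = sd.SimConfig(seed=8)
    regions, _, _ = sd.simulate_maternal_pedigree(cfg)
    a = regions["Onc_GR_LemonHeart"]["ycf1-trnR"]  # rate multiplier 1.0
    b = regions["Onc_GR_Sunkiss"]["ycf1-trnR"]
    L = len(a)
    p = sum(1 for x, y in zip(a, b) if x != y) / L
    expected = 2 * cfg.per_generation_rate
    sigma = (expected * (1 - expected) / L) ** 0.5
    assert abs(p - expected) < 3 * sigma + 0.01  # small allowance for double hits


def test_male_parent_contributes_nothing():
    cfg1 = sd.SimConfig(seed=9)
    ped = sd.default_pedigree()
    swapped = io.Pedigree([
        io.PedigreeEntry(e.variety, e.female_parent, "SomeoneElse")
        for e in ped.entries
    ])
    cfg2 = sd.SimConfig(seed=9, pedigree=swapped)
    r1, _, _ = sd.simulate_maternal_pedigree(cfg1)
    r2, _, _ = sd.simulate_maternal_pedigree(cfg2)
    assert r1 == r2


def test_generating_tree_groups_match_pedigree_groups():
    cfg = sd.SimConfig(seed=10)
    _, pedigree, truth = sd.simulate_maternal_pedigree(cfg)
    tree = io.Tree.get(data=truth.tree_newick, schema="newick",
                       suppress_internal_node_taxa=True, preserve_underscores=True)
    splits = ph.tree_splits(tree)
    all_taxa = frozenset(cfg.taxa)
    for founder, group in cg.maternal_groups(pedigree, taxa=cfg.taxa):
        if 2 <= len(group) <= len(all_taxa) - 2:
            assert group in splits or (all_taxa - group) in splits
    assert truth.lineage["Bllra_Eurostar"] == "Brassia_verrucosa"


def test_lineage_ids_are_constant_within_groups():
    cfg = sd.SimConfig(seed=11)
    _, pedigree, truth = sd.simulate_maternal_pedigree(cfg)
    for founder, group in cg.maternal_groups(pedigree, taxa=cfg.taxa):
        assert {truth.lineage[t] for t in group} == {founder}


# ------------------------------------------------------------------ fixtures

def test_emitted_fixtures_reparse_and_manifest_is_deterministic(tmp_path):
    cfg = sd.SimConfig(seed=12)
    m1 = sd.emit_fixtures(cfg, tmp_path / "a")
    m2 = sd.emit_fixtures(sd.SimConfig(seed=12), tmp_path / "b")
    assert m1["files"] == m2["files"]

    m3 = sd.emit_fixtures(sd.SimConfig(seed=13), tmp_path / "c")
    assert set(m3["files"]) == set(m1["files"])  # same inventory
    assert m3["files"]["genome.fasta"] != m1["files"]["genome.fasta"]

    out = tmp_path / "a"
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        (rec,) = io.read_fasta(out / "genome.fasta")
        anns = io.read_annotation_table(out / "genome.gff3")
        primers = io.read_primer_table(out / "primers.tsv")
        pedigree = io.read_pedigree(out / "pedigree.tsv")
        for region in (out / "regions").glob("*.fasta"):
            io.read_fasta(region)
    assert rec.circular and len(anns) == 11 and len(primers) == 11
    assert set(sd.default_taxa()) <= set(pedigree.varieties)
    truth = json.loads((out / "truth.json").read_text())
    assert truth["seed"] == 12 and truth["tree_newick"]
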