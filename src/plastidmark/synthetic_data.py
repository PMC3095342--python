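"""Synthetic plastome, lesion-cohort and pedigree simulators.

Everything the pipeline consumes can be generated here with
machine-readable ground truth: structured circular plastomes (LSC + IRb
+ SSC + IRa with an exactly planted inverted repeat), an ndh gene panel
of valid ORFs, per-variety gene lesions (segmental deletions,
frame-shifting indels, premature-stop substitutions, whole-gene loss),
and marker-region sequence sets evolved with strictly maternal
inheritance along a known hybridization pedigree.

Defaults are the study conditions the pipeline targets: a 146,484 bp
genome (82,324 / 25,755 / 12,650 structure), 37.32% GC, an 11-locus
ndhA-ndhK panel, a 15-variety ornamental-orchid-style pedigree with
maternal groups of size 4, 6 and 3 plus two singletons, and eight
marker regions totalling 7,042 bp (the two most variable spacers,
trnH-psbA and trnF-ndhJ, totalling 1,846 bp).

The planted IR boundaries are made non-extendable (the flanking bases
are adjusted so the maximal exact inverted repeat is exactly the planted
one); without this, detection would stochastically report a repeat a few
bases longer than constructed.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .core_io import (
    FormatError,
    GeneAnnotation,
    MultipleAlignment,
    Pedigree,
    PedigreeEntry,
    PlastomeRecord,
    PrimerPair,
    UNKNOWN,
    reverse_complement,
    write_annotation_gff3,
    write_fasta,
    write_fasta_strings,
    write_pedigree,
    write_primer_table,
)
from .gene_status import NDH_PANEL, StatusThresholds

__all__ = [
    "GeneSpec",
    "RegionSpec",
    "Lesion",
    "SimConfig",
    "TruthTable",
    "default_gene_panel",
    "default_regions",
    "default_pedigree",
    "default_taxa",
    "default_lesion_spec",
    "simulate_plastome",
    "inject_lesions",
    "variety_regions",
    "simulate_lesioned_cohort",
    "simulate_maternal_pedigree",
    "simulate_alignment_on_tree",
    "emit_fixtures",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

LESION_KINDS = (
    "delete_internal", "delete_terminal_5p", "delete_terminal_3p",
    "insert", "point_stop", "remove_gene",
)


@dataclass(frozen=True)
class GeneSpec:
    """A panel gene: CDS length (incl. stop), region, strand, intron."""

    name: str
    length: int
    region: str = "LSC"
    strand: str = "+"
    intron_length: int = 0

    def __post_init__(self) -> None:
        if self.length % 3 != 0 or self.length < 30:
            raise FormatError(f"{self.name}: CDS length must be a multiple of 3, >= 30")
        if self.region not in ("LSC", "SSC"):
            raise FormatError(f"{self.name}: region must be LSC or SSC")


@dataclass(frozen=True)
class RegionSpec:
    """A marker region: alignment-ready locus with a rate multiplier."""

    name: str
    length: int
    rate_multiplier: float = 1.0


@dataclass(frozen=True)
class Lesion:
    """One pseudogenizing lesion applied to one gene of one variety."""

    variety: str
    gene: str
    kind: str
    length: int = 0  # bp for deletions/insertions; stop count for point_stop

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise FormatError(f"unknown lesion kind {self.kind!r}")
        if self.kind != "remove_gene" and self.length <= 0:
            raise FormatError(f"{self.kind} lesion requires a positive length/count")


def default_gene_panel() -> list[GeneSpec]:
    """ndhA-ndhK with realistic CDS lengths; ndhA/ndhB carry one intron."""
    return [
        GeneSpec("ndhA", 1092, "SSC", "+", intron_length=240),
        GeneSpec("ndhB", 1533, "LSC", "+", intron_length=300),
        GeneSpec("ndhC", 363, "LSC", "+"),
        GeneSpec("ndhD", 1503, "SSC", "-"),
        GeneSpec("ndhE", 306, "SSC", "-"),
        GeneSpec("ndhF", 2241, "SSC", "-"),
        GeneSpec("ndhG", 531, "SSC", "-"),
        GeneSpec("ndhH", 1182, "SSC", "-"),
        GeneSpec("ndhI", 504, "SSC", "-"),
        GeneSpec("ndhJ", 477, "LSC", "+"),
        GeneSpec("ndhK", 678, "LSC", "+"),
    ]


def default_regions() -> list[RegionSpec]:
    """Eight marker regions, 7,042 bp total; spacer pair = 1,846 bp.

    Rate multipliers reflect the usual variability ranking: the
    trnH-psbA and trnF-ndhJ spacers most variable, matK next, rbcL
    nearly invariant.
    """
    return [
        RegionSpec("trnH-psbA", 800, 3.0),
        RegionSpec("trnF-ndhJ", 1046, 2.5),
        RegionSpec("ycf1-trnR", 1105, 1.0),
        RegionSpec("matK", 791, 1.5),
        RegionSpec("accD", 900, 0.7),
        RegionSpec("rbcL", 900, 0.2),
        RegionSpec("rpoB", 800, 0.5),
        RegionSpec("rpoC1", 700, 0.5),
    ]


def default_taxa() -> list[str]:
    """The 15 sampled varieties of the default pedigree."""
    return [
        "Onc_GowerRamsey", "Onc_GR_LemonHeart", "Onc_GR_Sunkiss",
        "Onc_SweetSugar", "Bllra_Eurostar", "Bllra_PeggyRuthCarpenter",
        "Bllra_Marfitch", "Bllra_TahomaGlacier", "Bllra_SmileEri",
        "Dgmra_FlyingHigh", "Odm_MargareteHolm", "Odm_ViolettaVonHolm",
        "Odcdm_GoldenGate", "Odcdm_Wildcat", "Zcdm_LittleAngel",
    ]


def default_pedigree() -> Pedigree:
    """A 15-variety commercial-orchid-style pedigree.

    Maternal groups among the sampled varieties: four Oncidium tracing to
    Onc_Goldiana, six Brassia-line varieties (five Beallara plus a
    Degarmoara, via two Miltassia mothers) tracing to Brassia_verrucosa,
    three tracing to Odm_bictoniense, and two singleton lineages.
    """
    E = PedigreeEntry
    return Pedigree([
        # intermediate mothers
        E("Onc_Aloha", "Onc_Goldiana", "Onc_StarWars"),
        E("Mtssa_CharlesMFitch", "Brassia_verrucosa", "Milt_spectabilis"),
        E("Mtssa_JetSetter", "Brassia_verrucosa", "Milt_Cartagena"),
        # sampled varieties
        E("Onc_GowerRamsey", "Onc_Goldiana", "Onc_GuineaGold"),
        E("Onc_GR_LemonHeart", "Onc_GowerRamsey", UNKNOWN),
        E("Onc_GR_Sunkiss", "Onc_GowerRamsey", UNKNOWN),
        E("Onc_SweetSugar", "Onc_Aloha", "Onc_VaricosumMillion"),
        E("Bllra_Eurostar", "Mtssa_CharlesMFitch", "Oda_Florence"),
        E("Bllra_PeggyRuthCarpenter", "Mtssa_CharlesMFitch", "Oda_Memoria"),
        E("Bllra_Marfitch", "Mtssa_CharlesMFitch", "Oda_Crowborough"),
        E("Bllra_TahomaGlacier", "Mtssa_CharlesMFitch", "Oda_PoggioGaiella"),
        E("Bllra_SmileEri", "Mtssa_CharlesMFitch", "Oda_Aviemore"),
        E("Dgmra_FlyingHigh", "Mtssa_JetSetter", "Odm_Harvengtense"),
        E("Odm_MargareteHolm", "Odm_bictoniense", "Odm_Crispum"),
        E("Odm_ViolettaVonHolm", "Odm_bictoniense", "Odm_Pescatorei"),
        E("Odcdm_GoldenGate", "Odm_bictoniense", "Onc_Incurvum"),
        E("Odcdm_Wildcat", "Odm_crispum_line", "Onc_Tigrinum"),
        E("Zcdm_LittleAngel", "Zelenkoa_onusta", "Onc_Cheirophorum"),
    ])


def default_lesion_spec(taxa: Optional[Sequence[str]] = None) -> list[Lesion]:
    """A survey-shaped lesion table: ndhK lost and ndhJ truncated in all
    varieties, the classic 17 bp ndhC deletion, three ndhG internal
    stops (with a larger ndhG deletion in the Beallara group), varied
    ndhE lesions, and assorted ndhD truncations."""
    taxa = list(taxa) if taxa is not None else default_taxa()
    lesions: list[Lesion] = []
    for t in taxa:
        lesions.append(Lesion(t, "ndhK", "remove_gene"))
        lesions.append(Lesion(t, "ndhJ", "delete_terminal_3p", 190))
        lesions.append(Lesion(t, "ndhC", "delete_internal", 17))
        if t.startswith("Bllra"):
            lesions.append(Lesion(t, "ndhG", "delete_internal", 250))
            lesions.append(Lesion(t, "ndhE", "delete_internal", 36))
            lesions.append(Lesion(t, "ndhD", "delete_terminal_3p", 400))
        else:
            lesions.append(Lesion(t, "ndhG", "point_stop", 3))
            lesions.append(Lesion(t, "ndhD", "delete_terminal_5p", 400))
        if t == "Dgmra_FlyingHigh":
            lesions.append(Lesion(t, "ndhE", "delete_internal", 30))
        if t.startswith("Odcdm"):
            lesions.append(Lesion(t, "ndhE", "insert", 1))
        lesions.append(Lesion(t, "ndhB", "point_stop", 1))
    return lesions


@dataclass
class SimConfig:
    """All generator knobs, with study-condition defaults."""

    seed: int = 0
    structure_lengths: tuple[int, int, int] = (82324, 25755, 12650)
    gc: float = 0.3732
    gene_panel: list[GeneSpec] = field(default_factory=default_gene_panel)
    lesion_spec: list[Lesion] = field(default_factory=list)
    taxa: list[str] = field(default_factory=default_taxa)
    pedigree: Pedigree = field(default_factory=default_pedigree)
    regions: list[RegionSpec] = field(default_factory=default_regions)
    per_generation_rate: float = 0.02  # substitutions/site per cross
    founder_divergence: float = 0.05   # founder drift from the common ancestor
    indel_rate: float = 0.0            # pedigree indels off: distances stay exact
    flank: int = 100                   # bp of context around extracted gene regions

    def __post_init__(self) -> None:
        lsc, ir, ssc = self.structure_lengths
        if min(lsc, ir, ssc) <= 0:
            raise FormatError("structure lengths must be positive")
        if lsc < ssc:
            raise FormatError("LSC must be at least as long as SSC")
        for r in (self.per_generation_rate, self.founder_divergence, self.indel_rate):
            if r < 0:
                raise FormatError("rates must be >= 0")

    @property
    def genome_length(self) -> int:
        lsc, ir, ssc = self.structure_lengths
        return lsc + 2 * ir + ssc


@dataclass
class TruthTable:
    """Generator ground truth: expected status per (variety, gene),
    maternal lineage per taxon, and the generating maternal tree."""

    cells: dict[tuple[str, str], dict] = field(default_factory=dict)
    lineage: dict[str, str] = field(default_factory=dict)
    tree_newick: Optional[str] = None
    seed: Optional[int] = None

    def expected_category(self, variety: str, gene: str) -> str:
        return self.cells[(variety, gene)]["category"]

    def to_json(self, path) -> None:
        payload = {
            "cells": [
                {"variety": v, "gene": g, **info}
                for (v, g), info in sorted(self.cells.items())
            ],
            "lineage": self.lineage,
            "tree_newick": self.tree_newick,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _codon_weights(gc: float) -> np.ndarray:
    """Sense-codon sampling weights matching a target base composition."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in _SENSE_CODONS])
    return w / w.sum()


def _random_orf(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    n_codons = length // 3
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2, p=_codon_weights(gc))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


# ---------------------------------------------------------------------------
# Plastome simulation
# ---------------------------------------------------------------------------

def _layout_genes(panel, region_start, region_len, rng, gc, margin=250, spacer=320):
    """Place genes left-to-right in a region; returns annotations and the
    (position -> sequence) overwrites, or raises if they do not fit."""
    overwrites = []
    annotations = []
    cur = region_start + margin
    end_limit = region_start + region_len - margin
    for spec in panel:
        orf = _random_orf(rng, spec.length, gc)
        if spec.strand == "-":
            genomic = reverse_complement(orf)
        else:
            genomic = orf
        if spec.intron_length:
            # split the genomic sequence into two exons around an intron
            half = (len(genomic) // 2) // 3 * 3
            exon1 = genomic[:half]
            exon2 = genomic[half:]
            intron = _random_dna(rng, spec.intron_length, gc)
            total = len(exon1) + len(intron) + len(exon2)
            exons = [
                (cur, cur + len(exon1)),
                (cur + len(exon1) + len(intron), cur + total),
            ]
            overwrites.append((cur, exon1 + intron + exon2))
        else:
            total = len(genomic)
            exons = [(cur, cur + total)]
            overwrites.append((cur, genomic))
        if cur + total > end_limit:
            raise FormatError(
                f"gene panel does not fit in {spec.region} "
                f"(need past {cur + total}, limit {end_limit})"
            )
        annotations.append(GeneAnnotation(spec.name, "CDS", spec.strand, exons))
        cur += total + spacer
    return annotations, overwrites


def simulate_plastome(cfg: SimConfig) -> tuple[PlastomeRecord, list[GeneAnnotation]]:
    """Simulate a quadripartite circular plastome with a planted IR.

    Single-copy regions are random sequence at the configured GC; the IR
    is planted exactly (IRa = revcomp(IRb)); panel genes are placed as
    valid ORFs (start codon, sense codons, terminal stop under the
    plastid/bacterial code) in their assigned single-copy regions.
    """
    lsc_len, ir_len, ssc_len = cfg.structure_lengths
    rng = _stage_rng(cfg.seed, "plastome")
    lsc = list(_random_dna(rng, lsc_len, cfg.gc))
    ir = _random_dna(rng, ir_len, cfg.gc)
    ssc = list(_random_dna(rng, ssc_len, cfg.gc))

    lsc_panel = [g for g in cfg.gene_panel if g.region == "LSC"]
    ssc_panel = [g for g in cfg.gene_panel if g.region == "SSC"]
    annotations = []
    for panel, target, start, length in (
        (lsc_panel, lsc, 0, lsc_len),
        (ssc_panel, ssc, lsc_len + ir_len, ssc_len),
    ):
        anns, overwrites = _layout_genes(panel, start, length, rng, cfg.gc)
        annotations.extend(anns)
        for pos, seq in overwrites:
            rel = pos - start
            target[rel : rel + len(seq)] = list(seq)

    genome = "".join(lsc) + ir + "".join(ssc) + reverse_complement(ir)
    genome = list(genome)
    L = len(genome)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # make the planted IR non-extendable at all four junctions
    irb_start, irb_end = lsc_len, lsc_len + ir_len
    ira_start = lsc_len + ir_len + ssc_len
    if genome[irb_start - 1] == comp[genome[0]]:  # last LSC base vs first base
        choices = [b for b in "ACGT" if b != comp[genome[0]]]
        genome[irb_start - 1] = choices[int(rng.integers(len(choices)))]
    if genome[irb_end] == comp[genome[ira_start - 1]]:  # SSC flanks
        choices = [b for b in "ACGT" if b != comp[genome[ira_start - 1]]]
        genome[irb_end] = choices[int(rng.integers(len(choices)))]
    record = PlastomeRecord("synthetic_plastome", "".join(genome), circular=True)
    annotations.sort(key=lambda a: a.start)
    return record, annotations


# ---------------------------------------------------------------------------
# Lesion injection
# ---------------------------------------------------------------------------

def _reading_to_genome_segments(ann: GeneAnnotation, a: int, b: int) -> list[tuple[int, int]]:
    """Genome intervals (ascending) covering spliced reading positions [a, b)."""
    segs = []
    off = 0
    exons = ann.exons if ann.strand == "+" else list(reversed(ann.exons))
    for (s, e) in exons:
        l = e - s
        lo, hi = max(a, off), min(b, off + l)
        if lo < hi:
            if ann.strand == "+":
                segs.append((s + lo - off, s + hi - off))
            else:
                segs.append((e - (hi - off), e - (lo - off)))
        off += l
    return sorted(segs)


def _expected_category(lesion: Lesion, gene_len: int,
                       thresholds: StatusThresholds) -> str:
    """The category the classifier's precedence rules imply for a lesion."""
    if lesion.kind == "remove_gene":
        return "absent"
    if lesion.kind in ("delete_terminal_5p", "delete_terminal_3p"):
        coverage = 1.0 - lesion.length / gene_len
        if coverage <= thresholds.absent_max_coverage:
            return "absent"
        if lesion.length / gene_len >= 1.0 - thresholds.truncated_max_coverage:
            return "truncated"
        return "functional"
    if lesion.kind in ("delete_internal", "insert"):
        return "frame_disrupted"
    if lesion.kind == "point_stop":
        return "internal_stop"
    raise FormatError(f"unknown lesion kind {lesion.kind!r}")


def inject_lesions(
    record: PlastomeRecord,
    annotations: Sequence[GeneAnnotation],
    lesion_spec: Sequence[Lesion],
    seed: int = 0,
    thresholds: Optional[StatusThresholds] = None,
) -> tuple[PlastomeRecord, list[GeneAnnotation], TruthTable]:
    """Apply lesions to one genome; return the mutated genome, remapped
    annotations, and the expected-category truth table.

    At most one lesion per gene (composite lesions are rejected); the
    expected category is derived with the same precedence rules the
    classifier applies, so the truth table is self-consistent with the
    thresholds in force.
    """
    th = thresholds or StatusThresholds()
    rng = _stage_rng(seed, "lesions")
    by_gene = {a.gene: a for a in annotations}
    seen = set()
    for lesion in lesion_spec:
        if lesion.gene not in by_gene:
            raise FormatError(f"lesion references unknown gene {lesion.gene!r}")
        if lesion.gene in seen:
            raise FormatError(f"multiple lesions on gene {lesion.gene!r}")
        seen.add(lesion.gene)

    edits: list[tuple[int, int, str]] = []  # (pos, del_len, insert)
    removed: dict[str, int] = {}  # gene -> original start of removed span
    truth = TruthTable(seed=seed)
    variety = lesion_spec[0].variety if lesion_spec else ""

    for lesion in lesion_spec:
        ann = by_gene[lesion.gene]
        glen = ann.spliced_length
        if lesion.kind != "remove_gene" and lesion.kind != "point_stop":
            if lesion.length >= glen - 6:
                raise FormatError(
                    f"{lesion.gene}: lesion length {lesion.length} too large for gene"
                )
        if lesion.kind == "remove_gene":
            edits.append((ann.start, ann.end - ann.start, ""))
            removed[lesion.gene] = ann.start
        elif lesion.kind == "delete_internal":
            margin = 30
            lo, hi = margin, glen - margin - lesion.length
            if hi <= lo:
                raise FormatError(f"{lesion.gene}: no room for internal deletion")
            a = int(rng.integers(lo, hi))
            for s, e in _reading_to_genome_segments(ann, a, a + lesion.length):
                edits.append((s, e - s, ""))
        elif lesion.kind == "delete_terminal_5p":
            for s, e in _reading_to_genome_segments(ann, 0, lesion.length):
                edits.append((s, e - s, ""))
        elif lesion.kind == "delete_terminal_3p":
            for s, e in _reading_to_genome_segments(ann, glen - lesion.length, glen):
                edits.append((s, e - s, ""))
        elif lesion.kind == "insert":
            a = int(rng.integers(30, glen - 30))
            segs = _reading_to_genome_segments(ann, a, a + 1)
            ins = _random_dna(rng, lesion.length, 0.5)
            edits.append((segs[0][0], 0, ins))
        elif lesion.kind == "point_stop":
            n_codons = glen // 3
            candidates = list(range(2, n_codons - 2))
            picked: list[int] = []
            rng.shuffle(candidates)
            for c in candidates:
                segs = _reading_to_genome_segments(ann, 3 * c, 3 * c + 3)
                if len(segs) != 1:
                    continue  # codon crosses an exon boundary
                picked.append(c)
                if len(picked) == lesion.length:
                    break
            if len(picked) < lesion.length:
                raise FormatError(f"{lesion.gene}: not enough codons for stops")
            for c in picked:
                (s, e), = _reading_to_genome_segments(ann, 3 * c, 3 * c + 3)
                stop = "TAA" if ann.strand == "+" else reverse_complement("TAA")
                edits.append((s, 3, stop))
        truth.cells[(variety, lesion.gene)] = {
            "category": _expected_category(lesion, glen, th),
            "lesion": lesion.kind,
            "length": lesion.length,
        }

    # untouched panel genes are functional by construction
    for gene in by_gene:
        truth.cells.setdefault((variety, gene), {"category": "functional",
                                                 "lesion": None, "length": 0})

    edits.sort()
    for (p1, d1, _), (p2, d2, _) in zip(edits, edits[1:]):
        if p1 + d1 > p2:
            raise FormatError("overlapping lesion edits")

    seq = record.sequence
    for pos, dlen, ins in reversed(edits):
        seq = seq[:pos] + ins + seq[pos + dlen :]

    def remap(c: int) -> int:
        delta = 0
        for pos, dlen, ins in edits:
            if c >= pos + dlen:
                delta += len(ins) - dlen
            elif c > pos:
                return pos + delta
            else:
                break
        return c + delta

    new_annotations = []
    for ann in annotations:
        if ann.gene in removed:
            continue
        exons = [(remap(s), remap(e)) for s, e in ann.exons]
        exons = [(s, e) for s, e in exons if e > s]
        new_annotations.append(GeneAnnotation(ann.gene, ann.feature_type, ann.strand, exons, ann.copy))

    new_record = PlastomeRecord(record.id, seq, circular=record.circular)
    truth.lineage = {}
    # remember removed-gene junctions for region extraction
    for gene, old_start in removed.items():
        truth.cells[(variety, gene)]["junction"] = remap(old_start)
    return new_record, new_annotations, truth


def variety_regions(
    record: PlastomeRecord,
    annotations: Sequence[GeneAnnotation],
    panel: Sequence[str],
    flank: int = 100,
    junctions: Optional[dict[str, int]] = None,
) -> dict[str, str]:
    """Extract per-locus query regions: spliced gene sequence with
    ``flank`` bp of context, in reading orientation.

    For genes no longer present, the sequence around the deletion
    junction (if known) is returned -- it contains no gene sequence and
    classifies as absent.
    """
    by_gene = {a.gene: a for a in annotations}
    junctions = junctions or {}
    out = {}
    for gene in panel:
        ann = by_gene.get(gene)
        if ann is None:
            j = junctions.get(gene)
            if j is None:
                continue  # locus yields nothing at all -> no_data upstream
            out[gene] = record.fetch(max(j - flank, 0), min(j + flank, len(record)))
            continue
        up = record.fetch(max(ann.start - flank, 0), ann.start)
        down = record.fetch(ann.end, min(ann.end + flank, len(record)))
        core = ann.spliced_sequence(record)
        if ann.strand == "+":
            out[gene] = up + core + down
        else:
            out[gene] = reverse_complement(down) + core + reverse_complement(up)
    return out


def simulate_lesioned_cohort(
    cfg: SimConfig,
) -> tuple[list[tuple[str, dict[str, str]]], dict[str, str], TruthTable]:
    """Simulate a cohort of varieties carrying per-variety gene lesions.

    Returns (varieties as (name, gene->region) pairs, reference CDS per
    gene from the unlesioned base genome, merged truth table).  When
    ``cfg.lesion_spec`` is empty the default survey-shaped spec is used.
    """
    base, annotations = simulate_plastome(cfg)
    references = {
        a.gene: a.spliced_sequence(base) for a in annotations
    }
    lesions = cfg.lesion_spec or default_lesion_spec(cfg.taxa)
    by_variety: dict[str, list[Lesion]] = {}
    for l in lesions:
        by_variety.setdefault(l.variety, []).append(l)
    panel = [g.name for g in cfg.gene_panel]
    varieties = []
    truth = TruthTable(seed=cfg.seed)
    for i, name in enumerate(cfg.taxa):
        spec = by_variety.get(name, [])
        mutated, new_anns, t = inject_lesions(
            base, annotations, spec, seed=cfg.seed * 1000 + i
        )
        junctions = {
            g: info["junction"]
            for (v, g), info in t.cells.items()
            if "junction" in info
        }
        regions = variety_regions(mutated, new_anns, panel, cfg.flank, junctions)
        varieties.append((name, regions))
        for (_, gene), info in t.cells.items():
            truth.cells[(name, gene)] = info
    return varieties, references, truth


# ---------------------------------------------------------------------------
# Maternal pedigree simulation
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return seq
    L = len(seq)
    n = rng.binomial(L, min(rate, 0.75))
    if n == 0:
        return seq
    positions = rng.choice(L, size=n, replace=False)
    out = list(seq)
    for p in positions:
        cur = out[p]
        alternatives = [b for b in "ACGT" if b != cur]
        out[p] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _maternal_tree_newick(pedigree: Pedigree, taxa: Sequence[str]) -> str:
    """Newick for the maternal genealogy restricted to the sampled taxa."""
    taxa_set = set(taxa)
    children: dict[str, list[str]] = {}
    for e in pedigree.entries:
        if e.female_parent != UNKNOWN:
            children.setdefault(e.female_parent, []).append(e.variety)

    def subtree(name: str) -> Optional[str]:
        parts = [s for s in (subtree(k) for k in children.get(name, [])) if s]
        if name in taxa_set:
            parts.append(name)
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    founders = sorted(
        {pedigree.maternal_founder(t) for t in taxa}
    )
    tops = [s for s in (subtree(f) for f in founders) if s]
    return "(" + ",".join(tops) + ");"


def simulate_maternal_pedigree(
    cfg: SimConfig,
) -> tuple[dict[str, dict[str, str]], Pedigree, TruthTable]:
    """Evolve marker-region sequences along the pedigree's female lines.

    Founders drift independently (star-like) from one ancestral region
    set at ``founder_divergence`` subs/site; each hybrid's regions are a
    mutated copy of its female parent's at ``per_generation_rate``
    subs/site; the male parent contributes nothing.  Per-region rates
    are scaled by the region's rate multiplier.  Returns
    (taxon -> region -> sequence, pedigree, truth) where truth carries
    the maternal lineage ids and the generating maternal tree.
    """
    rng = _stage_rng(cfg.seed, "pedigree")
    pedigree = cfg.pedigree
    ancestral = {
        r.name: _random_dna(rng, r.length, cfg.gc) for r in cfg.regions
    }
    mult = {r.name: r.rate_multiplier for r in cfg.regions}

    founders = sorted({pedigree.maternal_founder(t) for t in pedigree.varieties})
    seqs: dict[str, dict[str, str]] = {}
    for f in founders:
        seqs[f] = {
            name: _mutate(s, cfg.founder_divergence * mult[name], rng)
            for name, s in ancestral.items()
        }

    # process entries mothers-first (pedigree is acyclic)
    pending = [e for e in pedigree.entries if e.variety not in seqs]
    while pending:
        progressed = False
        remaining = []
        for e in pending:
            mother = e.female_parent if e.female_parent != UNKNOWN else e.variety
            if mother == e.variety:  # founder-less entry: its own founder
                continue
            if mother in seqs:
                seqs[e.variety] = {
                    name: _mutate(s, cfg.per_generation_rate * mult[name], rng)
                    for name, s in seqs[mother].items()
                }
                progressed = True
            else:
                remaining.append(e)
        pending = remaining
        if pending and not progressed:
            raise FormatError("unresolvable pedigree ordering")

    taxa = [t for t in cfg.taxa if t in seqs]
    missing = set(cfg.taxa) - set(taxa)
    if missing:
        raise FormatError(f"taxa without pedigree-derived sequences: {sorted(missing)}")
    truth = TruthTable(
        lineage={t: pedigree.maternal_founder(t) for t in cfg.taxa},
        tree_newick=_maternal_tree_newick(pedigree, cfg.taxa),
        seed=cfg.seed,
    )
    return {t: seqs[t] for t in cfg.taxa}, pedigree, truth


def simulate_alignment_on_tree(
    newick: str, length: int, seed: int = 0, gc: float = 0.4
) -> MultipleAlignment:
    """Evolve a gap-free alignment along a tree with branch lengths in
    substitutions/site (Jukes-Cantor-style site-independent mutation)."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    rng = _stage_rng(seed, "tree_sim")
    root_seq = _random_dna(rng, length, gc)
    rows: dict[str, str] = {}

    def walk(node, seq):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_seq = _mutate(seq, bl, rng)
            if child.is_leaf():
                rows[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root_seq)
    taxa = sorted(rows)
    return MultipleAlignment(taxa, [rows[t] for t in taxa])


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def emit_fixtures(cfg: SimConfig, outdir) -> dict:
    """Write a complete fixture set and a checksum manifest.

    Emits the base plastome (FASTA + GFF3), a primer panel flanking every
    panel gene, the pedigree TSV, per-region taxon FASTAs from the
    maternal simulation, the truth JSON and a manifest TSV.  Re-running
    with the same config yields byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    record, annotations = simulate_plastome(cfg)
    write_fasta([record], out / "genome.fasta")
    write_annotation_gff3(annotations, out / "genome.gff3", record.id)

    flank = cfg.flank
    primers = []
    for ann in annotations:
        fwd = record.fetch(ann.start - flank - 20, ann.start - flank)
        rev = reverse_complement(record.fetch(ann.end + flank, ann.end + flank + 20))
        expected = (ann.end + flank + 20) - (ann.start - flank - 20)
        primers.append(PrimerPair(ann.gene, fwd, rev, expected))
    write_primer_table(primers, out / "primers.tsv")

    write_pedigree(cfg.pedigree, out / "pedigree.tsv")

    taxon_regions, _, truth = simulate_maternal_pedigree(cfg)
    regions_dir = out / "regions"
    regions_dir.mkdir(exist_ok=True)
    for region in cfg.regions:
        named = {t: taxon_regions[t][region.name] for t in cfg.taxa}
        write_fasta_strings(named, regions_dir / f"{region.name}.fasta")

    truth.to_json(out / "truth.json")

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.tsv"
    )
    manifest_rows = [(str(p.relative_to(out)), _sha256(p)) for p in files]
    with open(out / "manifest.tsv", "w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        fh.write("path\tsha256\n")
        for rel, digest in manifest_rows:
            fh.write(f"{rel}\t{digest}\n")
    return {"seed": cfg.seed, "files": dict(manifest_rows)}
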