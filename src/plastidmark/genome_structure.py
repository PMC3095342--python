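"""Quadripartite plastome structure: IR detection, statistics, PCR tiling.

A typical plastome is a circle of 120-220 kb carrying two exact (or
near-exact) inverted repeats (IRa/IRb) that separate a large and a small
single-copy region (LSC/SSC).  This module finds the longest pair of
exactly reverse-complementary disjoint segments, partitions the genome
around them, computes genome-level composition statistics, and provides
the PCR-walking helpers used to sequence such genomes: an overlapping
amplicon tiling planner and a greedy overlap-layout amplicon assembler.

IR detection uses exact matches only (seed-and-extend over k-mer anchors
against the reverse complement); inverted repeats with internal
mismatches are out of scope.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import (
    FormatError,
    GeneAnnotation,
    PlastomeRecord,
    reverse_complement,
)

__all__ = [
    "NoQuadripartiteStructure",
    "QuadripartitePartition",
    "GenomeStats",
    "TilingPlan",
    "detect_inverted_repeats",
    "partition_lengths",
    "genome_stats",
    "plan_tiling_amplicons",
    "assemble_amplicons",
]


class NoQuadripartiteStructure(ValueError):
    """No inverted repeat of the required length exists: single-copy genome."""


@dataclass
class QuadripartitePartition:
    """The four structural intervals of a plastome.

    Intervals are 0-based half-open ``(start, end)`` with ``end > start``;
    ``end`` may exceed ``genome_length`` for the one region allowed to
    wrap the circular origin (starts are always within ``[0, L)``).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def __post_init__(self) -> None:
        lengths = [e - s for s, e in (self.lsc, self.irb, self.ssc, self.ira)]
        if any(l <= 0 for l in lengths):
            raise FormatError("empty partition interval")
        if sum(lengths) != self.genome_length:
            raise FormatError(
                f"partition lengths {lengths} do not sum to genome length "
                f"{self.genome_length}"
            )
        if lengths[1] != lengths[3]:
            raise FormatError(
                f"asymmetric inverted repeats: |IRb|={lengths[1]} != |IRa|={lengths[3]}"
            )
        if lengths[0] < lengths[2]:
            raise FormatError("|LSC| must be >= |SSC|")

    @property
    def lengths(self) -> tuple[int, int, int, int]:
        return tuple(e - s for s, e in (self.lsc, self.irb, self.ssc, self.ira))

    def region_sequences(self, record: PlastomeRecord) -> dict[str, str]:
        return {
            name: record.fetch(s, e)
            for name, (s, e) in zip(
                ("LSC", "IRb", "SSC", "IRa"), (self.lsc, self.irb, self.ssc, self.ira)
            )
        }

    def validate_against(self, record: PlastomeRecord) -> None:
        """Assert IRa equals the reverse complement of IRb on ``record``."""
        seqs = self.region_sequences(record)
        if seqs["IRa"] != reverse_complement(seqs["IRb"]):
            raise FormatError("IRa is not the reverse complement of IRb")


def partition_lengths(p: QuadripartitePartition) -> tuple[int, int, int, int, int]:
    """(lsc, irb, ssc, ira, total) lengths in bp."""
    lsc, irb, ssc, ira = p.lengths
    return lsc, irb, ssc, ira, lsc + irb + ssc + ira


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _maximal_ir_pairs(seq: str, circular: bool, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal (a_start, b_start, length) pairs with
    seq[b:b+len] == revcomp(seq[a:a+len]), length >= min_len.

    Starts are reported modulo L for circular genomes; segments may wrap.
    """
    L = len(seq)
    k = min(21, max(8, min_len // 4))
    text = seq + seq[: L - 1] if circular else seq
    rc = reverse_complement(seq)

    # Index every k-mer of the reverse complement.
    index: dict[str, list[int]] = {}
    for p in range(L - k + 1):
        index.setdefault(rc[p : p + k], []).append(p)

    def cbase(i: int) -> Optional[str]:
        if circular:
            return seq[i % L]
        return seq[i] if 0 <= i < L else None

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    # Sparse anchors: any inverted repeat of length >= min_len must contain
    # an anchor k-mer starting at a multiple of `step`.
    step = max(1, min_len - k)
    found: dict[tuple[int, int], int] = {}
    for i in range(0, len(text) - k + 1, step):
        for p in index.get(text[i : i + k], ()):
            # rc[p:p+k] corresponds to seq segment [L-p-k, L-p) reversed.
            a, b = i, L - p - k
            # extend left of a / right of b
            ext_l = 0
            while k + ext_l < L:
                x, y = cbase(a - ext_l - 1), cbase(b + k + ext_l)
                if x is None or y is None or comp.get(x) != y:
                    break
                ext_l += 1
            # extend right of a / left of b
            ext_r = 0
            while k + ext_l + ext_r < L:
                x, y = cbase(a + k + ext_r), cbase(b - ext_r - 1)
                if x is None or y is None or comp.get(x) != y:
                    break
                ext_r += 1
            a0, b0 = a - ext_l, b - ext_r
            length = k + ext_l + ext_r
            if length < min_len:
                continue
            key = tuple(sorted((a0 % L, b0 % L)))
            if found.get(key, 0) < length:
                found[key] = length
    return [(a, b, ln) for (a, b), ln in sorted(found.items())]


def detect_inverted_repeats(
    record: PlastomeRecord, min_len: int = 1000
) -> QuadripartitePartition:
    """Partition a plastome into LSC/IRb/SSC/IRa.

    Finds the longest pair of disjoint, exactly reverse-complementary
    segments of length >= ``min_len`` (rotation-invariant on circular
    genomes), assigns the larger single-copy gap as LSC, and orients the
    quadripartite order LSC -> IRb -> SSC -> IRa.

    Raises :class:`NoQuadripartiteStructure` when no such repeat exists.
    """
    L = len(record)
    if L < 4 * min_len:
        raise ValueError(f"genome length {L} < 4 x min_len {min_len}")
    pairs = _maximal_ir_pairs(record.sequence, record.circular, min_len)

    candidates = []
    for a, b, length in pairs:
        # single-copy gaps on the circle (a linearized record closes cyclically)
        ga = (b - (a + length)) % L
        gb = (a - (b + length)) % L
        if ga + gb + 2 * length != L:
            continue  # overlapping segments
        if ga == 0 and gb == 0:
            continue  # genome is one giant palindrome; no single-copy regions
        candidates.append((a, b, length, ga, gb))
    if not candidates:
        raise NoQuadripartiteStructure(
            f"no exact inverted repeat of length >= {min_len}"
        )

    def sort_key(c):
        a, b, length, ga, gb = c
        ssc = min(ga, gb)
        return (-length, ssc, min(a, b))

    a, b, length, ga, gb = min(candidates, key=sort_key)
    # Quadripartite order: ... IRb -> SSC -> IRa -> LSC ...  The smaller gap
    # is the SSC and sits between IRb and IRa.
    if ga <= gb:
        irb_start, ira_start, ssc_len, lsc_len = a, b, ga, gb
    else:
        irb_start, ira_start, ssc_len, lsc_len = b, a, gb, ga
    irb = (irb_start, irb_start + length)
    ssc_start = (irb_start + length) % L
    ssc = (ssc_start, ssc_start + ssc_len)
    ira = ((ssc_start + ssc_len) % L, (ssc_start + ssc_len) % L + length)
    lsc_start = (ira[0] + length) % L
    lsc = (lsc_start, lsc_start + lsc_len)
    part = QuadripartitePartition(lsc, irb, ssc, ira, L)
    part.validate_against(record)
    return part


# ---------------------------------------------------------------------------
# Genome statistics
# ---------------------------------------------------------------------------

@dataclass
class GenomeStats:
    """Composition and gene-content statistics of an annotated plastome.

    Fractions are percentages.  Conservation identities are enforced:
    gc + at = 100, protein_coding + rna = coding, coding + noncoding = 100.
    """

    gc_fraction: float
    at_fraction: float
    coding_fraction: float
    protein_coding_fraction: float
    rna_fraction: float
    noncoding_fraction: float
    n_distinct_genes: int
    n_ir_duplicated: int
    n_total_genes: int
    n_distinct_trnas: int
    n_intron_genes: int

    def __post_init__(self) -> None:
        if abs(self.gc_fraction + self.at_fraction - 100.0) > 1e-9:
            raise FormatError("gc + at must equal 100")
        if abs(self.protein_coding_fraction + self.rna_fraction - self.coding_fraction) > 1e-9:
            raise FormatError("protein + rna must equal coding")
        if abs(self.coding_fraction + self.noncoding_fraction - 100.0) > 1e-9:
            raise FormatError("coding + noncoding must equal 100")
        for name in ("n_distinct_genes", "n_ir_duplicated", "n_total_genes",
                     "n_distinct_trnas", "n_intron_genes"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be >= 0")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _interval_union(intervals: list[tuple[int, int]], L: int, circular: bool) -> int:
    """Total bp covered by a union of (possibly wrapping) intervals."""
    flat = []
    for s, e in intervals:
        if e > L:
            if not circular:
                raise FormatError(f"exon [{s},{e}) outside linear genome of length {L}")
            flat.extend([(s, L), (0, e - L)])
        else:
            flat.append((s, e))
    covered = np.zeros(L, dtype=bool)
    for s, e in flat:
        if s < 0 or e > L:
            raise FormatError(f"exon [{s},{e}) outside genome of length {L}")
        covered[s:e] = True
    return int(covered.sum())


def _coding_masks(annotations, L, circular):
    cds = np.zeros(L, dtype=bool)
    rna = np.zeros(L, dtype=bool)
    for ann in annotations:
        target = cds if ann.feature_type == "CDS" else rna
        for s, e in ann.exons:
            if e > L:
                if not circular:
                    raise FormatError(f"{ann.gene}: exon outside linear genome")
                target[s:L] = True
                target[0 : e - L] = True
            else:
                if s < 0 or e > L:
                    raise FormatError(f"{ann.gene}: exon outside genome")
                target[s:e] = True
    return cds, rna


def _within(interval: tuple[int, int], region: tuple[int, int], L: int) -> bool:
    """Is (start,end) inside the (possibly wrapping) region interval?"""
    s, e = interval
    rs, re = region
    off = (s - rs) % L
    return off + (e - s) <= (re - rs)


def genome_stats(
    record: PlastomeRecord,
    partition: Optional[QuadripartitePartition],
    annotations: Sequence[GeneAnnotation],
) -> GenomeStats:
    """Compute composition and gene-content statistics.

    GC is computed over the whole genome with N excluded from numerator
    and denominator.  The coding fraction is the union of exon intervals
    over the genome length, with the protein (CDS) component measured
    first and the RNA component defined as coding minus protein so the
    decomposition is exact even where features overlap.  A gene counts as
    IR-duplicated when it is annotated twice with one copy inside each
    inverted repeat (or when both copies carry the IR_duplicate flag).
    """
    L = len(record)
    seq = record.sequence
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise FormatError("sequence has no unambiguous bases")
    gc_fraction = 100.0 * gc / (gc + at)

    cds_mask, rna_mask = _coding_masks(annotations, L, record.circular)
    coding = int((cds_mask | rna_mask).sum())
    protein = int(cds_mask.sum())
    coding_fraction = 100.0 * coding / L
    protein_fraction = 100.0 * protein / L
    rna_fraction = coding_fraction - protein_fraction

    by_gene: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_gene.setdefault(ann.gene, []).append(ann)

    n_distinct = len(by_gene)
    n_ir_dup = 0
    for gene, anns in by_gene.items():
        if len(anns) < 2:
            continue
        if all(a.copy == "IR_duplicate" for a in anns):
            n_ir_dup += 1
            continue
        if partition is not None:
            spans = [(a.start, a.end) for a in anns]
            in_irb = any(_within(sp, partition.irb, L) for sp in spans)
            in_ira = any(_within(sp, partition.ira, L) for sp in spans)
            if in_irb and in_ira:
                n_ir_dup += 1
    n_total = n_distinct + n_ir_dup
    n_trnas = len({g for g, anns in by_gene.items() if anns[0].feature_type == "tRNA"})
    n_intron = len({g for g, anns in by_gene.items() if any(len(a.exons) > 1 for a in anns)})

    return GenomeStats(
        gc_fraction=gc_fraction,
        at_fraction=100.0 - gc_fraction,
        coding_fraction=coding_fraction,
        protein_coding_fraction=protein_fraction,
        rna_fraction=rna_fraction,
        noncoding_fraction=100.0 - coding_fraction,
        n_distinct_genes=n_distinct,
        n_ir_duplicated=n_ir_dup,
        n_total_genes=n_total,
        n_distinct_trnas=n_trnas,
        n_intron_genes=n_intron,
    )


# ---------------------------------------------------------------------------
# PCR tiling planner
# ---------------------------------------------------------------------------

@dataclass
class TilingPlan:
    """Overlapping amplicons covering an interval for PCR walking."""

    interval: tuple[int, int]
    amplicons: list[tuple[int, int]]
    target_len: int
    overlap: int

    @property
    def overlaps(self) -> list[int]:
        """Realized overlap of each amplicon with its predecessor."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.amplicons, self.amplicons[1:]):
            out.append(e0 - s1)
        return out

    def to_bed(self, path, chrom: str) -> None:
        with open(path, "w") as fh:
            for i, (s, e) in enumerate(self.amplicons):
                fh.write(f"{chrom}\t{s}\t{e}\tamplicon_{i + 1}\n")


def plan_tiling_amplicons(
    interval: tuple[int, int], target_len: int = 2500, overlap: int = 200
) -> TilingPlan:
    """Plan a series of overlapping PCR amplicons covering ``interval``.

    Amplicons of ``target_len`` bp step by ``target_len - overlap`` so
    adjacent products share ``overlap`` bp; the final amplicon is
    truncated to the interval end.  Defaults mirror a 2-3 kb walking
    strategy with ~200 bp overlaps.
    """
    if not (target_len > overlap >= 0):
        raise ValueError("require target_len > overlap >= 0")
    start, end = interval
    L = end - start
    if L <= 0:
        raise ValueError("empty interval")
    if L <= max(overlap, 1) or L <= target_len:
        return TilingPlan(interval, [(start, end)], target_len, overlap)
    step = target_len - overlap
    n = math.ceil((L - overlap) / step)
    amps = []
    for i in range(n):
        s = start + i * step
        e = min(s + target_len, end)
        if i == n - 1:
            e = end
        amps.append((s, e))
    return TilingPlan(interval, amps, target_len, overlap)


# ---------------------------------------------------------------------------
# Amplicon assembly (greedy overlap-layout)
# ---------------------------------------------------------------------------

def _best_suffix_prefix(a: str, b: str, min_overlap: int, min_identity: float,
                        min_score: int) -> Optional[tuple[int, float]]:
    """Longest suffix(a)/prefix(b) overlap meeting identity and score cutoffs.

    Score is +1 per match, -1 per mismatch over the overlap (no indels).
    Returns (overlap_len, identity) or None.
    """
    max_o = min(len(a), len(b))
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    for olen in range(max_o, min_overlap - 1, -1):
        if a[-olen:] == b[:olen]:
            matches = olen
        else:
            matches = int((arr_a[-olen:] == arr_b[:olen]).sum())
        identity = matches / olen
        score = matches - (olen - matches)
        if identity >= min_identity and score >= min_score:
            return olen, identity
    return None


def assemble_amplicons(
    fragments: Sequence[str],
    min_overlap: int = 30,
    min_identity: float = 0.95,
    min_score: int = 40,
) -> list[str]:
    """Greedy assembly of amplicon sequences into contigs.

    Repeatedly merges the fragment pair whose best suffix/prefix overlap
    (either orientation of either fragment) is longest, subject to the
    overlap length, identity and alignment-score cutoffs (match +1,
    mismatch -1 -- an approximation of the original vendor scoring).
    Ties break by longest overlap, then lexicographically smallest
    fragment-id pair, so assembly is deterministic.
    """
    items: dict[str, str] = {f"f{i:04d}": s.upper() for i, s in enumerate(fragments)}
    if not items:
        return []
    while len(items) > 1:
        best = None  # (overlap_len, id_pair, merged_seq)
        ids = sorted(items)
        for ia in ids:
            for ib in ids:
                if ia == ib:
                    continue
                a = items[ia]
                for b, flipped in ((items[ib], False), (reverse_complement(items[ib]), True)):
                    hit = _best_suffix_prefix(a, b, min_overlap, min_identity, min_score)
                    if hit is None:
                        continue
                    olen, _ = hit
                    key = (-olen, ia, ib, flipped)
                    if best is None or key < best[0]:
                        best = (key, ia, ib, a + b[olen:])
        if best is None:
            break
        _, ia, ib, merged = best
        del items[ia], items[ib]
        items[min(ia, ib)] = merged
    return [items[k] for k in sorted(items)]
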