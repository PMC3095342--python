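"""In-silico PCR marker extraction, per-region alignment, supermatrix.

Marker regions (intergenic spacers such as trnH-psbA, coding loci such
as matK or rbcL) are pulled out of plastome templates with a primer
panel: primer annealing sites are located on both strands of the
(circular) template, unique compatible site pairs define an amplicon,
and per-region alignments are concatenated column-wise into a
partitioned supermatrix for phylogenetic analysis.

Stringency mirrors in-silico PCR practice rather than wet-lab PCR: the
primer 3'-terminal base must match exactly and at most ``max_mismatch``
other positions may mismatch (IUPAC degenerate primer bases match their
expansion sets; ambiguity codes in the template count as mismatches).

The bundled aligner is a deliberately simple, fully deterministic
progressive method (k-mer distances, NJ guide tree, profile merging via
consensus alignment with affine gaps); pre-aligned FASTA can be supplied
instead for anything harder.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from .core_io import (
    FormatError,
    IUPAC_SETS,
    MultipleAlignment,
    PlastomeRecord,
    PrimerPair,
    reverse_complement,
)
from .phylogeny import DistanceMatrix, _nj_node, _PNode

__all__ = [
    "Amplicon",
    "MultipleAlignment",
    "NoAmplification",
    "AmbiguousAmplification",
    "find_primer_sites",
    "extract_amplicon",
    "extract_regions",
    "align_region",
    "concatenate_supermatrix",
]


class NoAmplification(ValueError):
    """No compatible primer-site pair: the locus yields no product."""


class AmbiguousAmplification(ValueError):
    """Multiple candidate products (e.g. an IR-duplicated annealing site)."""

    def __init__(self, region: str, candidates: list):
        self.candidates = candidates
        super().__init__(
            f"{region}: {len(candidates)} candidate products "
            f"{[(c[0], c[1]) for c in candidates]}"
        )


@dataclass
class Amplicon:
    """A predicted PCR product, oriented forward-primer-first."""

    region_name: str
    taxon: str
    sequence: str
    template_interval: tuple[int, int]
    strand: str
    primer_mismatches: tuple[int, int]

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Primer-site scanning
# ---------------------------------------------------------------------------

def _scan_plus(seq_bytes: np.ndarray, primer: str, max_mismatch: int,
               n_starts: int) -> list[tuple[int, int]]:
    """(start, mismatches) for plus-strand matches of ``primer``.

    The primer's 3' terminal base (its last base) must match exactly.
    """
    plen = len(primer)
    if n_starts <= 0:
        return []
    mism = np.zeros(n_starts, dtype=np.int32)
    for j, base in enumerate(primer):
        allowed = np.frombuffer(IUPAC_SETS[base].encode(), dtype=np.uint8)
        window = seq_bytes[j : j + n_starts]
        ok = np.isin(window, allowed)
        if j == plen - 1:
            terminal_ok = ok
        mism += (~ok).astype(np.int32)
    hits = np.nonzero((mism <= max_mismatch) & terminal_ok)[0]
    return [(int(i), int(mism[i])) for i in hits]


def find_primer_sites(
    record: PlastomeRecord, primer: str, max_mismatch: int = 2
) -> list[tuple[int, str, int]]:
    """Annealing sites of a primer on both strands of a template.

    Returns (position, strand, mismatches) triples where ``position`` is
    the 0-based plus-strand start of the annealed segment (leftmost
    coordinate; for circular templates, in [0, L)).  Scanning is
    circular-aware: sites spanning the origin are found and reported
    with their wrap coordinates.
    """
    primer = primer.upper().replace("U", "T")
    L = len(record)
    plen = len(primer)
    if plen > L:
        return []
    text = record.sequence + (record.sequence[: plen - 1] if record.circular else "")
    sb = np.frombuffer(text.encode(), dtype=np.uint8)
    n_starts = (L if record.circular else L - plen + 1)
    hits = []
    for pos, mm in _scan_plus(sb, primer, max_mismatch, n_starts):
        hits.append((pos, "+", mm))
    for pos, mm in _scan_plus(sb, reverse_complement(primer), max_mismatch, n_starts):
        hits.append((pos, "-", mm))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Amplicon extraction
# ---------------------------------------------------------------------------

def extract_amplicon(
    record: PlastomeRecord,
    pair: PrimerPair,
    taxon: str = "",
    size_tolerance: float = 0.5,
    max_mismatch: int = 2,
    max_product: int = 20000,
) -> Amplicon:
    """In-silico PCR of one region from one template.

    Exactly one compatible forward/reverse site pair must yield a
    product; when ``expected_size`` is given, products outside
    ``expected_size * (1 +- size_tolerance)`` are discarded first.
    Raises :class:`NoAmplification` or :class:`AmbiguousAmplification`
    otherwise.  The amplicon is returned oriented forward-primer-first.
    """
    L = len(record)
    fwd_hits = find_primer_sites(record, pair.forward, max_mismatch)
    rev_hits = find_primer_sites(record, pair.reverse, max_mismatch)
    lf, lr = len(pair.forward), len(pair.reverse)

    candidates = []  # (template_start, length, strand, fwd_mm, rev_mm)
    for fpos, fstrand, fmm in fwd_hits:
        for rpos, rstrand, rmm in rev_hits:
            if fstrand == "+" and rstrand == "-":
                length = (rpos + lr) - fpos if not record.circular else ((rpos + lr) - fpos) % L
                if record.circular and length == 0:
                    length = L
                if length >= lf + lr and length <= min(max_product, L):
                    candidates.append((fpos, length, "+", fmm, rmm))
            elif fstrand == "-" and rstrand == "+":
                length = (fpos + lf) - rpos if not record.circular else ((fpos + lf) - rpos) % L
                if record.circular and length == 0:
                    length = L
                if length >= lf + lr and length <= min(max_product, L):
                    candidates.append((rpos, length, "-", fmm, rmm))

    if pair.expected_size is not None:
        lo = pair.expected_size * (1.0 - size_tolerance)
        hi = pair.expected_size * (1.0 + size_tolerance)
        candidates = [c for c in candidates if lo <= c[1] <= hi]
    if not candidates:
        raise NoAmplification(f"{pair.region_name}: no product from {record.id}")
    if len(candidates) > 1:
        raise AmbiguousAmplification(pair.region_name, candidates)
    start, length, strand, fmm, rmm = candidates[0]
    seq = record.fetch(start, start + length)
    if strand == "-":
        seq = reverse_complement(seq)
    return Amplicon(
        region_name=pair.region_name,
        taxon=taxon or record.id,
        sequence=seq,
        template_interval=(start, start + length),
        strand=strand,
        primer_mismatches=(fmm, rmm),
    )


def extract_regions(
    records: Sequence[PlastomeRecord],
    panel: Sequence[PrimerPair],
    size_tolerance: float = 0.5,
    max_mismatch: int = 2,
) -> dict[str, dict[str, Optional[str]]]:
    """Amplify every panel region from every template.

    Returns region -> taxon -> sequence, with None marking failed
    amplification (the "no product" cell of a marker survey); ambiguous
    amplification propagates as an error.
    """
    out: dict[str, dict[str, Optional[str]]] = {}
    for pair in panel:
        per_taxon: dict[str, Optional[str]] = {}
        for rec in records:
            try:
                per_taxon[rec.id] = extract_amplicon(
                    rec, pair, size_tolerance=size_tolerance, max_mismatch=max_mismatch
                ).sequence
            except NoAmplification:
                per_taxon[rec.id] = None
        out[pair.region_name] = per_taxon
    return out


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _kmer_profile(seq: str, k: int) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def _kmer_distance_matrix(names: list[str], seqs: list[str], k: int = 6) -> DistanceMatrix:
    profs = [_kmer_profile(s, k) for s in seqs]
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = profs[i], profs[j]
            shared = sum(min(c, pj.get(km, 0)) for km, c in pi.items())
            denom = min(sum(pi.values()), sum(pj.values())) or 1
            d = 1.0 - shared / denom
            m[i, j] = m[j, i] = d
    return DistanceMatrix(names, m)


def _consensus(rows: list[str]) -> str:
    """Column-majority consensus; gaps ignored, ties broken alphabetically."""
    width = len(rows[0])
    out = []
    for c in range(width):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[c]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append("N")
        else:
            out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)


def _merge_profiles(p1, p2, aligner):
    """Merge two sub-alignments by aligning their consensus sequences and
    propagating the induced gap columns."""
    names1, rows1 = p1
    names2, rows2 = p2
    c1, c2 = _consensus(rows1), _consensus(rows2)
    alignment = next(iter(aligner.align(c1, c2)))
    b1 = [(int(s), int(e)) for s, e in alignment.aligned[0]]
    b2 = [(int(s), int(e)) for s, e in alignment.aligned[1]]
    ops = []  # (take1, take2) column counts
    i1 = i2 = 0
    for (s1, e1), (s2, e2) in zip(b1, b2):
        if s1 > i1:
            ops.append((s1 - i1, 0))
        if s2 > i2:
            ops.append((0, s2 - i2))
        ops.append((e1 - s1, e2 - s2))
        i1, i2 = e1, e2
    if len(c1) > i1:
        ops.append((len(c1) - i1, 0))
    if len(c2) > i2:
        ops.append((0, len(c2) - i2))

    new1 = ["" for _ in rows1]
    new2 = ["" for _ in rows2]
    j1 = j2 = 0
    for t1, t2 in ops:
        n = max(t1, t2)
        for idx, r in enumerate(rows1):
            new1[idx] += r[j1 : j1 + t1] + "-" * (n - t1)
        for idx, r in enumerate(rows2):
            new2[idx] += r[j2 : j2 + t2] + "-" * (n - t2)
        j1 += t1
        j2 += t2
    return names1 + names2, new1 + new2


def align_region(
    sequences,
    region_name: str = "region",
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 15.0,
    gap_extend: float = 6.66,
    k: int = 6,
) -> MultipleAlignment:
    """Progressive multiple alignment of one marker region.

    ``sequences`` maps taxon -> DNA (dict or (taxon, seq) pairs).  A
    k-mer distance matrix drives an NJ guide tree; profiles are merged
    bottom-up with affine-gap consensus alignment (defaults: gap open
    15, extension 6.66).  Deterministic for a fixed input order.
    """
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = list(sequences)
    if not items:
        raise ValueError("no sequences")
    names = [n for n, _ in items]
    seqs = [s.upper().replace("U", "T") for _, s in items]
    if len(items) == 1:
        return MultipleAlignment(names, seqs, {region_name: (0, len(seqs[0]))})

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)

    if len(items) == 2:
        merged = _merge_profiles((names[:1], seqs[:1]), (names[1:], seqs[1:]), aligner)
    else:
        dm = _kmer_distance_matrix(names, seqs, k=k)
        guide = _nj_node(dm.taxa, dm.matrix)
        by_name = dict(zip(names, seqs))

        def build(node: _PNode):
            if node.is_leaf():
                return [node.label], [by_name[node.label]]
            profile = build(node.children[0])
            for child in node.children[1:]:
                profile = _merge_profiles(profile, build(child), aligner)
            return profile

        merged = build(guide)
    mnames, mrows = merged
    order = [mnames.index(n) for n in names]
    rows = [mrows[i] for i in order]
    return MultipleAlignment(names, rows, {region_name: (0, len(rows[0]))})


# ---------------------------------------------------------------------------
# Supermatrix concatenation
# ---------------------------------------------------------------------------

def concatenate_supermatrix(
    alignments: Sequence[MultipleAlignment],
) -> MultipleAlignment:
    """Column-wise concatenation of per-region alignments.

    The taxon set is the union over regions (in first-appearance order);
    a taxon absent from a region gets a gap-filled row over that
    partition.  Region names must be unique; the partition map records
    each region's column range, so the supermatrix can be split back
    losslessly.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    partition_map: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    offset = 0
    for aln in alignments:
        names = list(aln.partition_map) or [f"region{len(partition_map) + 1}"]
        if len(names) != 1:
            # multi-partition inputs contribute each of their partitions
            names = sorted(aln.partition_map, key=lambda n: aln.partition_map[n])
        for name in names:
            if name in partition_map:
                raise FormatError(f"duplicate region name {name!r}")
            s, e = aln.partition_map.get(name, (0, aln.width))
            width = e - s
            for t in taxa:
                if t in aln.taxa:
                    rows[t].append(aln.row(t)[s:e])
                else:
                    rows[t].append("-" * width)
            partition_map[name] = (offset, offset + width)
            offset += width
    return MultipleAlignment(taxa, ["".join(rows[t]) for t in taxa], partition_map)
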