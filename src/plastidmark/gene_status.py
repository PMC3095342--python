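"""Five-category functionality classification of plastid genes.

Plastid *ndh* genes in orchids frequently lose function through whole-gene
loss, terminal truncation, frame-disrupting (or in-frame) indels, or
premature internal stop codons.  Each query gene region is compared with
a functional reference CDS by local affine-gap alignment and classified
into exactly one of five categories:

``absent``           no alignable sequence remains (or nearly none)
``truncated``        only a partial coding sequence is observed
``frame_disrupted``  reading frame shifted or nucleotides deleted/inserted
``internal_stop``    gene size unchanged but internal stop codons present
``functional``       intact coding capacity

plus ``no_data`` when no region was obtained for the locus at all.  The
precedence is absent > truncated > frame_disrupted > internal_stop >
functional; note that in-frame deletions deliberately fall under
``frame_disrupted`` ("nucleotides deleted"), so a 30 bp in-frame deletion
is reported there, not under internal stops.

Premature stops are assessed with the plastid/bacterial genetic code by
translating the aligned query in the reading frame anchored at the
reference start codon, so frameshift-induced stops downstream of an
indel are visible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable

from .core_io import FormatError

__all__ = [
    "NDH_PANEL",
    "CATEGORIES",
    "CATEGORY_LABELS",
    "CATEGORY_GLYPHS",
    "PairwiseComparison",
    "StatusCall",
    "StatusMatrix",
    "StatusThresholds",
    "align_gene_to_reference",
    "classify_gene_status",
    "build_status_matrix",
]

#: The eleven plastid-encoded NAD(P)H dehydrogenase subunit loci.
NDH_PANEL = [f"ndh{c}" for c in "ABCDEFGHIJK"]

CATEGORIES = (
    "functional", "absent", "truncated", "frame_disrupted", "internal_stop", "no_data",
)

#: Report labels matching the field's usual terminology.
CATEGORY_LABELS = {
    "functional": "functional",
    "absent": "absent",
    "truncated": "truncated",
    "frame_disrupted": "frame shift",
    "internal_stop": "stop codon",
    "no_data": "-",
}

#: Glyphs for a compact status-matrix rendering.
CATEGORY_GLYPHS = {
    "functional": "o",      # white circle: functional protein
    "absent": "*",          # black star: no sequence exists
    "truncated": "T",       # black triangle: partial coding sequence
    "frame_disrupted": "F", # white triangle: frame shifted / nucleotides deleted
    "internal_stop": "S",   # white star: internal stop codons, size unchanged
    "no_data": "-",         # no product obtained
}

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOP_CODONS = frozenset(_BACTERIAL_TABLE.stop_codons)
_START_CODONS = frozenset(_BACTERIAL_TABLE.start_codons)


@dataclass
class PairwiseComparison:
    """Evidence extracted from a query-vs-reference CDS alignment.

    ``indel_events`` are (reference_position, length_bp, kind) with kind
    ``insertion`` (extra query bases) or ``deletion`` (missing reference
    bases); ``net_length_change`` is total insertions minus deletions.
    ``premature_stops`` holds codon indices (reference-anchored frame)
    strictly before the terminal stop.  Terminal truncations are the bp
    of reference CDS unaligned at each end.
    """

    reference_gene: str
    reference_length: int
    query_coverage: float
    identity: float
    indel_events: list[tuple[int, int, str]] = field(default_factory=list)
    net_length_change: int = 0
    frame_preserved: bool = True
    premature_stops: list[int] = field(default_factory=list)
    terminal_truncation_5p: int = 0
    terminal_truncation_3p: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise FormatError("coverage and identity must lie in [0, 1]")
        net = sum(l for _, l, k in self.indel_events if k == "insertion") - sum(
            l for _, l, k in self.indel_events if k == "deletion"
        )
        if net != self.net_length_change:
            raise FormatError("net_length_change inconsistent with indel events")


@dataclass
class StatusCall:
    gene: str
    category: str
    evidence: Optional[PairwiseComparison] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise FormatError(f"unknown category {self.category!r}")
        if (self.category == "no_data") != (self.evidence is None):
            raise FormatError("no_data iff evidence absent")


@dataclass
class StatusThresholds:
    """Coverage knobs for the absent/truncated boundaries.

    The qualitative definitions ("no sequence exists", "only partial
    coding sequences") are quantified as coverage cutoffs; both are
    config-exposed because no published boundary exists.
    """

    absent_max_coverage: float = 0.10
    truncated_max_coverage: float = 0.90
    identity_floor: float = 0.5


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _validate_reference(ref_cds: str, gene: str) -> None:
    if len(ref_cds) % 3 != 0:
        raise FormatError(f"{gene}: reference CDS length not divisible by 3")
    if ref_cds[:3] not in _START_CODONS:
        raise FormatError(f"{gene}: reference CDS does not begin with a start codon")
    if ref_cds[-3:] not in _STOP_CODONS:
        raise FormatError(f"{gene}: reference CDS does not end with a stop codon")


def _local_blocks(aligner, ref: str, query: str) -> tuple[list, list]:
    """Aligned block lists of the best local alignment (empty on none)."""
    if not ref or not query:
        return [], []
    try:
        alignment = next(iter(aligner.align(ref, query)))
    except StopIteration:
        return [], []
    blocks = alignment.aligned
    return (
        [(int(s), int(e)) for s, e in blocks[0]],
        [(int(s), int(e)) for s, e in blocks[1]],
    )


def _block_identity(ref, query, rb, qb) -> float:
    matched = sum(
        1
        for (rs, re), (qs, qe) in zip(rb, qb)
        for a, b in zip(ref[rs:re], query[qs:qe])
        if a == b
    )
    total = sum(e - s for s, e in rb)
    return matched / total if total else 0.0


def _aligned_blocks_with_tail_rescue(
    aligner, ref: str, query: str, min_tail: int = 20, tail_identity: float = 0.8
) -> tuple[list, list]:
    """Local alignment blocks, with unaligned terminal tails re-aligned.

    Affine penalties this heavy refuse to bridge deletions much longer
    than the flanking arms, leaving a genuinely present distal gene
    segment unaligned.  When both a reference tail and a query tail of
    at least ``min_tail`` bp remain outside the primary local alignment,
    they are aligned recursively and kept if they match convincingly;
    the intervening unaligned span then surfaces as an ordinary indel
    event between blocks.
    """
    rb, qb = _local_blocks(aligner, ref, query)
    if not rb:
        return rb, qb

    def rescue(ref_lo, ref_hi, q_lo, q_hi):
        if ref_hi - ref_lo < min_tail or q_hi - q_lo < min_tail:
            return [], []
        sub_rb, sub_qb = _aligned_blocks_with_tail_rescue(
            aligner, ref[ref_lo:ref_hi], query[q_lo:q_hi], min_tail, tail_identity
        )
        if not sub_rb:
            return [], []
        if sum(e - s for s, e in sub_rb) < min_tail:
            return [], []
        if _block_identity(ref[ref_lo:ref_hi], query[q_lo:q_hi], sub_rb, sub_qb) < tail_identity:
            return [], []
        return (
            [(s + ref_lo, e + ref_lo) for s, e in sub_rb],
            [(s + q_lo, e + q_lo) for s, e in sub_qb],
        )

    left_rb, left_qb = rescue(0, rb[0][0], 0, qb[0][0])
    right_rb, right_qb = rescue(rb[-1][1], len(ref), qb[-1][1], len(query))
    return left_rb + rb + right_rb, left_qb + qb + right_qb


def align_gene_to_reference(
    query_region: str,
    ref_cds: str,
    gene: str = "",
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 15.0,
    gap_extend: float = 6.66,
    identity_floor: float = 0.5,
) -> PairwiseComparison:
    """Compare a query gene region with a functional reference CDS.

    Local (Smith-Waterman) alignment with affine gaps; the query may
    carry flanking non-coding sequence, which simply stays unaligned.
    If the best alignment's identity falls below ``identity_floor`` the
    comparison is returned as unalignable (coverage 0).
    """
    query_region = query_region.upper().replace("U", "T")
    ref_cds = ref_cds.upper().replace("U", "T")
    _validate_reference(ref_cds, gene or "reference")
    n_ref = len(ref_cds)

    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    unalignable = PairwiseComparison(
        reference_gene=gene, reference_length=n_ref,
        query_coverage=0.0, identity=0.0,
        terminal_truncation_5p=n_ref, terminal_truncation_3p=0,
        frame_preserved=False,
    )
    if not query_region:
        return unalignable
    ref_blocks, q_blocks = _aligned_blocks_with_tail_rescue(
        aligner, ref_cds, query_region
    )
    if not ref_blocks:
        return unalignable

    aligned_ref = sum(e - s for s, e in ref_blocks)
    matches = 0
    for (rs, re), (qs, qe) in zip(ref_blocks, q_blocks):
        matches += sum(
            1 for a, b in zip(ref_cds[rs:re], query_region[qs:qe]) if a == b
        )
    span_columns = aligned_ref + sum(
        max(r1 - r0e, q1 - q0e)
        for (_, r0e), (r1, _), (_, q0e), (q1, _) in (
            (ref_blocks[i], ref_blocks[i + 1], q_blocks[i], q_blocks[i + 1])
            for i in range(len(ref_blocks) - 1)
        )
    )
    identity = matches / span_columns if span_columns else 0.0
    if identity < identity_floor:
        return unalignable

    indel_events: list[tuple[int, int, str]] = []
    for i in range(len(ref_blocks) - 1):
        dr = ref_blocks[i + 1][0] - ref_blocks[i][1]
        dq = q_blocks[i + 1][0] - q_blocks[i][1]
        if dr > 0:
            indel_events.append((ref_blocks[i][1], dr, "deletion"))
        if dq > 0:
            indel_events.append((ref_blocks[i][1], dq, "insertion"))
    net = sum(l for _, l, k in indel_events if k == "insertion") - sum(
        l for _, l, k in indel_events if k == "deletion"
    )
    frame_preserved = net % 3 == 0 and all(l % 3 == 0 for _, l, _ in indel_events)

    trunc5 = ref_blocks[0][0]
    trunc3 = n_ref - ref_blocks[-1][1]
    coverage = aligned_ref / n_ref

    premature = _premature_stops(ref_cds, query_region, ref_blocks, q_blocks)

    return PairwiseComparison(
        reference_gene=gene,
        reference_length=n_ref,
        query_coverage=coverage,
        identity=identity,
        indel_events=indel_events,
        net_length_change=net,
        frame_preserved=frame_preserved,
        premature_stops=premature,
        terminal_truncation_5p=trunc5,
        terminal_truncation_3p=trunc3,
    )


def _premature_stops(ref_cds, query, ref_blocks, q_blocks) -> list[int]:
    """Stop codons in the query read in the reference-anchored frame.

    The query's aligned subsequence (gaps stripped) is translated from
    the first complete reference codon boundary inside the alignment;
    codon indices count from that boundary.  The terminal reference stop
    position is excluded, as are trailing query codons past the
    reference codon count (they lie beyond the gene).
    """
    n_codons = len(ref_cds) // 3
    p0 = ref_blocks[0][0]
    first_codon = (p0 + 2) // 3  # first codon fully covered
    codon_start_ref = first_codon * 3
    # map codon_start_ref to a query coordinate via the aligned blocks
    q_anchor = None
    for (rs, re), (qs, qe) in zip(ref_blocks, q_blocks):
        if rs <= codon_start_ref < re:
            q_anchor = qs + (codon_start_ref - rs)
            break
    if q_anchor is None:
        return []
    q_end = q_blocks[-1][1]
    stops = []
    idx = first_codon
    for qpos in range(q_anchor, q_end - 2, 3):
        if idx >= n_codons - 1:
            break
        codon = query[qpos : qpos + 3]
        if codon in _STOP_CODONS:
            stops.append(idx)
        idx += 1
    return stops


def classify_gene_status(
    cmp: PairwiseComparison, thresholds: StatusThresholds | None = None
) -> StatusCall:
    """Assign one of the five functionality categories.

    Precedence: (1) absent when essentially nothing aligns; (2) truncated
    when terminal loss alone reduces coverage below the truncation
    threshold; (3) frame_disrupted on any indel event (in-frame included);
    (4) internal_stop when the length is unchanged but premature stops
    exist; (5) functional otherwise.
    """
    th = thresholds or StatusThresholds()
    gene = cmp.reference_gene
    if cmp.query_coverage <= th.absent_max_coverage:
        return StatusCall(gene, "absent", cmp)
    terminal_missing = cmp.terminal_truncation_5p + cmp.terminal_truncation_3p
    if terminal_missing / cmp.reference_length >= 1.0 - th.truncated_max_coverage:
        return StatusCall(gene, "truncated", cmp)
    if cmp.indel_events:
        return StatusCall(gene, "frame_disrupted", cmp)
    if cmp.net_length_change == 0 and cmp.premature_stops:
        return StatusCall(gene, "internal_stop", cmp)
    return StatusCall(gene, "functional", cmp)


@dataclass
class StatusMatrix:
    """Varieties x genes grid of status calls."""

    varieties: list[str]
    genes: list[str]
    cells: dict[tuple[str, str], StatusCall]

    def __post_init__(self) -> None:
        for v in self.varieties:
            for g in self.genes:
                if (v, g) not in self.cells:
                    raise FormatError(f"incomplete status grid: missing ({v}, {g})")

    def category(self, variety: str, gene: str) -> str:
        return self.cells[(variety, gene)].category

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for call in self.cells.values():
            counts[call.category] += 1
        return counts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("variety\t" + "\t".join(self.genes) + "\n")
            for v in self.varieties:
                row = [CATEGORY_LABELS[self.category(v, g)] for g in self.genes]
                fh.write(v + "\t" + "\t".join(row) + "\n")

    def to_glyph_table(self) -> str:
        width = max(len(v) for v in self.varieties)
        lines = [" " * width + "  " + " ".join(g[-1] for g in self.genes)]
        for v in self.varieties:
            glyphs = " ".join(CATEGORY_GLYPHS[self.category(v, g)] for g in self.genes)
            lines.append(f"{v:<{width}}  {glyphs}")
        return "\n".join(lines)


def build_status_matrix(
    varieties: Sequence[tuple[str, dict[str, str]]],
    references: dict[str, str],
    panel: Sequence[str] | None = None,
    thresholds: StatusThresholds | None = None,
) -> StatusMatrix:
    """Classify every (variety, gene) cell of a cohort.

    ``varieties`` maps each variety name to its per-locus region
    sequences (spliced, with flanks allowed); loci with no region at all
    become ``no_data``.  A reference CDS must exist for every panel gene.
    """
    panel = list(panel) if panel is not None else list(NDH_PANEL)
    missing = [g for g in panel if g not in references]
    if missing:
        raise FormatError(f"no reference CDS for panel genes: {missing}")
    names = [name for name, _ in varieties]
    cells: dict[tuple[str, str], StatusCall] = {}
    for name, regions in varieties:
        for gene in panel:
            region = regions.get(gene)
            if region is None:
                cells[(name, gene)] = StatusCall(gene, "no_data", None)
                continue
            cmp = align_gene_to_reference(region, references[gene], gene=gene)
            cells[(name, gene)] = classify_gene_status(cmp, thresholds)
    return StatusMatrix(names, panel, cells)
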