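"""Readers, writers and shared domain types.

Every pipeline stage consumes the dataclasses defined here: plastome
records, gene annotations, primer pairs, breeding pedigrees, multiple
alignments and (via dendropy) phylogenetic trees.  External formats are
FASTA for sequences, a GFF3 subset or a six-column TSV for annotations,
TSV for primer panels and pedigrees, and Newick for trees (bootstrap
supports stored as internal-node labels).

Coordinate convention: internally everything is 0-based, half-open, on
the plus strand.  GFF3 files are converted from/to their native 1-based
inclusive convention on read/write.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "UNKNOWN",
    "reverse_complement",
    "PlastomeRecord",
    "GeneAnnotation",
    "PrimerPair",
    "PedigreeEntry",
    "Pedigree",
    "MultipleAlignment",
    "Tree",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_gff3",
    "read_primer_table",
    "write_primer_table",
    "read_pedigree",
    "write_pedigree",
    "read_newick",
    "write_newick",
    "validate_tree",
]

UNKNOWN = "UNKNOWN"

#: IUPAC nucleotide one-letter codes (ambiguity codes included).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
#: Expansion of each IUPAC code into the set of plain bases it matches.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn-",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn-",
)


class FormatError(ValueError):
    """Raised when an input file or value violates its format contract."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PlastomeRecord:
    """A (possibly circular) plastome sequence with identifier.

    ``sequence`` is case-normalized to upper on construction; the alphabet
    is restricted to IUPAC nucleotide codes.  Circular records support
    index wrap-around via :meth:`fetch`.
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps past the end when circular.

        ``end`` may exceed the genome length (circular records only), and
        ``start`` may be negative modulo the genome length.
        """
        n = len(self.sequence)
        if end < start:
            raise ValueError(f"end {end} < start {start}")
        if not self.circular:
            if start < 0 or end > n:
                raise ValueError(
                    f"interval [{start}, {end}) outside linear record of length {n}"
                )
            return self.sequence[start:end]
        if end - start > n:
            raise ValueError("interval longer than circular genome")
        length = end - start
        start %= n
        stop = start + length
        if stop <= n:
            return self.sequence[start:stop]
        return self.sequence[start:] + self.sequence[: stop - n]

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Return the record rotated so position ``offset`` becomes 0."""
        if not self.circular:
            raise ValueError("rotation requires a circular record")
        off = offset % len(self.sequence)
        return PlastomeRecord(
            self.id, self.sequence[off:] + self.sequence[:off], circular=True
        )


FEATURE_TYPES = ("CDS", "tRNA", "rRNA")


@dataclass
class GeneAnnotation:
    """A gene feature as a set of exon intervals on the plus strand.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    ``copy`` marks whether the record is one of an inverted-repeat
    duplicated pair.
    """

    gene: str
    feature_type: str
    strand: str
    exons: list[tuple[int, int]]
    copy: str = "single"

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise FormatError(
                f"{self.gene}: unknown feature type {self.feature_type!r}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene}: strand must be '+' or '-'")
        if self.copy not in ("single", "IR_duplicate"):
            raise FormatError(f"{self.gene}: bad copy flag {self.copy!r}")
        if not self.exons:
            raise FormatError(f"{self.gene}: no exons")
        exs = sorted(tuple(e) for e in self.exons)
        for (s, e) in exs:
            if e <= s:
                raise FormatError(f"{self.gene}: empty/inverted exon [{s},{e})")
        for (a, b), (c, d) in zip(exs, exs[1:]):
            if c < b:
                raise FormatError(f"{self.gene}: overlapping exons")
        self.exons = exs

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, record: PlastomeRecord) -> str:
        """Spliced sequence in reading orientation (revcomp for '-')."""
        seq = "".join(record.fetch(s, e) for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class PrimerPair:
    """A named PCR primer pair with an optional expected product size."""

    region_name: str
    forward: str
    reverse: str
    expected_size: Optional[int] = None

    def __post_init__(self) -> None:
        self.forward = self.forward.upper().replace("U", "T")
        self.reverse = self.reverse.upper().replace("U", "T")
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise FormatError(
                    f"{self.region_name}: {label} primer shorter than 10 nt"
                )
            bad = set(p) - IUPAC_CODES
            if bad:
                raise FormatError(
                    f"{self.region_name}: {label} primer has non-IUPAC {sorted(bad)}"
                )
        if self.expected_size is not None and self.expected_size <= 0:
            raise FormatError(f"{self.region_name}: expected_size must be positive")


@dataclass(frozen=True)
class PedigreeEntry:
    variety: str
    female_parent: str = UNKNOWN
    male_parent: str = UNKNOWN


@dataclass
class Pedigree:
    """Parentage of a panel of varieties.

    The plastome is maternally inherited, so the female-parent links are
    the phylogenetically meaningful ones: following them from any variety
    terminates at a *maternal founder* (an ancestor without an entry, or
    the variety itself when its female parent is UNKNOWN).
    """

    entries: list[PedigreeEntry]

    def __post_init__(self) -> None:
        names = [e.variety for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate pedigree entries: {dupes}")
        self._by_name = {e.variety: e for e in self.entries}
        for e in self.entries:
            self.maternal_chain(e.variety)  # raises on cycles
        # full ancestry acyclicity (both parents)
        for e in self.entries:
            self._check_acyclic(e.variety, set())

    def _check_acyclic(self, name: str, seen: set) -> None:
        if name in seen:
            raise FormatError(f"pedigree cycle involving {name!r}")
        entry = self._by_name.get(name)
        if entry is None:
            return
        seen = seen | {name}
        for parent in (entry.female_parent, entry.male_parent):
            if parent != UNKNOWN:
                self._check_acyclic(parent, seen)

    @property
    def varieties(self) -> list[str]:
        return [e.variety for e in self.entries]

    def maternal_chain(self, variety: str) -> list[str]:
        """Female-line ancestors of ``variety``, starting with itself."""
        chain = [variety]
        seen = {variety}
        cur = variety
        while True:
            entry = self._by_name.get(cur)
            if entry is None or entry.female_parent == UNKNOWN:
                return chain
            cur = entry.female_parent
            if cur in seen:
                raise FormatError(f"maternal-line cycle involving {cur!r}")
            seen.add(cur)
            chain.append(cur)

    def maternal_founder(self, variety: str) -> str:
        """The terminal name of the female-parent chain."""
        return self.maternal_chain(variety)[-1]


@dataclass
class MultipleAlignment:
    """Aligned sequences plus an optional per-region partition map.

    ``rows[i]`` is the aligned sequence (over ``ACGTN-``) of ``taxa[i]``.
    ``partition_map`` maps region names to 0-based half-open column
    ranges; when present the ranges must be disjoint and cover every
    column, which makes a concatenated supermatrix losslessly splittable.
    """

    taxa: list[str]
    rows: list[str]
    partition_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise FormatError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon names in alignment")
        if not self.rows:
            raise FormatError("empty alignment")
        w = len(self.rows[0])
        if any(len(r) != w for r in self.rows):
            raise FormatError("unequal alignment row lengths")
        self.rows = [r.upper() for r in self.rows]
        if self.partition_map:
            spans = sorted(self.partition_map.values())
            covered = 0
            for s, e in spans:
                if s != covered:
                    raise FormatError("partition ranges must tile all columns")
                covered = e
            if covered != w:
                raise FormatError("partition ranges must cover all columns")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def region(self, name: str) -> "MultipleAlignment":
        """Extract one partition as a stand-alone alignment."""
        s, e = self.partition_map[name]
        return MultipleAlignment(
            list(self.taxa), [r[s:e] for r in self.rows], {name: (0, e - s)}
        )

    def to_fasta(self, path) -> None:
        write_fasta_strings(dict(zip(self.taxa, self.rows)), path)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.taxa)} {self.width}\n")
            for t, r in zip(self.taxa, self.rows):
                fh.write(f"{t}  {r}\n")


#: Trees are dendropy objects throughout the package.
Tree = dendropy.Tree


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[PlastomeRecord]:
    """Read FASTA into :class:`PlastomeRecord` objects.

    Sequences are uppercased and U is normalized to T.  Circularity is
    taken from a ``circular=true`` key in the description line (default
    linear).  Non-ACGTN IUPAC ambiguity codes are kept but flagged with a
    warning; anything else raises :class:`FormatError`.
    """
    records = []
    with open(path) as handle:
        parsed = list(SeqIO.parse(handle, "fasta"))
    for rec in parsed:
        circular = "circular=true" in rec.description.lower()
        pr = PlastomeRecord(rec.id, str(rec.seq), circular=circular)
        ambiguous = set(pr.sequence) - set("ACGTN")
        if ambiguous:
            warnings.warn(
                f"record {pr.id!r}: ambiguity codes {sorted(ambiguous)} kept; "
                "they are treated as mismatches by comparisons"
            )
        records.append(pr)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[PlastomeRecord], path) -> None:
    seqs = []
    for r in records:
        desc = "circular=true" if r.circular else ""
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def write_fasta_strings(named: dict[str, str], path) -> None:
    """Write a plain name -> sequence mapping as FASTA."""
    SeqIO.write(
        [SeqRecord(Seq(s), id=n, description="") for n, s in named.items()],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Annotations (GFF3 subset or 6-column TSV)
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation_table(path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (subset) or the 6-column TSV dialect.

    GFF3: only CDS/tRNA/rRNA feature lines are used; multi-exon features
    are grouped by their Parent (or ID) attribute; coordinates are
    converted from 1-based inclusive to 0-based half-open.  The TSV
    dialect has columns ``gene type strand start end copy`` with 0-based
    half-open coordinates, one row per exon.
    """
    lines = Path(path).read_text().splitlines()
    data = [
        (i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")
    ]
    if not data:
        raise FormatError(f"no annotation rows in {path}")
    ncols = len(data[0][1].split("\t"))
    if ncols == 9:
        return _read_gff3(data)
    if ncols == 6:
        return _read_annotation_tsv(data)
    raise FormatError(f"{path}: expected 9-column GFF3 or 6-column TSV, got {ncols} columns")


def _read_gff3(data: list[tuple[int, str]]) -> list[GeneAnnotation]:
    groups: dict[str, dict] = {}
    order: list[str] = []
    for lineno, ln in data:
        fields = ln.split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: malformed GFF3 row")
        _, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
        if ftype in ("gene", "exon"):
            continue  # gene containers / exon children are redundant here
        if ftype not in FEATURE_TYPES:
            raise FormatError(f"line {lineno}: unknown feature type {ftype!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinates") from exc
        if end < start:
            raise FormatError(f"line {lineno}: end < start")
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: invalid strand {strand!r}")
        attrs = _parse_gff3_attributes(attr_s)
        key = attrs.get("Parent") or attrs.get("ID") or f"line{lineno}"
        gene = attrs.get("gene") or attrs.get("Name") or key
        g = groups.get(key)
        if g is None:
            groups[key] = g = {
                "gene": gene, "type": ftype, "strand": strand,
                "copy": attrs.get("copy", "single"), "exons": [],
            }
            order.append(key)
        g["exons"].append((start - 1, end))  # 1-based incl -> 0-based half-open
    return [
        GeneAnnotation(g["gene"], g["type"], g["strand"], g["exons"], g["copy"])
        for g in (groups[k] for k in order)
    ]


def _read_annotation_tsv(data: list[tuple[int, str]]) -> list[GeneAnnotation]:
    rows = []
    for lineno, ln in data:
        fields = [f.strip() for f in ln.split("\t")]
        if fields[0].lower() == "gene":  # header row
            continue
        gene, ftype, strand, start_s, end_s, copy = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinates") from exc
        if end < start:
            raise FormatError(f"line {lineno}: end < start")
        if ftype not in FEATURE_TYPES:
            raise FormatError(f"line {lineno}: unknown feature type {ftype!r}")
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: invalid strand {strand!r}")
        rows.append((gene, ftype, strand, start, end, copy))
    groups: dict[tuple, dict] = {}
    order = []
    for gene, ftype, strand, start, end, copy in rows:
        key = (gene, ftype, strand, copy)
        if key not in groups:
            groups[key] = {"exons": []}
            order.append(key)
        groups[key]["exons"].append((start, end))
    return [
        GeneAnnotation(k[0], k[1], k[2], groups[k]["exons"], k[3]) for k in order
    ]


def write_annotation_gff3(annotations: Sequence[GeneAnnotation], path, seqid: str) -> None:
    """Write annotations as a GFF3 subset (coordinates back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations):
            fid = f"feat{i}"
            for s, e in ann.exons:
                attrs = f"ID={fid};Parent={fid};gene={ann.gene};copy={ann.copy}"
                fh.write(
                    "\t".join(
                        [seqid, "plastidmark", ann.feature_type, str(s + 1), str(e),
                         ".", ann.strand, ".", attrs]
                    ) + "\n"
                )


# ---------------------------------------------------------------------------
# Primer panels
# ---------------------------------------------------------------------------

def read_primer_table(path) -> list[PrimerPair]:
    """Read a primer panel TSV with header region_name/forward/reverse/expected_size."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_name", "forward", "reverse"}
    if not required.issubset(df.columns):
        raise FormatError(f"primer table missing columns {sorted(required - set(df.columns))}")
    pairs = []
    seen = set()
    for _, row in df.iterrows():
        name = row["region_name"]
        if name in seen:
            raise FormatError(f"duplicate region_name {name!r}")
        seen.add(name)
        size = row.get("expected_size")
        expected = None
        if size is not None and str(size).strip() not in ("", "nan"):
            expected = int(float(size))
        pairs.append(PrimerPair(name, row["forward"], row["reverse"], expected))
    if not pairs:
        raise FormatError(f"no primer rows in {path}")
    return pairs


def write_primer_table(pairs: Sequence[PrimerPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_name\tforward\treverse\texpected_size\n")
        for p in pairs:
            size = "" if p.expected_size is None else str(p.expected_size)
            fh.write(f"{p.region_name}\t{p.forward}\t{p.reverse}\t{size}\n")


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    """Read a pedigree from TSV (variety/female_parent/male_parent) or JSON."""
    text = Path(path).read_text()
    entries = []
    if text.lstrip().startswith(("[", "{")):
        payload = json.loads(text)
        rows = payload["entries"] if isinstance(payload, dict) else payload
        for row in rows:
            entries.append(
                PedigreeEntry(
                    row["variety"],
                    row.get("female_parent", UNKNOWN) or UNKNOWN,
                    row.get("male_parent", UNKNOWN) or UNKNOWN,
                )
            )
    else:
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = [f.strip() for f in ln.split("\t")]
            if fields[0].lower() == "variety":
                continue
            while len(fields) < 3:
                fields.append(UNKNOWN)
            entries.append(PedigreeEntry(fields[0], fields[1] or UNKNOWN, fields[2] or UNKNOWN))
    if not entries:
        raise FormatError(f"no pedigree entries in {path}")
    return Pedigree(entries)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("variety\tfemale_parent\tmale_parent\n")
        for e in pedigree.entries:
            fh.write(f"{e.variety}\t{e.female_parent}\t{e.male_parent}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def validate_tree(tree: Tree) -> None:
    """Check Tree invariants: unique leaves, lengths >= 0, supports in [0,100]."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf names in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < -1e-12:
            raise FormatError(f"negative branch length {edge.length}")
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            support = float(node.label)
        except ValueError:
            continue  # non-numeric internal label: not a support value
        if not (0.0 <= support <= 100.0):
            raise FormatError(f"support {support} outside [0, 100]")


def read_newick(path) -> Tree:
    """Parse a Newick tree; internal-node labels are bootstrap supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise FormatError(f"newick parse error in {path}: {exc}") from exc
    validate_tree(tree)
    return tree


def write_newick(tree: Tree, path) -> None:
    validate_tree(tree)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    Path(path).write_text(text)
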