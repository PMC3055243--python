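"""Alignment and tree input/output, taxon-label parsing, and coordinates.

Every downstream module shares the conventions fixed here: alignment columns
are 0-based half-open internally (BED-compatible); human-readable reports
print 1-based inclusive; taxon names encode species, chromosome (X/Y, or U
when unknown) and an optional allele identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO as _BioAlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

log = logging.getLogger(__name__)

#: numeric codes for the four bases; everything else (gap, N, IUPAC
#: ambiguity) is MISSING_CODE and treated as missing by distance code.
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASES = "ACGT"
MISSING_CODE = 255

_VALID_CHARS = set("ACGTUMRWSYKVHDBN-")


class AlignmentError(ValueError):
    """Raised for malformed alignments or unknown taxa."""


@dataclass(frozen=True, order=True)
class TaxonLabel:
    """Species + chromosome + allele identity parsed from a sequence name.

    ``chromosome`` is ``"X"``, ``"Y"`` or ``"U"`` (unknown, e.g. an outgroup
    whose gametolog assignment is irrelevant).
    """

    species: str
    chromosome: str = "U"
    allele_id: str = ""

    def __post_init__(self):
        if not self.species:
            raise ValueError("species must be non-empty")
        if self.chromosome not in ("X", "Y", "U"):
            raise ValueError(f"chromosome must be X/Y/U, got {self.chromosome!r}")

    def format(self) -> str:
        """Canonical name; round-trips through :func:`parse_taxon_label`."""
        parts = [self.species]
        if self.allele_id:
            parts.append(self.allele_id)
        if self.chromosome != "U":
            parts.append(self.chromosome)
        return "_".join(parts)

    def __str__(self) -> str:
        return self.format()


def parse_taxon_label(name: str, template: str = "{species}_{allele}_{chrom}") -> TaxonLabel:
    """Parse a sequence name into a :class:`TaxonLabel`.

    Default template: underscore-delimited, species first, chromosome is the
    last token when it is a bare ``X`` or ``Y``; everything in between is the
    allele id. A name whose last token is not X/Y yields chromosome ``U``
    with a logged warning (the name may still serve as an outgroup).
    """
    if template != "{species}_{allele}_{chrom}":
        m = re.fullmatch(_template_to_regex(template), name)
        if m is None:
            log.warning("taxon name %r does not match template %r; chromosome set to U", name, template)
            return TaxonLabel(species=name, chromosome="U", allele_id="")
        gd = m.groupdict()
        chrom = gd.get("chrom", "U").upper()
        return TaxonLabel(
            species=gd.get("species", name),
            chromosome=chrom if chrom in ("X", "Y") else "U",
            allele_id=gd.get("allele", "") or "",
        )
    tokens = name.split("_")
    if len(tokens) >= 2 and tokens[-1].upper() in ("X", "Y"):
        return TaxonLabel(
            species=tokens[0],
            chromosome=tokens[-1].upper(),
            allele_id="_".join(tokens[1:-1]),
        )
    log.warning("taxon name %r has no trailing X/Y token; chromosome set to U", name)
    return TaxonLabel(species=tokens[0], chromosome="U", allele_id="_".join(tokens[1:]))


def _template_to_regex(template: str) -> str:
    out = ""
    i = 0
    for piece in re.split(r"(\{[a-z]+\})", template):
        if piece.startswith("{") and piece.endswith("}"):
            out += f"(?P<{piece[1:-1]}>.*?)" if piece != "{chrom}" else r"(?P<chrom>[XYxy])"
        else:
            out += re.escape(piece)
    return out


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open column interval."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def human(self) -> str:
        """1-based inclusive rendering for reports."""
        return f"{self.start + 1}-{self.end}"


class Alignment:
    """An in-memory nucleotide alignment keyed by :class:`TaxonLabel`.

    Rows are equal-length uppercase strings over ACGT, gap ``-``, ``N`` and
    IUPAC ambiguity codes. ``codes`` exposes the uint8 matrix used by all
    distance kernels (ambiguity/gap/N collapsed to :data:`MISSING_CODE`).
    """

    def __init__(self, taxa: Sequence[TaxonLabel], rows: Sequence[str]):
        taxa = list(taxa)
        rows = [r.upper() for r in rows]
        if len(taxa) != len(rows):
            raise AlignmentError("taxa and rows differ in count")
        if len(rows) < 2:
            raise AlignmentError("alignment needs >=2 rows")
        L = len(rows[0])
        for t, r in zip(taxa, rows):
            if len(r) != L:
                raise AlignmentError(
                    f"ragged alignment: record {t} has length {len(r)}, expected {L}"
                )
            bad = set(r) - _VALID_CHARS
            if bad:
                raise AlignmentError(f"record {t} contains invalid characters {sorted(bad)}")
        if len(set(taxa)) != len(taxa):
            dups = [t for t in taxa if taxa.count(t) > 1]
            raise AlignmentError(f"duplicate taxon label(s): {sorted(set(map(str, dups)))}")
        self.taxa: list[TaxonLabel] = taxa
        self.rows: list[str] = rows
        self._index = {t: i for i, t in enumerate(taxa)}
        self._codes: np.ndarray | None = None

    # -- basic protocol -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def index_of(self, taxon: TaxonLabel) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise AlignmentError(f"unknown taxon {taxon}") from None

    def row(self, taxon: TaxonLabel) -> str:
        return self.rows[self.index_of(taxon)]

    @property
    def codes(self) -> np.ndarray:
        """(n_taxa, length) uint8 matrix; non-ACGT cells are MISSING_CODE."""
        if self._codes is None:
            lut = np.full(256, MISSING_CODE, dtype=np.uint8)
            for b, c in BASE_CODES.items():
                lut[ord(b)] = c
            mat = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
            self._codes = lut[mat].reshape(len(self.rows), self.length)
        return self._codes

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.taxa:
            seen.setdefault(t.species, None)
        return list(seen)

    def taxa_for(self, species: str, chromosome: str | None = None) -> list[TaxonLabel]:
        return [
            t
            for t in self.taxa
            if t.species == species and (chromosome is None or t.chromosome == chromosome)
        ]

    def xy_species(self) -> list[str]:
        """Species with at least one X and one Y sequence."""
        return [
            s
            for s in self.species()
            if self.taxa_for(s, "X") and self.taxa_for(s, "Y")
        ]

    def subalignment(self, taxa: Sequence[TaxonLabel]) -> "Alignment":
        return Alignment(list(taxa), [self.row(t) for t in taxa])


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    template: str = "{species}_{allele}_{chrom}",
) -> Alignment:
    """Read a FASTA or CLUSTAL alignment, parsing taxon labels.

    Sequences are uppercased on read; label parsing follows ``template``.
    A ragged FASTA (FASTA carries no length guarantee) raises
    :class:`AlignmentError` naming the offending record.
    """
    fmt = {"fasta": "fasta", "clustal": "clustal", "aln": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    if fmt == "fasta":
        # read as plain records so we can report ragged rows ourselves
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(_BioAlignIO.read(str(path), fmt))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    taxa = [parse_taxon_label(r.id, template) for r in records]
    return Alignment(taxa, [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=taxon.format(), description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    fmt = {"fasta": "fasta", "clustal": "clustal", "aln": "clustal"}[format]
    if fmt == "fasta":
        from Bio import SeqIO

        SeqIO.write(records, str(path), "fasta")
    else:
        _BioAlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


# ---------------------------------------------------------------------------
# Species tree


class SpeciesTree:
    """A time-calibrated (ultrametric) species tree.

    Branch lengths are in million years (myr); node ages are depths below the
    tips. Branches are addressed by the frozenset of descendant species.
    """

    def __init__(self, tree: dendropy.Tree, tolerance: float = 1e-3):
        self.tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise ValueError("species tree needs >=2 leaves")
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate species in tree")
        self.species = leaves
        self._ages: dict[int, float] = {}
        self._compute_ages(tolerance)

    def _compute_ages(self, tolerance: float) -> None:
        # depth of every leaf from root must agree (ultrametric)
        depths: dict[int, float] = {}

        def down(node, d):
            depths[id(node)] = d
            for ch in node.child_nodes():
                down(ch, d + (ch.edge.length or 0.0))

        down(self.tree.seed_node, 0.0)
        leaf_depths = [depths[id(lf)] for lf in self.tree.leaf_node_iter()]
        height = max(leaf_depths)
        if height <= 0:
            raise ValueError("species tree has zero height")
        if (max(leaf_depths) - min(leaf_depths)) > tolerance * height:
            raise ValueError(
                f"species tree is not ultrametric: tip depths range "
                f"{min(leaf_depths):.4g}..{max(leaf_depths):.4g} myr"
            )
        for node in self.tree.preorder_node_iter():
            self._ages[id(node)] = height - depths[id(node)]

    @property
    def root_age(self) -> float:
        return self._ages[id(self.tree.seed_node)]

    def node_age(self, node) -> float:
        return self._ages[id(node)]

    def clades(self) -> dict[frozenset, float]:
        """Map descendant-species frozenset -> node age, for every node."""
        out = {}
        for node in self.tree.postorder_node_iter():
            key = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[key] = self._ages[id(node)]
        return out

    def branches(self) -> dict[frozenset, tuple[float, float]]:
        """Descendant set -> (node age, parent age) for every non-root branch.

        The pair is the time interval during which the branch (lineage)
        existed; a conversion on that branch must fall inside it.
        """
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            key = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[key] = (self._ages[id(node)], self._ages[id(node.parent_node)])
        return out

    def mrca_age(self, species: Iterable[str]) -> float:
        species = set(species)
        best = None
        for key, age in self.clades().items():
            if species <= key and (best is None or age < best):
                best = age
        if best is None:
            raise ValueError(f"species {sorted(species)} not all in tree")
        return best

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_species_tree(path_or_newick: str | Path, tolerance: float = 1e-3) -> SpeciesTree:
    """Read a Newick species tree with branch lengths in myr.

    The tree must be ultrametric within ``tolerance`` (relative to height);
    single-leaf trees are rejected.
    """
    src = str(path_or_newick)
    if Path(src).exists():
        tree = dendropy.Tree.get(path=src, schema="newick")
    else:
        tree = dendropy.Tree.get(data=src, schema="newick")
    return SpeciesTree(tree, tolerance=tolerance)


# ---------------------------------------------------------------------------
# Tabular writers shared downstream


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bed(path: str | Path, rows: Iterable[Sequence]) -> None:
    """Rows are (chrom/name, start, end, *rest); 0-based half-open."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
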