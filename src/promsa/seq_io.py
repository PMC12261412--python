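"""File formats and run configuration.

Input sequences are nucleotide FASTA; the working alphabet is the six
symbols A, C, G, T, N and the gap '-', in that fixed index order.  Every
IUPAC ambiguity code other than N is collapsed to N on input.  Guide trees
are Newick (branch lengths optional, polytomies allowed); substitution
matrices are whitespace-delimited labelled tables.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from Bio import SeqIO

from .guide_tree import GuideTree, TreeNode

ALPHABET = "ACGTN-"
ALPHABET_INDEX = {c: i for i, c in enumerate(ALPHABET)}
GAP = "-"

_VALID_RESIDUES = set("ACGTN")

__all__ = [
    "ALPHABET",
    "ALPHABET_INDEX",
    "GAP",
    "SequenceRecord",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_aligned_fasta",
    "parse_newick",
    "load_matrix",
]


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One unaligned input sequence after normalization."""

    identifier: str
    residues: str


@dataclasses.dataclass
class RunConfig:
    """Tunable knobs of a pipeline run.

    gappy_threshold: columns whose gap fraction strictly exceeds this are
        excised before profile alignment (1.0 disables the heuristic).
    xdrop: banding threshold in score units; None derives 600 x |gep| from
        the active scheme.
    max_subtree: divide-and-conquer bound on sequences per subtree; None
        means unbounded (no decomposition).
    psgp_enabled: position-specific gap penalties on gappy columns.
    tile_size: wavefront bound and traceback-tile extent of the tiled DP.
    """

    gappy_threshold: float = 0.95
    xdrop: Optional[float] = None
    max_subtree: Optional[int] = None
    psgp_enabled: bool = False
    seed: int = 0
    matrix_path: Optional[str] = None
    tile_size: int = 512
    wrap: int = 60
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.gappy_threshold <= 1.0):
            raise ValueError("gappy_threshold must be in (0, 1]")
        if self.xdrop is not None and self.xdrop < 0:
            raise ValueError("xdrop must be nonnegative")
        if self.max_subtree is not None and self.max_subtree < 1:
            raise ValueError("max_subtree must be a positive integer")
        if self.tile_size < 2:
            raise ValueError("tile_size must be >= 2")

    def effective_xdrop(self, gep: float) -> float:
        return 600.0 * abs(gep) if self.xdrop is None else self.xdrop

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _normalize_residues(raw: str, identifier: str) -> str:
    seq = raw.upper()
    if GAP in seq or "." in seq:
        raise ValueError(
            f"sequence {identifier!r} contains gap characters; "
            "input must be unaligned"
        )
    return "".join(c if c in _VALID_RESIDUES else "N" for c in seq)


def read_fasta(path) -> List[SequenceRecord]:
    """Read unaligned FASTA records, normalizing to the A/C/G/T/N alphabet.

    Rejects duplicate identifiers, empty files and gapped input.
    """
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_residues(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_aligned_fasta(path) -> List[Tuple[str, str]]:
    """Read an aligned FASTA (gaps allowed) as (identifier, row) pairs."""
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if rows:
        width = len(rows[0][1])
        if any(len(r) != width for _, r in rows):
            raise ValueError(f"ragged alignment in {path}")
    return rows


def write_fasta(
    records: Iterable[Tuple[str, str]],
    path,
    width: int = 60,
    require_equal_width: bool = True,
) -> None:
    """Write (identifier, sequence) pairs as wrapped FASTA.

    Alignment rows must share one length; pass ``require_equal_width=False``
    for unaligned sequences.  An empty record list yields an empty file.
    """
    records = list(records)
    if records and require_equal_width:
        w0 = len(records[0][1])
        for ident, row in records:
            if len(row) != w0:
                raise ValueError(
                    f"row {ident!r} has length {len(row)}, expected {w0}"
                )
    with open(path, "w") as fh:
        for ident, row in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def parse_newick(text: str) -> GuideTree:
    """Parse a Newick string into a guide tree.

    Polytomies and missing branch lengths are preserved; if any edge lacks a
    length the whole tree is treated as having uniform branch lengths.
    """
    import dendropy

    try:
        d_tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc

    def _convert(d_node) -> TreeNode:
        name = d_node.taxon.label if d_node.taxon is not None else None
        length = d_node.edge.length
        node = TreeNode(name=name, length=None if length is None else float(length))
        for child in d_node.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(d_tree.seed_node)
    root.length = None
    tree = GuideTree(root)
    names = tree.leaf_names()
    if any(n is None for n in names):
        raise ValueError("Newick tree contains unlabelled leaves")
    if len(set(names)) != len(names):
        raise ValueError("Newick tree contains duplicate leaf labels")
    return tree


def load_matrix(path, gop: float = -50.0, gep: float = -5.0):
    """Load a user substitution matrix over the 6-letter alphabet.

    Expected format: a header row of labels, then one labelled row per
    symbol, whitespace-delimited.  A table over A C G T N without the gap
    symbol is accepted; gap rows/columns then default to the built-in gap
    scores (mismatch-to-gap -5, gap-gap 0).  Non-symmetric or incomplete
    tables are rejected.
    """
    from .pair_align import SubstitutionScheme, default_scheme

    lines = [
        ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise ValueError(f"empty matrix file {path}")
    header = [c.upper() for c in lines[0]]
    allowed = set(ALPHABET)
    if not set(header) <= allowed:
        raise ValueError(f"unknown matrix labels: {sorted(set(header) - allowed)}")
    table: Dict[Tuple[str, str], float] = {}
    for row in lines[1:]:
        label = row[0].upper()
        if label not in allowed:
            raise ValueError(f"unknown matrix row label {label!r}")
        if len(row) - 1 != len(header):
            raise ValueError(f"row {label!r} has {len(row) - 1} entries, expected {len(header)}")
        for col, val in zip(header, row[1:]):
            table[(label, col)] = float(val)

    base = default_scheme().s
    s = base.copy()
    present = set(header) & {lbl for lbl, _ in table}
    missing = []
    for p in present:
        for q in present:
            if (p, q) not in table:
                missing.append((p, q))
    if missing:
        raise ValueError(f"missing matrix entries: {missing}")
    for p in present:
        for q in present:
            if table[(p, q)] != table[(q, p)]:
                raise ValueError(f"matrix not symmetric at ({p},{q})")
            s[ALPHABET_INDEX[p], ALPHABET_INDEX[q]] = table[(p, q)]
    required = set("ACGT")
    if not required <= present:
        raise ValueError(
            f"matrix must cover at least A C G T; missing {sorted(required - present)}"
        )
    return SubstitutionScheme(s=s, gop=gop, gep=gep)
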