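"""MAF block parsing, interval indexing, and reference→target column mapping.

Blocks are read with Biopython's MAF parser and held as lean records:
one gapped text row per species, with the usual multiz "s"-line fields
(source, start, size, strand, srcSize). The index answers interval
queries in reference coordinates; ``map_position`` turns a reference
coordinate into the aligned column of a target species together with a
gap-stripped sequence context around it.

Species names are the part of the MAF source field before the first
'.' (multiz convention, e.g. ``hg38.chr1`` → ``hg38``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import AlignIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class MafFormatError(ValueError):
    """Raised when a MAF block violates the format contract."""


class PositionError(ValueError):
    """Raised when a reference position falls outside a block."""


@dataclass(frozen=True)
class MafRow:
    src: str  # species.sequence
    start: int  # 0-based start in source coordinates
    size: int  # ungapped length
    strand: str
    src_size: int
    text: str  # gapped sequence

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def seq_name(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]


@dataclass
class AlignmentBlock:
    rows: list[MafRow]
    file_order: int = 0
    _by_species: dict[str, MafRow] = field(default_factory=dict, repr=False)
    _ref_cols: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MafFormatError(f"block {self.file_order}: no sequence rows")
        width = len(self.rows[0].text)
        for row in self.rows:
            if len(row.text) != width:
                raise MafFormatError(
                    f"block {self.file_order}: row {row.src} has text length "
                    f"{len(row.text)}, expected {width}"
                )
            if len(row.text) - row.text.count("-") != row.size:
                raise MafFormatError(
                    f"block {self.file_order}: row {row.src} ungapped length "
                    "does not match its size field"
                )
            self._by_species.setdefault(row.species, row)

    @property
    def width(self) -> int:
        return len(self.rows[0].text)

    def row_for(self, species: str) -> MafRow | None:
        return self._by_species.get(species)

    def ref_columns(self, ref_species: str) -> np.ndarray:
        """Alignment column index of each reference base, cached."""
        if self._ref_cols is None:
            ref = self.row_for(ref_species)
            if ref is None:
                raise MafFormatError(
                    f"block {self.file_order}: no row for reference "
                    f"species {ref_species!r}"
                )
            arr = np.frombuffer(ref.text.encode("ascii"), dtype=np.uint8)
            self._ref_cols = np.flatnonzero(arr != ord("-"))
        return self._ref_cols


@dataclass(frozen=True)
class MappedColumn:
    """Result of mapping one reference coordinate into a target species row.

    ``target_context`` is the gap-stripped target subsequence spanning
    ``w`` alignment columns each side of the mapped column (in alignment
    orientation); ``context_offset`` is the index within that context of
    the character aligned to the reference base (equivalently, the number
    of non-gap target characters in the window strictly left of the
    mapped column).
    """

    species: str
    aligned: bool
    target_char: str = ""
    target_context: str = ""
    context_offset: int = -1


def read_maf(path: str | Path) -> Iterator[AlignmentBlock]:
    """Iterate over MAF blocks in file order."""
    parser = AlignIO.parse(str(path), "maf")
    for i in itertools.count():
        try:
            msa = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise MafFormatError(f"block {i}: {exc}") from exc
        rows = []
        for rec in msa:
            ann = rec.annotations
            strand = "+" if ann.get("strand", 1) in (1, "+") else "-"
            rows.append(
                MafRow(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand=strand,
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        yield AlignmentBlock(rows, file_order=i)


class MafIndex:
    """Interval index over the reference rows of a MAF file.

    The reference species is a required parameter, never inferred; its
    rows must be '+' strand (the multiz convention for the reference).
    """

    def __init__(self, path: str | Path, ref_species: str):
        self.path = Path(path)
        self.ref_species = ref_species
        self.blocks: list[AlignmentBlock] = []
        self.species_seen: set[str] = set()
        self._trees: dict[str, IntervalTree] = {}
        for block in read_maf(self.path):
            ref = block.row_for(ref_species)
            if ref is None:
                raise MafFormatError(
                    f"block {block.file_order}: missing reference species "
                    f"{ref_species!r}"
                )
            if ref.strand != "+":
                raise MafFormatError(
                    f"block {block.file_order}: reference row on '-' strand"
                )
            self.blocks.append(block)
            for row in block.rows:
                self.species_seen.add(row.species)
            tree = self._trees.setdefault(ref.seq_name, IntervalTree())
            if ref.size > 0:
                tree.addi(ref.start, ref.start + ref.size, block)
        if not self.blocks:
            log.warning("MAF file %s contains no alignment blocks", path)

    def query(self, chrom: str, start: int, end: int) -> list[AlignmentBlock]:
        """Blocks whose reference row overlaps [start, end), in file order."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda b: b.file_order)
        return hits


def map_position(
    block: AlignmentBlock,
    ref_species: str,
    ref_pos: int,
    species: str,
    w: int = 8,
) -> MappedColumn:
    """Map a reference coordinate to a target species within one block."""
    ref = block.row_for(ref_species)
    if ref is None:
        raise MafFormatError(f"block has no reference row for {ref_species!r}")
    if not (ref.start <= ref_pos < ref.start + ref.size):
        raise PositionError(
            f"position {ref_pos} outside reference span "
            f"[{ref.start}, {ref.start + ref.size}) of block {block.file_order}"
        )
    col = int(block.ref_columns(ref_species)[ref_pos - ref.start])
    row = block.row_for(species)
    if row is None:
        return MappedColumn(species=species, aligned=False)
    lo = max(0, col - w)
    hi = min(block.width, col + w + 1)
    window = row.text[lo:hi]
    context = window.replace("-", "")
    offset = len(row.text[lo:col].replace("-", ""))
    return MappedColumn(
        species=species,
        aligned=True,
        target_char=row.text[col],
        target_context=context,
        context_offset=offset,
    )
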