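"""Transcript models and splice-site extraction.

Transcripts are exon chains on a reference genome, held in 0-based
half-open coordinates (the BED convention). Every intron of a
multi-exonic transcript contributes two splice sites: a donor at its
5' end (canonically GT on the transcript strand) and an acceptor at
its 3' end (canonically AG). Splice sites are the unit at which
gene-structure conservation is scored downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

DONOR = "donor"
ACCEPTOR = "acceptor"

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class SpliceSite:
    """One exon/intron boundary of a transcript.

    ``boundary_pos`` is the leftmost reference coordinate (0-based) of
    the intronic dinucleotide in reference orientation: for a '+'
    transcript the donor dinucleotide occupies ``[boundary_pos,
    boundary_pos + 2)`` at the intron 5' end and reads GT on the
    reference; on '-' the same interval holds the reverse complement.
    ``expected_dinucleotide`` is always given on the transcript strand.
    """

    transcript_id: str
    site_kind: str  # donor | acceptor
    chrom: str
    boundary_pos: int
    strand: str
    expected_dinucleotide: str


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain of one transcript on the reference genome."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unknown"  # coding | noncoding | unknown

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"{self.transcript_id}: empty or inverted exon ({start}, {end})"
                )
            if start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exonic(self) -> bool:
        return len(self.exons) >= 2

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def extract_splice_sites(transcript: TranscriptModel) -> list[SpliceSite]:
    """Return the 2(k-1) splice sites of a k-exon transcript.

    A single-exon transcript yields an empty list (such transcripts are
    excluded from conservation scoring). Sites are returned sorted by
    ``boundary_pos``. On the '-' strand donor/acceptor kinds are swapped
    relative to the '+' layout so that the expected dinucleotide is
    always stated on the transcript strand.
    """
    sites: list[SpliceSite] = []
    t = transcript
    for (_, exon_end), (next_start, _) in zip(t.exons, t.exons[1:]):
        # intron spans [exon_end, next_start) in reference coordinates
        if t.strand == "+":
            sites.append(
                SpliceSite(t.transcript_id, DONOR, t.chrom, exon_end, "+", "GT")
            )
            sites.append(
                SpliceSite(t.transcript_id, ACCEPTOR, t.chrom, next_start - 2, "+", "AG")
            )
        else:
            # transcript 5' end of the intron is at the right-hand boundary
            sites.append(
                SpliceSite(t.transcript_id, ACCEPTOR, t.chrom, exon_end, "-", "AG")
            )
            sites.append(
                SpliceSite(t.transcript_id, DONOR, t.chrom, next_start - 2, "-", "GT")
            )
    sites.sort(key=lambda s: s.boundary_pos)
    return sites


def filter_multi_exonic(
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[TranscriptModel], int]:
    """Drop single-exon transcripts, logging how many were excluded."""
    kept = [t for t in transcripts if t.is_multi_exonic]
    n_excluded = len(transcripts) - len(kept)
    if n_excluded:
        log.info("excluded %d single-exon transcript(s)", n_excluded)
    return kept, n_excluded


# ---------------------------------------------------------------------------
# readers


def read_annotation(path: str | Path, format: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from BED12 or GTF.

    ``format`` is ``"bed12"`` or ``"gtf"``; if omitted it is inferred
    from the file suffix. Output is deterministic: sorted by
    (chrom, start, transcript_id).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            format = "bed12"
        elif suffix in (".gtf", ".gff"):
            format = "gtf"
        else:
            raise AnnotationError(
                f"cannot infer annotation format from suffix {suffix!r}; "
                "pass format='bed12' or 'gtf'"
            )
    if format == "bed12":
        transcripts = _read_bed12(path)
    elif format == "gtf":
        transcripts = _read_gtf(path)
    else:
        raise AnnotationError(f"unknown annotation format {format!r}")
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    if not transcripts:
        log.warning("annotation file %s contained no transcripts", path)
    return transcripts


def _read_bed12(path: Path) -> list[TranscriptModel]:
    seen: dict[str, TranscriptModel] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            try:
                model = TranscriptModel(name, chrom, strand, exons)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            _register(seen, model, f"{path}:{lineno}")
    return list(seen.values())


def _read_gtf(path: Path) -> list[TranscriptModel]:
    # accumulate exon records per transcript_id
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # id -> (chrom, strand, biotype)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start_1based = int(fields[3])
                end_closed = int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if not tid:
                raise AnnotationError(
                    f"{path}:{lineno}: exon record without transcript_id"
                )
            chrom, strand = fields[0], fields[6]
            biotype = _biotype_of(attrs)
            if tid in meta and meta[tid][:2] != (chrom, strand):
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tid} spans multiple "
                    "chromosomes or strands"
                )
            meta.setdefault(tid, (chrom, strand, biotype))
            # GTF is 1-based closed; convert to 0-based half-open
            exons.setdefault(tid, []).append((start_1based - 1, end_closed))
    seen: dict[str, TranscriptModel] = {}
    for tid, exon_list in exons.items():
        chrom, strand, biotype = meta[tid]
        model = TranscriptModel(tid, chrom, strand, tuple(sorted(exon_list)), biotype)
        _register(seen, model, str(path))
    return list(seen.values())


def _biotype_of(attrs: dict[str, str]) -> str:
    raw = attrs.get("transcript_biotype") or attrs.get("gene_biotype") or ""
    if raw == "protein_coding":
        return "coding"
    if raw and ("RNA" in raw or "noncoding" in raw or "antisense" in raw):
        return "noncoding"
    return "unknown"


def _register(
    seen: dict[str, TranscriptModel], model: TranscriptModel, where: str
) -> None:
    prior = seen.get(model.transcript_id)
    if prior is None:
        seen[model.transcript_id] = model
    elif prior.exons != model.exons or prior.strand != model.strand:
        raise AnnotationError(
            f"{where}: duplicate transcript_id {model.transcript_id} "
            "with conflicting exon structure"
        )
    else:
        log.warning("duplicate identical record for %s ignored", model.transcript_id)


# ---------------------------------------------------------------------------
# writers


def write_site_table(sites: Iterable[SpliceSite], path: str | Path) -> None:
    """Write splice sites as TSV."""
    with open(path, "w") as out:
        out.write(
            "transcript_id\tsite_kind\tchrom\tboundary_pos\tstrand\t"
            "expected_dinucleotide\n"
        )
        for s in sites:
            out.write(
                f"{s.transcript_id}\t{s.site_kind}\t{s.chrom}\t{s.boundary_pos}\t"
                f"{s.strand}\t{s.expected_dinucleotide}\n"
            )


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12."""
    with open(path, "w") as out:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            starts = ",".join(str(s - t.start) for s, _ in t.exons) + ","
            out.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t{t.strand}\t"
                f"{t.start}\t{t.start}\t0\t{t.n_exons}\t{sizes}\t{starts}\n"
            )
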