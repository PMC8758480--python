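"""Synthetic splice-site turnover fixtures with scripted ground truth.

The generator emulates the inputs of the conservation pipeline: a
vertebrate-like species tree with the reference (human stand-in) as one
leaf, per-transcript exon chains, and splice-site survival along the
tree. Each site survives a branch of length d with probability
exp(-lambda * d), independently per site and branch; once lost on a
lineage it stays lost, so the probability that a site is still found in
a species at patristic distance D from the reference is exp(-lambda*D).
Branches shared by several species are drawn once, giving realistic
correlation between sister lineages. A target transcript set evolves
with an elevated loss rate relative to the background, emulating a
gene set with accelerated gene-structure evolution.

Outputs are standard files (MAF + BED12 + newick + ID lists) plus a
ground-truth table, so every pipeline stage can be checked against
scripted statuses. Around every splice-site dinucleotide, a guard
window is kept free of allowed dinucleotides in every row; scripted
statuses therefore remain exact under any shift window not exceeding
the guard, and substitution noise (applied outside guard windows only)
cannot flip a call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import binom

from . import gene_models
from .conservation import classify_transcript, level_column
from .gene_models import SpliceSite, TranscriptModel, extract_splice_sites
from .setstats import fisher_exact_2x2, patristic_distances

log = logging.getLogger(__name__)

#: synthetic 19-leaf vertebrate tree (reference hg38 plus 18 species);
#: human-patristic distances span ~0.013 (chimp) to ~2.5 (zebrafish)
DEFAULT_TREE = (
    "((((((((((((hg38:0.0065,panTro:0.0065):0.004,gorGor:0.009):0.008,"
    "ponAbe:0.018):0.016,rheMac:0.032):0.030,calJac:0.062):0.090,"
    "micMur:0.140):0.020,(oryCun:0.210,(mm10:0.230,rn6:0.240):0.090):0.060)"
    ":0.015,((canFam:0.130,felCat:0.125):0.060,(bosTau:0.180,susScr:0.160)"
    ":0.040):0.030):0.080,loxAfr:0.280):0.120,monDom:0.620):0.130,"
    "galGal:0.900):0.200,(xenTro:1.500,danRer:1.900):0.350);"
)

DEFAULT_REFERENCE = "hg38"

CHROM = "chrS"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# status codes in the truth matrix
ST_CONSERVED, ST_LOST, ST_NOT_ALIGNABLE = 1, 0, -1
_STATUS_NAMES = {1: "conserved", 0: "lost", -1: "not_alignable"}
# reference-orientation dinucleotide at each site kind x strand
_REF_DINUC = {
    ("donor", "+"): b"GT",
    ("acceptor", "+"): b"AG",
    ("donor", "-"): b"AC",  # revcomp of transcript-strand GT
    ("acceptor", "-"): b"CT",  # revcomp of transcript-strand AG
}
_LOST_DINUC = b"CC"  # never an allowed splice dinucleotide on either strand


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulation run.

    Loss rates are per unit branch length; the default target rate is
    twice the background rate, the contrast under study. ``dropout`` is
    the per-(block, species) probability that the species row is absent
    (the only source of not_alignable calls). ``noise`` is the
    per-position substitution probability outside guard windows.
    """

    seed: int = 0
    tree: str = DEFAULT_TREE
    reference: str = DEFAULT_REFERENCE
    n_background: int = 2000
    n_target: int = 150
    min_exons: int = 2
    max_exons: int = 15
    mean_exon_len: int = 150
    mean_intron_len: int = 400
    min_feature_len: int = 50
    loss_rate_background: float = 0.15
    loss_rate_target: float = 0.30
    dropout: float = 0.0
    noise: float = 0.0
    guard: int = 8
    fragment_blocks: bool = False
    negative_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.loss_rate_background, self.loss_rate_target,
               self.dropout, self.noise) < 0:
            raise ValueError("rates must be non-negative")
        if self.min_exons < 2:
            raise ValueError("transcripts must be multi-exonic (min_exons >= 2)")


def elevated_turnover(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset with an elevated-turnover target set vs a large background.

    150 target / 2000 background transcripts across 18 species, target
    loss rate twice the background rate, with mild alignment dropout
    and substitution noise.
    """
    cfg = SimulationConfig(seed=seed, dropout=0.05, noise=0.01, **overrides)
    if cfg.loss_rate_target < cfg.loss_rate_background:
        raise ValueError(
            "elevated-turnover preset requires loss_rate_target >= loss_rate_background"
        )
    return cfg


# ---------------------------------------------------------------------------
# tree plumbing


def _leaf_edge_paths(
    tree_newick: str, reference: str
) -> tuple[list[str], np.ndarray, dict[str, np.ndarray]]:
    """Per-species edge paths from the reference leaf.

    Returns (species sorted by (distance, name), edge lengths, paths),
    where ``paths[sp]`` indexes the edges on the path reference->sp.
    """
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    leaves = {}
    for leaf in tree.leaf_node_iter():
        leaves[leaf.taxon.label] = leaf
    if reference not in leaves:
        raise ValueError(f"tree has no leaf named {reference!r}")

    def up_edges(node):
        out = []
        while node.parent_node is not None:
            out.append(node.edge)
            node = node.parent_node
        return out

    ref_edges = up_edges(leaves[reference])
    ref_ids = {id(e) for e in ref_edges}
    edge_index: dict[int, int] = {}
    lengths: list[float] = []

    def index_of(edge) -> int:
        key = id(edge)
        if key not in edge_index:
            edge_index[key] = len(lengths)
            lengths.append(float(edge.length or 0.0))
        return edge_index[key]

    paths: dict[str, np.ndarray] = {}
    for label, node in leaves.items():
        if label == reference:
            continue
        node_edges = up_edges(node)
        node_ids = {id(e) for e in node_edges}
        path = [index_of(e) for e in node_edges if id(e) not in ref_ids]
        path += [index_of(e) for e in ref_edges if id(e) not in node_ids]
        paths[label] = np.array(sorted(path), dtype=np.intp)

    lengths_arr = np.asarray(lengths, dtype=float)
    dist = {sp: float(lengths_arr[idx].sum()) for sp, idx in paths.items()}
    species = sorted(paths, key=lambda s: (dist[s], s))
    return species, lengths_arr, paths


# ---------------------------------------------------------------------------
# truth simulation


@dataclass
class SimulatedTruth:
    """Scripted per-(site, species) statuses plus the transcript models."""

    config: SimulationConfig
    transcripts: list[TranscriptModel]
    labels: dict[str, str]  # transcript_id -> target | background
    sites: list[SpliceSite]  # flat, transcript order then boundary order
    site_offsets: np.ndarray  # first flat index of each transcript's sites
    status: np.ndarray  # (n_sites_total, n_species) int8
    species: list[str]
    distances: dict[str, float]
    chrom_length: int
    block_spans: list[tuple[int, int]]  # per transcript
    rng: np.random.Generator = field(repr=False, default=None)

    def status_name(self, code: int) -> str:
        return _STATUS_NAMES[int(code)]


def _draw_length(rng: np.random.Generator, mean: int, minimum: int, size: int):
    # shifted geometric with the stated mean and hard minimum
    return minimum + rng.geometric(1.0 / (mean - minimum + 1), size=size) - 1


def simulate_truth(config: SimulationConfig) -> SimulatedTruth:
    """Simulate transcripts and site survival; no files are written."""
    rng = np.random.default_rng(config.seed)
    species, edge_lengths, paths = _leaf_edge_paths(config.tree, config.reference)
    distances = {sp: float(edge_lengths[idx].sum()) for sp, idx in paths.items()}

    n_total = config.n_target + config.n_background
    labels = {}
    transcripts: list[TranscriptModel] = []
    sites: list[SpliceSite] = []
    offsets = [0]
    block_spans: list[tuple[int, int]] = []
    pad, gap = 20, 100
    cursor = 100
    exon_counts = rng.integers(config.min_exons, config.max_exons + 1, size=n_total)
    for i in range(n_total):
        is_target = i < config.n_target
        tid = f"T{i:05d}" if is_target else f"B{i - config.n_target:05d}"
        labels[tid] = "target" if is_target else "background"
        k = int(exon_counts[i])
        exon_lens = _draw_length(rng, config.mean_exon_len, config.min_feature_len, k)
        intron_lens = _draw_length(
            rng, config.mean_intron_len, config.min_feature_len, k - 1
        )
        strand = "-" if rng.random() < config.negative_strand_fraction else "+"
        block_start = cursor
        pos = cursor + pad
        exons = []
        for j in range(k):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < k - 1:
                pos += int(intron_lens[j])
        block_end = pos + pad
        cursor = block_end + gap
        t = TranscriptModel(tid, CHROM, strand, tuple(exons))
        transcripts.append(t)
        block_spans.append((block_start, block_end))
        tx_sites = extract_splice_sites(t)
        sites.extend(tx_sites)
        offsets.append(offsets[-1] + len(tx_sites))
    offsets = np.asarray(offsets, dtype=np.intp)

    # per-branch survival, shared across species through shared edges
    n_species = len(species)
    status = np.empty((offsets[-1], n_species), dtype=np.int8)
    for lam, lo, hi in (
        (config.loss_rate_target, 0, offsets[config.n_target]),
        (config.loss_rate_background, offsets[config.n_target], offsets[-1]),
    ):
        m = hi - lo
        edge_p = np.exp(-lam * edge_lengths)
        surv = rng.random((m, len(edge_lengths))) < edge_p[None, :]
        for j, sp in enumerate(species):
            conserved = surv[:, paths[sp]].all(axis=1)
            status[lo:hi, j] = np.where(conserved, ST_CONSERVED, ST_LOST)

    # alignment dropout: whole species row absent from a transcript's block
    if config.dropout > 0:
        drop = rng.random((n_total, n_species)) < config.dropout
        for i in range(n_total):
            for j in np.flatnonzero(drop[i]):
                status[offsets[i] : offsets[i + 1], j] = ST_NOT_ALIGNABLE

    return SimulatedTruth(
        config=config,
        transcripts=transcripts,
        labels=labels,
        sites=sites,
        site_offsets=offsets,
        status=status,
        species=species,
        distances=distances,
        chrom_length=cursor,
        block_spans=block_spans,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# file emission


def simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the simulation and write MAF, BED12, newick, ID lists and truth.

    Same seed => byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    rng = truth.rng

    refseq = _reference_sequence(config, truth, rng)

    paths = {
        "maf": outdir / "alignment.maf",
        "bed": outdir / "transcripts.bed",
        "tree": outdir / "tree.nwk",
        "target_ids": outdir / "target_ids.txt",
        "background_ids": outdir / "background_ids.txt",
        "truth": outdir / "ground_truth.tsv",
    }

    _write_maf(paths["maf"], config, truth, refseq, rng)
    gene_models.write_bed12(truth.transcripts, paths["bed"])
    paths["tree"].write_text(config.tree.strip() + "\n")
    for key, label in (("target_ids", "target"), ("background_ids", "background")):
        ids = [t.transcript_id for t in truth.transcripts
               if truth.labels[t.transcript_id] == label]
        paths[key].write_text("".join(i + "\n" for i in ids))
    truth_frame(truth).to_csv(paths["truth"], sep="\t", index=False)
    log.info(
        "simulated %d transcripts (%d target / %d background) x %d species -> %s",
        len(truth.transcripts), config.n_target, config.n_background,
        len(truth.species), outdir,
    )
    return paths


def _reference_sequence(
    config: SimulationConfig, truth: SimulatedTruth, rng: np.random.Generator
) -> np.ndarray:
    seq = _BASES[rng.integers(0, 4, size=truth.chrom_length)]
    g = config.guard
    for site in truth.sites:
        b = site.boundary_pos
        seq[b - g : b] = ord("C")
        seq[b + 2 : b + 2 + g] = ord("C")
        seq[b : b + 2] = np.frombuffer(
            _REF_DINUC[(site.site_kind, site.strand)], dtype=np.uint8
        )
    return seq


def _noise_mask(
    config: SimulationConfig,
    truth: SimulatedTruth,
    tx_index: int,
    block: tuple[int, int],
) -> np.ndarray:
    """Positions within a block eligible for substitution noise."""
    bs, be = block
    ok = np.ones(be - bs, dtype=bool)
    g = config.guard
    lo, hi = truth.site_offsets[tx_index], truth.site_offsets[tx_index + 1]
    for site in truth.sites[lo:hi]:
        ok[max(0, site.boundary_pos - g - bs) : site.boundary_pos + 2 + g - bs] = False
    return ok


def _write_maf(
    path: Path,
    config: SimulationConfig,
    truth: SimulatedTruth,
    refseq: np.ndarray,
    rng: np.random.Generator,
) -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.AlignIO.MafIO import MafWriter
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    src_size = truth.chrom_length
    with open(path, "w") as handle:
        writer = MafWriter(handle)
        writer.write_header()
        for i, t in enumerate(truth.transcripts):
            bs, be = truth.block_spans[i]
            ref_slice = refseq[bs:be]
            rows: list[tuple[str, np.ndarray]] = [(config.reference, ref_slice)]
            lo, hi = truth.site_offsets[i], truth.site_offsets[i + 1]
            noise_ok = (
                _noise_mask(config, truth, i, (bs, be)) if config.noise > 0 else None
            )
            for j, sp in enumerate(truth.species):
                col = truth.status[lo:hi, j]
                if len(col) and (col == ST_NOT_ALIGNABLE).all():
                    continue  # dropout: species row absent from this block
                arr = ref_slice.copy()
                for s_idx in np.flatnonzero(col == ST_LOST):
                    b = truth.sites[lo + s_idx].boundary_pos
                    arr[b - bs : b - bs + 2] = np.frombuffer(
                        _LOST_DINUC, dtype=np.uint8
                    )
                if noise_ok is not None:
                    hitpos = np.flatnonzero(
                        (rng.random(be - bs) < config.noise) & noise_ok
                    )
                    if hitpos.size:
                        old = np.searchsorted(_BASES, arr[hitpos])
                        step = rng.integers(1, 4, size=hitpos.size)
                        arr[hitpos] = _BASES[(old + step) % 4]
                rows.append((sp, arr))
            for span in _block_splits(config, truth, i, (bs, be)):
                msa = MultipleSeqAlignment([])
                for name, arr in rows:
                    sub = arr[span[0] - bs : span[1] - bs]
                    rec = SeqRecord(
                        Seq(sub.tobytes().decode("ascii")),
                        id=f"{name}.{CHROM}",
                        annotations={
                            "start": span[0],
                            "size": span[1] - span[0],
                            "strand": 1,
                            "srcSize": src_size,
                        },
                    )
                    msa.append(rec)
                writer.write_alignment(msa)


def _block_splits(
    config: SimulationConfig,
    truth: SimulatedTruth,
    tx_index: int,
    block: tuple[int, int],
) -> list[tuple[int, int]]:
    """One span per emitted block; the fragmentation preset splits at the
    midpoint of the middle intron (always far from any splice site)."""
    bs, be = block
    if not config.fragment_blocks:
        return [(bs, be)]
    t = truth.transcripts[tx_index]
    introns = [
        (t.exons[j][1], t.exons[j + 1][0]) for j in range(t.n_exons - 1)
    ]
    e, s = introns[len(introns) // 2]
    mid = (e + s) // 2
    return [(bs, mid), (mid, be)]


# ---------------------------------------------------------------------------
# tabular and analytic views


def truth_frame(truth: SimulatedTruth) -> pd.DataFrame:
    """Long ground-truth table: one row per (site, species)."""
    rows = []
    offsets = truth.site_offsets
    for i, t in enumerate(truth.transcripts):
        label = truth.labels[t.transcript_id]
        for flat in range(offsets[i], offsets[i + 1]):
            site = truth.sites[flat]
            for j, sp in enumerate(truth.species):
                rows.append(
                    (t.transcript_id, label, site.site_kind, site.boundary_pos,
                     site.strand, sp, _STATUS_NAMES[int(truth.status[flat, j])])
                )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "set", "site_kind", "boundary_pos", "strand",
                 "species", "status"],
    )


def truth_transcript_table(
    truth: SimulatedTruth,
    min_present: int = 1,
    thresholds: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Transcript-level conservation table straight from scripted truth.

    Same schema as the table produced by the alignment-based pipeline;
    used for statistical experiments where re-emitting and re-parsing
    alignment files would only re-test the (separately validated)
    classification stage.
    """
    offsets = truth.site_offsets
    n_sites = np.diff(offsets)
    rows = []
    for j, sp in enumerate(truth.species):
        col = truth.status[:, j]
        conserved = np.add.reduceat(
            (col == ST_CONSERVED).astype(np.int64), offsets[:-1]
        )
        alignable = np.add.reduceat(
            (col != ST_NOT_ALIGNABLE).astype(np.int64), offsets[:-1]
        )
        for i, t in enumerate(truth.transcripts):
            ns, nc, na = int(n_sites[i]), int(conserved[i]), int(alignable[i])
            frac = nc / ns
            row = {
                "transcript_id": t.transcript_id,
                "species": sp,
                "n_sites": ns,
                "n_conserved": nc,
                "n_alignable": na,
                "fraction_conserved": frac,
                "fraction_alignable": na / ns,
                "present": nc >= min_present,
                "complete": nc == ns,
            }
            for f in thresholds:
                row[level_column(f)] = frac >= f
            rows.append(row)
    return pd.DataFrame(rows)


def expected_rates(
    config: SimulationConfig,
    level: str | float,
    which: str = "background",
    min_present: int = 1,
) -> dict[str, float]:
    """Closed-form expected per-species conservation rates (oracle regime:
    no dropout, no noise).

    With per-site survival p = exp(-lambda * D) at patristic distance D
    and n = 2(k - 1) sites for a k-exon transcript, the number of
    conserved sites is Binomial(n, p); the expected rate at each level
    marginalizes the corresponding tail probability over the uniform
    exon-count distribution.
    """
    lam = (
        config.loss_rate_target if which == "target" else config.loss_rate_background
    )
    ks = np.arange(config.min_exons, config.max_exons + 1)
    ns = 2 * (ks - 1)
    _, edge_lengths, paths = _leaf_edge_paths(config.tree, config.reference)
    out = {}
    for sp, idx in paths.items():
        d = float(edge_lengths[idx].sum())
        p = math.exp(-lam * d)
        if level == "complete":
            vals = p ** ns
        elif level == "present":
            vals = binom.sf(min_present - 1, ns, p)
        else:
            need = np.ceil(float(level) * ns)
            vals = binom.sf(need - 1, ns, p)
        out[sp] = float(np.mean(vals))
    return out


def null_rejection_rates(
    config: SimulationConfig,
    n_reps: int = 500,
    level: str = "complete",
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical per-species type-I error of the set comparison under the
    null of equal turnover (target loss rate forced to the background's).

    Each replicate draws fresh exon counts and per-transcript level
    outcomes from the exact marginal success probability (p^n for
    complete structure, 1-(1-p)^n for presence) and applies the
    two-sided Fisher test per species.
    """
    cfg = replace(config, loss_rate_target=config.loss_rate_background)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    _, edge_lengths, paths = _leaf_edge_paths(cfg.tree, cfg.reference)
    species = sorted(paths, key=lambda s: (float(edge_lengths[paths[s]].sum()), s))
    dist = {sp: float(edge_lengths[paths[sp]].sum()) for sp in species}
    rejections = {sp: 0 for sp in species}
    for _ in range(n_reps):
        k_t = rng.integers(cfg.min_exons, cfg.max_exons + 1, size=cfg.n_target)
        k_b = rng.integers(cfg.min_exons, cfg.max_exons + 1, size=cfg.n_background)
        n_t, n_b = 2 * (k_t - 1), 2 * (k_b - 1)
        for sp in species:
            p = math.exp(-cfg.loss_rate_background * dist[sp])
            if level == "complete":
                pt, pb = p ** n_t, p ** n_b
            elif level == "present":
                pt, pb = 1 - (1 - p) ** n_t, 1 - (1 - p) ** n_b
            else:
                raise ValueError(f"unsupported level {level!r}")
            kt = int((rng.random(cfg.n_target) < pt).sum())
            kb = int((rng.random(cfg.n_background) < pb).sum())
            if kt + kb == 0 or (cfg.n_target - kt) + (cfg.n_background - kb) == 0:
                continue  # degenerate margin, p = 1, never rejects
            pval = fisher_exact_2x2(
                [[kt, cfg.n_target - kt], [kb, cfg.n_background - kb]]
            )
            if pval < alpha:
                rejections[sp] += 1
    return pd.DataFrame(
        {
            "species": species,
            "distance": [dist[sp] for sp in species],
            "n_reps": n_reps,
            "rejection_rate": [rejections[sp] / n_reps for sp in species],
        }
    )
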