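"""End-to-end orchestration: annotation -> MAF -> conservation -> comparison.

Stages exchange plain TSV tables so each one is independently runnable
and re-loadable; outputs are deterministic for fixed inputs and
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import (
    ConservationConfig,
    calls_to_frame,
    run_conservation,
    transcript_table,
)
from .gene_models import extract_splice_sites, read_annotation, write_site_table
from .maf_io import MafIndex
from .setstats import compare_sets, load_tree

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    annotation: Path
    maf: Path
    tree: Path
    target_ids: Path
    background_ids: Path
    outdir: Path
    reference: str
    annotation_format: str | None = None
    species: tuple[str, ...] = ()
    max_shift: int = 6
    min_present: int = 1
    thresholds: tuple[float, ...] = (0.25, 0.5, 0.75)
    include_minor: bool = False
    mode: str = "strict"
    levels: tuple[str, ...] = ("present", "complete")
    alpha: float = 0.05

    def conservation_config(self) -> ConservationConfig:
        return ConservationConfig(
            species=tuple(self.species),
            max_shift=self.max_shift,
            min_present=self.min_present,
            thresholds=tuple(self.thresholds),
            include_minor=self.include_minor,
            mode=self.mode,
        )


def _read_ids(path: Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Writes site_calls.tsv, transcript_conservation.tsv, rates.tsv,
    comparisons.tsv and run.log. Any stage failure aborts with the
    stage name and cause.
    """
    for name in ("annotation", "maf", "tree", "target_ids", "background_ids"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise PipelineError(f"[inputs] {name} path does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("splicecons")
    root.addHandler(handler)
    prior_level = root.level
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        log.info("splicecons %s", __version__)
        log.info("parameters: %s", config)

        stage = "read_annotation"
        try:
            transcripts = read_annotation(config.annotation, config.annotation_format)
            n_single = sum(not t.is_multi_exonic for t in transcripts)
            log.info(
                "read %d transcripts (%d single-exon, excluded)",
                len(transcripts), n_single,
            )
            n_sites = sum(
                len(extract_splice_sites(t)) for t in transcripts if t.is_multi_exonic
            )
            log.info("extracted %d splice sites", n_sites)
            sites = [
                s for t in transcripts if t.is_multi_exonic
                for s in extract_splice_sites(t)
            ]
            write_site_table(sites, outdir / "splice_sites.tsv")

            stage = "index_maf"
            index = MafIndex(config.maf, config.reference)
            log.info(
                "indexed %d MAF blocks; species seen: %s",
                len(index.blocks), ",".join(sorted(index.species_seen)),
            )

            stage = "classify"
            calls, records = run_conservation(
                transcripts, index, config.conservation_config()
            )
            calls_df = calls_to_frame(calls)
            table = transcript_table(records)
            calls_df.to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
            table.to_csv(outdir / "transcript_conservation.tsv", sep="\t", index=False)

            stage = "compare"
            target = _read_ids(config.target_ids)
            background = _read_ids(config.background_ids)
            tree = load_tree(config.tree)
            rates, comparisons = compare_sets(
                table, target, background, tree, config.reference,
                levels=list(config.levels), alpha=config.alpha, mode=config.mode,
            )
            rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
            comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
            log.info("pipeline complete: %s", outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[{stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prior_level)
    return outdir


def load_transcript_table(path: str | Path) -> pd.DataFrame:
    """Re-load a transcript_conservation.tsv with boolean flags restored."""
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col in ("present", "complete") or col.startswith("frac_ge_"):
            if df[col].dtype == object:
                df[col] = df[col].map({"True": True, "False": False})
            df[col] = df[col].astype(bool)
    return df
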