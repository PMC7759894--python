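"""End-to-end orchestration: ingest -> properties -> weighted profile ->
top-N selection -> amphiphilicity scoring -> reports.

The pipeline reads a peptide table, characterizes each sample (weighted and
unweighted property summaries, binned histograms, relative-intensity
abundance), selects the ``top_n`` most abundant peptides longer than
``min_pcl`` residues for amphiphilicity scoring (short peptides cannot form
a well-defined interfacial secondary structure), lists antioxidant
candidates (top-N with PCL <= ``antioxidant_max_pcl``; scores for these
come from external predictors and are only passed through), and writes all
result classes as TSV plus one JSON.  All randomness flows from a single
root seed, so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import amphiphilicity as amph
from . import io_tables, profile

logger = logging.getLogger("hydropep")

__all__ = ["PipelineConfig", "PipelineError", "run_profile", "run_compare"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    peptide_table: Path
    out_dir: Path
    top_n: int = 100
    min_pcl: int = 6                 # exclusive: score peptides with PCL > 6
    antioxidant_max_pcl: int = 30    # inclusive: candidates with PCL <= 30
    null_n: int = 40000
    seed: int = 0
    precision: int = 4
    dialect: io_tables.TableDialect = field(
        default_factory=io_tables.TableDialect
    )

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_pcl >= 65:
            raise ValueError("min_pcl filter leaves no identifiable peptides")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        data["peptide_table"] = Path(data["peptide_table"])
        data["out_dir"] = Path(data["out_dir"])
        return cls(**data)


def run_profile(config: PipelineConfig) -> dict:
    """Run the full characterization; returns result objects and file paths."""
    try:
        parsed = io_tables.read_peptide_table(
            config.peptide_table, dialect=config.dialect
        )
    except (OSError, ValueError) as exc:
        raise PipelineError(f"ingestion: {exc}") from exc
    if not parsed.records:
        raise PipelineError("ingestion: peptide table contains no usable records")
    logger.info(
        "ingestion: %d rows, %d records, %d rejected, %d zero-intensity dropped",
        parsed.n_rows, len(parsed.records), len(parsed.rejections),
        parsed.n_zero_dropped,
    )

    summaries: dict[str, dict[str, float]] = {}
    histograms: list[pd.DataFrame] = []
    abundance: dict[str, pd.DataFrame] = {}
    scored: dict[str, pd.DataFrame] = {}
    antioxidant: dict[str, pd.DataFrame] = {}
    entries_by_sample: dict[str, list[profile.AbundanceEntry]] = {}

    for sample in parsed.samples:
        records = [r for r in parsed.records if r.sample == sample]
        if len(records) < 2:
            logger.warning("profile: sample %s has < 2 records; skipped", sample)
            continue
        try:
            summary = profile.summarize_sample(records)
            counts = parsed.ids_per_sample()[sample]
            summaries[sample] = {**counts, **summary.as_dict()}
            for variable in ("PCL", "PMW", "Pz"):
                frame = profile.histogram(records, variable).to_frame()
                frame.insert(0, "sample", sample)
                histograms.append(frame)
            entries = profile.relative_intensity(records)
        except ValueError as exc:
            raise PipelineError(f"profiling[{sample}]: {exc}") from exc
        entries_by_sample[sample] = entries
        abundance[sample] = pd.DataFrame(
            [{"sequence": e.sequence, "rank": e.rank, "ri_pct": e.ri,
              "intensity": e.intensity} for e in entries]
        )
        logger.info("profile[%s]: %d distinct peptides", sample, len(entries))

        try:
            candidates = profile.top_n(entries, config.top_n,
                                       min_len=config.min_pcl)
            rows = []
            for entry in candidates:
                score = amph.score_peptide(
                    entry.sequence, n=config.null_n, seed=config.seed
                )
                flags = amph.classify(score)
                rows.append({
                    "sequence": entry.sequence,
                    "rank": entry.rank,
                    "ri_pct": entry.ri,
                    "z_alpha": score.z_alpha,
                    "z_beta": score.z_beta,
                    "z_gamma": score.z_gamma,
                    "best_conformation": score.best_conformation,
                    "emulsifier_flags": ",".join(flags),
                })
            scored[sample] = pd.DataFrame(rows)
        except ValueError as exc:
            raise PipelineError(f"scoring[{sample}]: {exc}") from exc
        logger.info("scoring[%s]: %d peptides scored", sample, len(rows))

        anox = profile.top_n(entries, config.top_n,
                             max_len=config.antioxidant_max_pcl)
        antioxidant[sample] = pd.DataFrame(
            [{"sequence": e.sequence, "rank": e.rank, "ri_pct": e.ri}
             for e in anox]
        )

    try:
        paths = io_tables.write_profile_report(
            config.out_dir, summaries, histograms, abundance, scored,
            precision=config.precision,
        )
        for sample, frame in antioxidant.items():
            p = Path(config.out_dir) / f"antioxidant_candidates_{sample}.tsv"
            frame.round(config.precision).to_csv(p, sep="\t", index=False)
            paths[f"antioxidant:{sample}"] = p
    except OSError as exc:
        raise PipelineError(f"reporting: {exc}") from exc

    samples = list(entries_by_sample)
    fold_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for i, sample_a in enumerate(samples):
        for sample_b in samples[i + 1:]:
            table = _fold_change_table(
                entries_by_sample[sample_a], entries_by_sample[sample_b]
            )
            fold_tables[(sample_a, sample_b)] = table
            p = (Path(config.out_dir)
                 / f"fold_change_{io_tables._slug(sample_a)}"
                   f"_vs_{io_tables._slug(sample_b)}.tsv")
            table.to_csv(p, sep="\t", index=False)
            paths[f"fold:{sample_a}|{sample_b}"] = p

    return {
        "parsed": parsed,
        "summaries": summaries,
        "abundance": abundance,
        "scored": scored,
        "antioxidant": antioxidant,
        "fold_changes": fold_tables,
        "paths": paths,
    }


def _fold_change_table(entries_a, entries_b) -> pd.DataFrame:
    ri_a = {e.sequence: e.ri for e in entries_a}
    ri_b = {e.sequence: e.ri for e in entries_b}
    rows = []
    for seq in sorted(set(ri_a) | set(ri_b)):
        a, b = ri_a.get(seq), ri_b.get(seq)
        rows.append({
            "sequence": seq,
            "ri_a_pct": a,
            "ri_b_pct": b,
            "fold_change": (
                profile.format_fold_change(a, b)
                if a is not None and b is not None else None
            ),
        })
    return pd.DataFrame(rows)


def run_compare(report_a: str | Path, report_b: str | Path) -> pd.DataFrame:
    """Fold-change table between two written abundance reports (TSV).

    Sequences present on only one side keep their observed RI with an empty
    ratio; if the reports share no sequences the table is empty and a
    warning is emitted.
    """
    frame_a = pd.read_csv(report_a, sep="\t")
    frame_b = pd.read_csv(report_b, sep="\t")
    ri_a = dict(zip(frame_a["sequence"], frame_a["ri_pct"]))
    ri_b = dict(zip(frame_b["sequence"], frame_b["ri_pct"]))
    if not set(ri_a) & set(ri_b):
        warnings.warn("abundance reports share no sequences")
    rows = []
    for seq in sorted(set(ri_a) | set(ri_b)):
        a, b = ri_a.get(seq), ri_b.get(seq)
        rows.append({
            "sequence": seq,
            "ri_a_pct": a,
            "ri_b_pct": b,
            "fold_change": (
                profile.format_fold_change(a, b)
                if a is not None and b is not None and b > 0 else None
            ),
        })
    return pd.DataFrame(rows)
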