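"""End-to-end orchestration: simulate → annotate → diff → ratios → proteome → report.

A run is driven by a :class:`RunConfig` (YAML round-trippable), writes one
CSV per stage plus a markdown report into the output directory, and returns
a :class:`RunManifest` whose hash is a function of the configuration alone —
identical config and inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import DecoySpec, annotate, fdr_estimate, write_annotation_csv, annotation_table
from .discriminant import compare_groups, discriminant_table
from .glycan_model import make_record, parse_composition
from .msi_io import MsiDataset, load_dataset, save_dataset
from .pathway_ratios import genotype_ratio_table
from .proteome_compare import (
    impute,
    lewis_a_proteins,
    normalize,
    preprocess,
    volcano,
    volcano_png,
    volcano_table,
)
from .synthetic_data import (
    DEFAULT_TRUNCATION_PAIRS,
    NoiseSpec,
    default_glycan_panel,
    simulate_dataset,
    simulate_quant_table,
)

logger = logging.getLogger("glyconodule")

__all__ = ["RunConfig", "RunManifest", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run."""

    seed: int = 0
    # MSI simulation
    n_sections_per_genotype: int = 3
    width: int = 120
    height: int = 120
    pixel_pitch_um: float = 50.0
    # annotation
    tol_ppm: float = 3.0
    k_isotopes: int = 3
    chaos_levels: int = 30
    decoy_draws: int = 3
    # discriminant
    auc_up: float = 0.6
    auc_down: float = 0.4
    unit: str = "pixel"
    # proteomics
    n_proteins: int = 1000
    n_pairs: int = 5
    n_shifted: int = 50
    shift_log2: float = 1.0
    missingness: float = 0.1
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    log2fc_threshold: float = 0.5
    p_threshold: float = 0.05
    # optional pre-existing inputs (skip simulation when given)
    msi_manifest: str | None = None
    quant_csv: str | None = None
    sample_sheet_csv: str | None = None
    glycopeptide_csv: str | None = None

    def __post_init__(self) -> None:
        for name in ("auc_up", "auc_down", "p_threshold", "missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        canonical = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    tool_version: str
    input_digests: dict[str, str]
    outputs: dict[str, str]
    log_path: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage, writing per-stage CSVs and a markdown report.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    input_digests: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = str(path)

    try:
        # --- stage: simulate / load -----------------------------------------
        stage = "simulate"
        try:
            if config.msi_manifest:
                input_digests["msi_manifest"] = _file_digest(Path(config.msi_manifest))
                dataset = load_dataset(config.msi_manifest,
                                       pixel_pitch_um=config.pixel_pitch_um)
                truth = None
            else:
                dataset, truth = simulate_dataset(
                    n_sections_per_genotype=config.n_sections_per_genotype,
                    width=config.width,
                    height=config.height,
                    pixel_pitch_um=config.pixel_pitch_um,
                    noise=NoiseSpec(),
                    k_isotopes=config.k_isotopes,
                    seed=config.seed,
                )
                truth.to_json(out / "ground_truth.json")
                record("ground_truth", out / "ground_truth.json")
            logger.info("simulate: %d sections", len(dataset.sections))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        panel = default_glycan_panel()
        database = [make_record(g.composition) for g in panel]

        # --- stage: annotate ------------------------------------------------
        stage = "annotate"
        try:
            results = annotate(
                dataset, database, tol_ppm=config.tol_ppm,
                k_isotopes=config.k_isotopes, n_levels=config.chaos_levels,
            )
            results = fdr_estimate(
                results,
                DecoySpec(draws_per_target=config.decoy_draws, seed=config.seed),
                dataset, database, tol_ppm=config.tol_ppm,
                k_isotopes=config.k_isotopes, n_levels=config.chaos_levels,
            )
            write_annotation_csv(results, out / "annotations.csv")
            record("annotations", out / "annotations.csv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- stage: diff ----------------------------------------------------
        stage = "diff"
        try:
            records = compare_groups(
                dataset, database, tol_ppm=config.tol_ppm, unit=config.unit,  # type: ignore[arg-type]
            )
            diff_df = discriminant_table(records)
            diff_df.to_csv(out / "discriminant.csv", index=False)
            record("discriminant", out / "discriminant.csv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- stage: ratios --------------------------------------------------
        stage = "ratios"
        try:
            ratio_df = genotype_ratio_table(
                dataset, DEFAULT_TRUNCATION_PAIRS, tol_ppm=config.tol_ppm
            )
            ratio_df.to_csv(out / "ratios.csv", index=False)
            record("ratios", out / "ratios.csv")
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- stage: proteome ------------------------------------------------
        stage = "proteome"
        try:
            if config.quant_csv and config.sample_sheet_csv:
                from .proteome_compare import read_quant_csv, read_glycopeptide_csv

                input_digests["quant_csv"] = _file_digest(Path(config.quant_csv))
                table = read_quant_csv(config.quant_csv, config.sample_sheet_csv)
                glycopeptides = (
                    read_glycopeptide_csv(config.glycopeptide_csv)
                    if config.glycopeptide_csv
                    else pd.DataFrame(columns=["accession", "peptide", "composition"])
                )
            else:
                table, glycopeptides, _ = simulate_quant_table(
                    n_proteins=config.n_proteins,
                    n_pairs=config.n_pairs,
                    n_shifted=config.n_shifted,
                    shift_log2=config.shift_log2,
                    missingness=config.missingness,
                    seed=config.seed,
                )
            chain = normalize(
                impute(preprocess(table), width=config.impute_width,
                       downshift=config.impute_downshift, seed=config.seed)
            )
            vrecords = volcano(chain)
            vdf = volcano_table(vrecords)
            vdf.to_csv(out / "volcano.csv", index=False)
            volcano_png(vrecords, out / "volcano.png")
            record("volcano", out / "volcano.csv")
            lewis = lewis_a_proteins(glycopeptides)
            lewis_df = pd.DataFrame(
                [
                    {"accession": acc, "compositions": ";".join(comps)}
                    for acc, comps in lewis.items()
                ]
            )
            lewis_df.to_csv(out / "lewis_a_proteins.csv", index=False)
            record("lewis_a_proteins", out / "lewis_a_proteins.csv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- stage: report --------------------------------------------------
        stage = "report"
        try:
            ann_df = annotation_table(results)
            top = ann_df.nlargest(10, "msm")
            lines = [
                "# glyconodule run report",
                "",
                f"- config hash: `{config.digest()}`",
                f"- sections: {', '.join(dataset.section_labels)}",
                "",
                "## Top annotations by MSM",
                "",
                top.to_markdown(index=False),
                "",
                "## Discriminant glycans (WT vs mutant)",
                "",
                diff_df.to_markdown(index=False),
                "",
                "## Precursor/product ratios",
                "",
                ratio_df.to_markdown(index=False),
                "",
                "## Differential proteome",
                "",
                f"significant proteins: {int(vdf['significant'].sum())} "
                f"of {len(vdf)}",
                "",
                "## Lewis-a carrier proteins",
                "",
                lewis_df.to_markdown(index=False) if len(lewis_df) else "(none)",
                "",
            ]
            (out / "report.md").write_text("\n".join(lines))
            record("report", out / "report.md")
        except Exception as exc:
            raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = RunManifest(
        config_hash=config.digest(),
        tool_version=__version__,
        input_digests=input_digests,
        outputs=outputs,
        log_path=str(log_path),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
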