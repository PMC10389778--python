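"""End-to-end orchestration: normalize -> induction -> dependence -> enrichment.

The pipeline reads a count (or FPKM) matrix with its sample design,
normalizes it, computes per-background induction tables, runs the
dependence regression on the background-1 induced genes, and optionally
scores gene-set enrichment of the induced, downregulated and dependent
gene lists.  All payload outputs (TSV/JSON) are byte-deterministic for
a fixed config and inputs; the run manifest carries the config echo,
warnings and a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dependence import DEPENDENT_ENHANCED, DEPENDENT_IMPAIRED, FilterConfig, analyze_dependence
from .enrichment import enrich, read_gene_list, read_gmt, write_enrichment_tsv, write_gene_list
from .induction import ThresholdConfig, test_induction, write_induction_tsv
from .matrix import (
    ExpressionMatrix,
    SampleDesign,
    read_expression_tsv,
    read_gene_lengths_tsv,
    write_expression_tsv,
)
from .normalize import to_unit

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class PipelineConfig:
    counts: Path
    design: Path
    out_dir: Path
    lengths: Path | None = None
    gmt: Path | None = None
    universe: Path | None = None
    unit: str = "counts"
    normalize_to: str = "cpm"
    background1: str = "WT"
    background2: str = "KO"
    stimulated: str = "stimulated"
    unstimulated: str = "unstimulated"
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    subset: str = "up"
    pseudocount: float = 1.0
    min_expression: float | None = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = ThresholdConfig(**raw["thresholds"])
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        for key in ("counts", "design", "out_dir", "lengths", "gmt", "universe"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, Path):
                out[key] = str(value)
        return out


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tfdep_version": __version__,
        "config": config.echo(),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
        "outputs": {},
    }

    def _stage(name: str):
        manifest["stages"].append(name)
        return name

    try:
        stage = _stage("load")
        lengths = read_gene_lengths_tsv(config.lengths) if config.lengths else None
        design = SampleDesign.read_tsv(config.design)
        matrix = read_expression_tsv(config.counts, unit=config.unit, design=design, gene_lengths_bp=lengths)

        stage = _stage("normalize")
        normalized = to_unit(matrix, config.normalize_to)
        normalized_path = out_dir / f"normalized_{config.normalize_to}.tsv"
        write_expression_tsv(normalized, normalized_path)
        manifest["outputs"]["normalized"] = str(normalized_path)

        stage = _stage("differential_induction")
        tables = {}
        for background in (config.background1, config.background2):
            records = test_induction(
                normalized,
                background,
                thresholds=config.thresholds,
                pseudocount=config.pseudocount,
                min_expression=config.min_expression,
                stimulated=config.stimulated,
                unstimulated=config.unstimulated,
            )
            if records.attrs.get("n_untestable"):
                manifest["warnings"].append(
                    f"{background}: {records.attrs['n_untestable']} genes untestable (<2 replicates)"
                )
            manifest["outputs"][f"n_filtered_{background}"] = records.attrs.get("n_filtered", 0)
            path = out_dir / f"de_{background}.tsv"
            write_induction_tsv(records, path)
            manifest["outputs"][f"de_{background}"] = str(path)
            tables[background] = records

        stage = _stage("dependence_regression")
        result = analyze_dependence(
            tables[config.background1],
            tables[config.background2],
            subset=config.subset,
            config=config.filter,
        )
        if result.points.attrs.get("n_dropped"):
            manifest["warnings"].append(
                f"dependence: {result.points.attrs['n_dropped']} subset genes missing from one background"
            )
        calls_path = out_dir / "dependence_calls.tsv"
        result.points.to_csv(calls_path, sep="\t", index=False)
        fits_path = out_dir / "dependence_fits.json"
        fits_path.write_text(json.dumps(result.fits_dict(), indent=2, sort_keys=True) + "\n")
        manifest["outputs"]["dependence_calls"] = str(calls_path)
        manifest["outputs"]["dependence_fits"] = str(fits_path)

        queries = {
            "induced": list(tables[config.background1].loc[tables[config.background1]["status"] == "up", "gene_id"]),
            "downregulated": list(
                tables[config.background1].loc[tables[config.background1]["status"] == "down", "gene_id"]
            ),
            "dependent": result.calls(DEPENDENT_IMPAIRED) + result.calls(DEPENDENT_ENHANCED),
        }
        for name, genes in queries.items():
            write_gene_list(genes, out_dir / f"genes_{name}.txt")

        if config.gmt is not None:
            stage = _stage("geneset_enrichment")
            collection = read_gmt(config.gmt)
            if config.universe is not None:
                universe = read_gene_list(config.universe)
            else:
                # default universe: genes passing the expression filter
                universe = list(tables[config.background1]["gene_id"])
            for name, genes in queries.items():
                results = enrich(genes, collection, universe)
                if results.attrs.get("n_query_outside"):
                    manifest["warnings"].append(
                        f"enrichment ({name}): {results.attrs['n_query_outside']} query genes outside universe"
                    )
                path = out_dir / f"enrichment_{name}.tsv"
                write_enrichment_tsv(results, path)
                manifest["outputs"][f"enrichment_{name}"] = str(path)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
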