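"""End-to-end pipeline runs: read or simulate, classify, aggregate, write.

A run executes: input acquisition (on-disk files or a simulated screen) ->
essentiality calls -> per-gene classification -> per-pathway summaries ->
per-line pathway fractions -> separation detection -> cancer-type
enrichment for separated pathways -> plot sidecars -> output TSV/JSON plus
a manifest listing every file written with its SHA-256.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import cluster_viz, io_formats
from .errors import ConfigError, SchemaError
from .essentiality import (
    ClassificationThresholds,
    call_essentiality,
    classify_genes,
    global_category_counts,
    summarize_pathways,
)
from .pathway_context import (
    SeparationConfig,
    cancer_type_enrichment,
    detect_separation,
    pathway_fraction_profile,
)
from .synthetic import SimulationConfig, simulate_screen, write_screen
from .types import FitnessMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "read_classification_tsv"]

CLASSIFICATION_COLUMNS = ["gene_symbol", "entrez", "n_evaluable",
                          "n_essential", "frequency", "category"]


def read_classification_tsv(path: str | Path) -> pd.DataFrame:
    """Load a classification TSV, checking the documented columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLASSIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: classification TSV missing columns {missing}")
    return df


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    Exactly one of ``input_paths`` (matrix / gene_sets / annotations file
    paths) or ``simulate`` (a :class:`SimulationConfig`) must be present.
    """

    out_dir: Path
    seed: int
    simulate: SimulationConfig | None = None
    input_paths: dict[str, Path] | None = None
    model_id_col: str = "ModelID"
    cancer_type_col: str = "OncotreePrimaryDisease"
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)
    separation: SeparationConfig = field(default_factory=SeparationConfig)
    enrich_threshold: float = 0.5
    images: bool = False
    heatmap_metric: str = "euclidean"
    heatmap_linkage: str = "average"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_paths is None):
            raise ConfigError(
                "exactly one of 'simulate' or 'input_paths' must be set")
        if self.input_paths is not None:
            required = {"matrix", "gene_sets", "annotations"}
            missing = required - set(self.input_paths)
            if missing:
                raise ConfigError(f"input_paths missing keys: {sorted(missing)}")
        if not (0 <= self.enrich_threshold < 1):
            raise ConfigError("enrich_threshold must be in [0, 1)")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], *,
                  out_dir: str | Path | None = None,
                  seed: int | None = None) -> "RunConfig":
        """Build from a parsed YAML/JSON mapping with CLI overrides."""
        raw = dict(raw)
        known = {"out_dir", "seed", "simulate", "inputs", "thresholds",
                 "separation", "enrich_threshold", "images", "heatmap"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if seed is None:
            seed = raw.get("seed")
        if seed is None:
            raise ConfigError("a seed is required (config 'seed' or --seed)")
        out = out_dir if out_dir is not None else raw.get("out_dir")
        if out is None:
            raise ConfigError("an output directory is required")

        sim = None
        paths = None
        model_id_col = "ModelID"
        cancer_type_col = "OncotreePrimaryDisease"
        if "simulate" in raw and "inputs" in raw:
            raise ConfigError("config must not set both 'simulate' and 'inputs'")
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"] or {})
            sim_raw.setdefault("seed", seed)
            sim = SimulationConfig.from_dict(sim_raw)
        elif "inputs" in raw:
            inp = dict(raw["inputs"])
            model_id_col = inp.pop("model_id_col", model_id_col)
            cancer_type_col = inp.pop("cancer_type_col", cancer_type_col)
            paths = {k: Path(v) for k, v in inp.items()}
        else:
            raise ConfigError("config needs either 'simulate' or 'inputs'")

        thr_raw = dict(raw.get("thresholds") or {})
        for key in ("aeg_bound", "reg_bound"):
            if key in thr_raw:
                thr_raw[key] = Fraction(str(thr_raw[key]))
        try:
            thresholds = ClassificationThresholds(**thr_raw)
            separation = SeparationConfig(**dict(raw.get("separation") or {}))
        except TypeError as exc:
            raise ConfigError(f"invalid config section: {exc}") from exc
        heat = dict(raw.get("heatmap") or {})
        return cls(
            out_dir=Path(out),
            seed=int(seed),
            simulate=sim,
            input_paths=paths,
            model_id_col=model_id_col,
            cancer_type_col=cancer_type_col,
            thresholds=thresholds,
            separation=separation,
            enrich_threshold=float(raw.get("enrich_threshold", 0.5)),
            images=bool(raw.get("images", False)),
            heatmap_metric=heat.get("metric", "euclidean"),
            heatmap_linkage=heat.get("linkage", "average"),
        )

    def echo(self) -> dict[str, Any]:
        """JSON-serializable echo of the configuration for the manifest."""
        d: dict[str, Any] = {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "thresholds": {
                "score_cutoff": self.thresholds.score_cutoff,
                "aeg_bound": str(self.thresholds.aeg_bound),
                "reg_bound": str(self.thresholds.reg_bound),
            },
            "separation": {"min_score": self.separation.min_score,
                           "min_group": self.separation.min_group},
            "enrich_threshold": self.enrich_threshold,
            "images": self.images,
            "heatmap": {"metric": self.heatmap_metric,
                        "linkage": self.heatmap_linkage},
        }
        if self.simulate is not None:
            sim = self.simulate
            d["simulate"] = {
                "seed": sim.seed,
                "n_cell_lines": sim.n_cell_lines,
                "target_unique_genes": sim.target_unique_genes,
                "target_multi_pathway": sim.target_multi_pathway,
                "score_mode": sim.score_mode,
                "missing_rate": sim.missing_rate,
                "boundary_margin": sim.boundary_margin,
                "n_cancer_types": sim.n_cancer_types,
                "pathway_sizes": dict(sim.pathway_sizes),
                "planted": [p.pathway for p in sim.planted_bimodal],
            }
        else:
            d["inputs"] = {k: str(v) for k, v in (self.input_paths or {}).items()}
        return d


def _pathway_submatrix(matrix: FitnessMatrix,
                       members: tuple[str, ...]) -> FitnessMatrix | None:
    labels, genes = [], []
    for g, lbl in zip(matrix.genes, matrix.gene_labels):
        if g.symbol in members:
            labels.append(lbl)
            genes.append(g)
    if len(labels) < 2:
        return None
    return FitnessMatrix(matrix.scores[labels], genes)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute a full run; returns the manifest dict.

    Raises ``FileNotFoundError`` for missing inputs and
    :class:`~rcd_essentiality.errors.ConfigError` /
    :class:`~rcd_essentiality.errors.SchemaError` for bad configuration —
    the CLI maps these to exit codes 2/3/4.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_hashes: dict[str, str] = {}

    if config.simulate is not None:
        screen = simulate_screen(config.simulate)
        matrix, gene_sets, annotations = (screen.matrix, screen.gene_sets,
                                          screen.annotations)
        sim_dir = out_dir / "inputs"
        written = write_screen(screen, sim_dir)
        input_hashes = {f"inputs/{p.name}": io_formats.file_sha256(p)
                        for p in written.values()}
    else:
        paths = config.input_paths or {}
        for key, p in paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input file for {key!r} not found: {p}")
        matrix = io_formats.read_fitness_matrix(paths["matrix"])
        gene_sets = io_formats.read_gene_sets_gmt(paths["gene_sets"])
        annotations = io_formats.read_cell_annotations(
            paths["annotations"], model_id_col=config.model_id_col,
            cancer_type_col=config.cancer_type_col)
        input_hashes = {str(p): io_formats.file_sha256(p)
                        for p in paths.values()}

    logger.info("pipeline input: %d cell lines x %d genes, %d pathways",
                matrix.shape[0], matrix.shape[1], len(gene_sets))

    calls = call_essentiality(matrix, config.thresholds)
    classification = classify_genes(matrix, config.thresholds)
    summaries = summarize_pathways(classification, gene_sets)
    counts = global_category_counts(classification, gene_sets)
    profile = pathway_fraction_profile(calls, classification, gene_sets)
    separation = detect_separation(profile, config.separation)

    extra: list[tuple[str, Path]] = []

    sep_path = out_dir / "separation.json"
    sep_payload = {
        name: {
            "separated": r.separated,
            "split_value": r.split_value,
            "separation_score": r.separation_score,
            "selected_lines": list(r.selected_lines),
        }
        for name, r in separation.items()
    }
    with open(sep_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(sep_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    extra.append(("separation", sep_path))

    enrich_frames = []
    for name, result in separation.items():
        if not result.separated:
            continue
        table = cancer_type_enrichment(set(result.selected_lines), annotations,
                                       config.enrich_threshold)
        table.insert(0, "pathway", name)
        enrich_frames.append(table)
    if enrich_frames:
        enrichment = pd.concat(enrich_frames, ignore_index=True)
    else:
        enrichment = pd.DataFrame(columns=["pathway", "cancer_type",
                                           "n_selected", "n_total",
                                           "fraction", "enriched"])
    enrich_path = out_dir / "enrichment.tsv"
    with open(enrich_path, "w", encoding="utf-8", newline="\n") as fh:
        enrichment.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    extra.append(("enrichment", enrich_path))

    counts_path = out_dir / "global_counts.json"
    with open(counts_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump({
            "unique": counts.unique,
            "pathway_sums": counts.pathway_sums,
            "n_union": counts.n_union,
            "n_multi_pathway": counts.n_multi_pathway,
            "n_categorized": counts.n_categorized,
            "uncategorized_genes": counts.uncategorized_genes,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    extra.append(("global_counts", counts_path))

    viz_dir = out_dir / "plots"
    viz_dir.mkdir(exist_ok=True)
    for name, members in gene_sets.items():
        slug = "".join(ch if ch.isalnum() else "_" for ch in name).lower()
        bar = cluster_viz.frequency_barplot(
            classification, name, gene_sets, viz_dir / f"bars_{slug}.png",
            write_image=config.images)
        extra.append((f"barplot_sidecar:{name}", bar["sidecar"]))
        if "image" in bar:
            extra.append((f"barplot_image:{name}", bar["image"]))
        sub = _pathway_submatrix(matrix, members)
        if sub is None:
            logger.warning("pathway %r has < 2 matrix genes; no heatmap", name)
            continue
        layout = cluster_viz.hierarchical_layout(
            sub, metric=config.heatmap_metric, method=config.heatmap_linkage)
        heat = cluster_viz.render_heatmap(
            sub, layout, viz_dir / f"heatmap_{slug}.png",
            write_image=config.images)
        extra.append((f"heatmap_sidecar:{name}", heat["sidecar"]))
        if "image" in heat:
            extra.append((f"heatmap_image:{name}", heat["image"]))

    manifest = io_formats.write_outputs(
        classification, summaries, profile.fractions, out_dir,
        config=config.echo(), seed=config.seed, input_hashes=input_hashes,
        extra_outputs=extra,
        created=datetime.now(timezone.utc).isoformat(),
    )
    return manifest
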