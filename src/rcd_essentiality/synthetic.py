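"""Synthetic DepMap-like CRISPR screens with known ground truth.

The generator emulates the structure the pipeline consumes: a cell-line x
gene fitness matrix whose scores follow a two-component mixture (an
essential component below the -1 cutoff and a non-essential component near
0), overlapping pathway gene sets with exact union / multi-pathway targets,
and cancer-type labels. Each gene g has a latent essential-fraction p_g;
its per-line essential states are Bernoulli(p_g) draws, optionally
block-structured for *planted* pathways so that pathway-fraction
separation and cancer-type enrichment can be recovered against a known
answer.

Two score modes:

* ``separated`` — essential scores are drawn uniformly from a bounded
  interval strictly below -1 and non-essential scores strictly above, so
  the cutoff call equals the latent state exactly and pipeline bugs are
  not confounded with sampling noise.
* ``gaussian`` — overlapping normal components (defaults N(-2, 0.25) and
  N(0, 0.25)) exercising boundary behaviour.

All randomness flows through one ``numpy.random.default_rng(seed)``
(PCG64); identical (config, seed) reproduce identical screens
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .essentiality import (
    Category,
    ClassificationThresholds,
    categorize_frequency,
)
from .types import CellLineTable, FitnessMatrix, GeneID, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PATHWAY_SIZES",
    "PlantedBimodal",
    "SimulationConfig",
    "SyntheticScreen",
    "simulate_screen",
    "write_screen",
    "RecoveryReport",
    "recovery_report",
]

#: Default pathway sizes: the 12 regulated-cell-death pathways with the
#: gene counts used throughout the analysis (Parthanatos and Pyroptosis
#: sizes are placeholders, config-overridable).
DEFAULT_PATHWAY_SIZES: dict[str, int] = {
    "Apoptosis": 134,
    "Autosis": 16,
    "Necroptosis": 148,
    "Ferroptosis": 41,
    "Autophagy": 167,
    "Efferocytosis": 156,
    "Mitotic cell death": 38,
    "Lysosome-dependent cell death": 10,
    "MPT-driven necrosis": 16,
    "Immunogenic cell death": 28,
    "Parthanatos": 20,
    "Pyroptosis": 25,
}


@dataclass(frozen=True)
class PlantedBimodal:
    """A pathway given a block-structured essentiality signal.

    ``n_genes`` member genes (preferring genes exclusive to this pathway)
    are made essential with probability ``high_p`` in cell lines of the
    listed cancer types and ``low_p`` elsewhere; the pathway's remaining
    members are forced into the rarely-essential regime. The result is a
    bimodal pathway-fraction profile whose high group tracks the block.
    """

    pathway: str
    cancer_types: tuple[str, ...]
    n_genes: int = 1
    high_p: float = 0.9
    low_p: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("planted n_genes must be >= 1")
        if not (0.0 <= self.low_p < self.high_p <= 1.0):
            raise ConfigError("need 0 <= low_p < high_p <= 1")
        if not self.cancer_types:
            raise ConfigError("planted block needs >= 1 cancer type")


def _default_planted() -> tuple[PlantedBimodal, ...]:
    # Three pathways with block-dependent essentiality: the high-fraction
    # blocks span 12, 3 and 2 cancer types respectively.
    t = [f"TYPE-{i:02d}" for i in range(1, 21)]
    return (
        PlantedBimodal("Autosis", tuple(t[0:12])),
        PlantedBimodal("Lysosome-dependent cell death", tuple(t[12:15])),
        PlantedBimodal("MPT-driven necrosis", tuple(t[15:17])),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic screen; ``seed`` is mandatory.

    ``category_mix`` gives target AEG/PEG/REG proportions for the latent
    essential-fractions (default: the 23:47:549 split over 619 categorized
    genes); ``boundary_margin`` keeps every latent p_g at least that far
    from the 0.10 and 0.90 category bounds so that finite-sample
    frequencies recover the category.
    """

    seed: int
    n_cell_lines: int = 1150
    pathway_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_SIZES))
    target_unique_genes: int = 600
    target_multi_pathway: int = 119
    category_mix: tuple[float, float, float] = (23 / 619, 47 / 619, 549 / 619)
    boundary_margin: float = 0.05
    score_mode: str = "separated"  # or "gaussian"
    essential_range: tuple[float, float] = (-3.0, -1.1)
    nonessential_range: tuple[float, float] = (-0.9, 0.5)
    mu_essential: float = -2.0
    sigma_essential: float = 0.25
    mu_nonessential: float = 0.0
    sigma_nonessential: float = 0.25
    missing_rate: float = 0.0
    n_cancer_types: int = 20
    cancer_type_counts: Mapping[str, int] | None = None
    planted_bimodal: tuple[PlantedBimodal, ...] = field(
        default_factory=_default_planted)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed is mandatory and must be an integer")
        if self.n_cell_lines < 1:
            raise ConfigError("n_cell_lines must be >= 1")
        if any(s < 1 for s in self.pathway_sizes.values()):
            raise ConfigError("every pathway size must be >= 1")
        if self.score_mode not in ("separated", "gaussian"):
            raise ConfigError(f"unknown score_mode {self.score_mode!r}")
        if self.score_mode == "separated":
            if not (self.essential_range[0] < self.essential_range[1] < -1.0):
                raise ConfigError(
                    "separated mode: essential score support must lie "
                    "strictly below -1")
            if not (-1.0 < self.nonessential_range[0] < self.nonessential_range[1]):
                raise ConfigError(
                    "separated mode: non-essential score support must lie "
                    "strictly above -1")
        mix = np.asarray(self.category_mix, dtype=float)
        if mix.size != 3 or (mix < 0).any() or mix.sum() <= 0:
            raise ConfigError("category_mix must be 3 non-negative weights")
        if not (0 <= self.boundary_margin < 0.1):
            raise ConfigError("boundary_margin must be in [0, 0.1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        self._check_gene_set_targets()
        counts = self.resolve_cancer_type_counts()
        if sum(counts.values()) != self.n_cell_lines:
            raise ConfigError(
                "cancer-type line counts must sum to n_cell_lines")
        for planted in self.planted_bimodal:
            if planted.pathway not in self.pathway_sizes:
                raise ConfigError(
                    f"planted pathway {planted.pathway!r} not in pathway_sizes")
            unknown = set(planted.cancer_types) - set(counts)
            if unknown:
                raise ConfigError(
                    f"planted block references unknown cancer types: "
                    f"{sorted(unknown)}")

    def _check_gene_set_targets(self) -> None:
        total = sum(self.pathway_sizes.values())
        unique = self.target_unique_genes
        multi = self.target_multi_pathway
        n_pathways = len(self.pathway_sizes)
        extras = total - unique
        if unique < 1:
            raise ConfigError("target_unique_genes must be >= 1")
        if multi < 0 or multi > unique:
            raise ConfigError("target_multi_pathway must be in [0, unique]")
        if extras < 0:
            raise ConfigError(
                f"sum of pathway sizes ({total}) < target_unique_genes "
                f"({unique}): targets infeasible")
        if multi == 0 and extras != 0:
            raise ConfigError(
                "overlap targets infeasible: extra memberships but no "
                "multi-pathway genes allowed")
        if multi > 0 and extras < multi:
            raise ConfigError(
                f"overlap targets infeasible: {multi} multi-pathway genes "
                f"need >= {multi} extra memberships, have {extras}")
        if multi > 0 and extras > multi * (n_pathways - 1):
            raise ConfigError(
                "overlap targets infeasible: extra memberships exceed "
                "multi-pathway capacity")

    @classmethod
    def from_dict(cls, raw: Mapping[str, object]) -> "SimulationConfig":
        """Build from a parsed YAML/JSON mapping (lists become tuples)."""
        d = dict(raw)
        if d.get("planted_bimodal") is not None:
            planted = []
            for item in d["planted_bimodal"]:  # type: ignore[union-attr]
                if isinstance(item, PlantedBimodal):
                    planted.append(item)
                else:
                    entry = dict(item)
                    entry["cancer_types"] = tuple(entry.get("cancer_types", ()))
                    try:
                        planted.append(PlantedBimodal(**entry))
                    except TypeError as exc:
                        raise ConfigError(
                            f"invalid planted_bimodal entry: {exc}") from exc
            d["planted_bimodal"] = tuple(planted)
        for key in ("category_mix", "essential_range", "nonessential_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])  # type: ignore[arg-type]
        try:
            return cls(**d)  # type: ignore[arg-type]
        except TypeError as exc:
            raise ConfigError(f"invalid simulation config: {exc}") from exc

    def resolve_cancer_type_counts(self) -> dict[str, int]:
        """Cancer-type -> number of cell lines (even split by default)."""
        if self.cancer_type_counts is not None:
            return dict(self.cancer_type_counts)
        labels = [f"TYPE-{i:02d}" for i in range(1, self.n_cancer_types + 1)]
        counts = _apportion(self.n_cell_lines,
                            np.ones(self.n_cancer_types))
        return dict(zip(labels, counts))


@dataclass
class SyntheticScreen:
    """A generated screen plus its latent truth."""

    matrix: FitnessMatrix
    gene_sets: GeneSetCollection
    annotations: CellLineTable
    truth: pd.DataFrame          # gene_symbol, entrez, p_g, true_category, planted
    latent_states: pd.DataFrame  # bool, same axes as matrix.scores
    config: SimulationConfig


def _apportion(total: int, weights: np.ndarray) -> list[int]:
    """Largest-remainder apportionment of *total* across weights."""
    w = np.asarray(weights, dtype=float)
    quotas = total * w / w.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts.tolist()


def _build_gene_sets(
    rng: np.random.Generator,
    sizes: Mapping[str, int],
    n_unique: int,
    n_multi: int,
    symbols: Sequence[str],
) -> GeneSetCollection:
    """Overlapping gene sets hitting the union and multi-pathway targets exactly.

    Multi-pathway genes are constructed first: each receives >= 2 distinct
    pathway memberships sampled proportional to remaining pathway capacity;
    the leftover capacity is filled with single-membership genes.
    """
    names = list(sizes)
    capacity = np.array([sizes[n] for n in names], dtype=int)
    extras = int(capacity.sum()) - n_unique

    # membership count per multi gene: start at 2, round-robin the rest
    memberships = [2] * n_multi
    leftover = extras - n_multi
    i = 0
    while leftover > 0:
        if memberships[i % n_multi] < len(names):
            memberships[i % n_multi] += 1
            leftover -= 1
        i += 1

    order = rng.permutation(n_unique)
    multi_idx = order[:n_multi]
    single_idx = order[n_multi:]

    assignment: dict[str, list[str]] = {n: [] for n in names}
    for gi, m in zip(multi_idx, sorted(memberships, reverse=True)):
        open_paths = np.nonzero(capacity > 0)[0]
        if open_paths.size < m:
            raise ConfigError(
                "overlap construction dead-end: not enough pathways with "
                "remaining capacity")
        probs = capacity[open_paths] / capacity[open_paths].sum()
        chosen = rng.choice(open_paths, size=m, replace=False, p=probs)
        for pi in chosen:
            assignment[names[pi]].append(symbols[gi])
            capacity[pi] -= 1

    slots = [pi for pi, cap in enumerate(capacity) for _ in range(cap)]
    if len(slots) != len(single_idx):
        raise ConfigError("overlap construction mismatch; targets infeasible")
    for gi, pi in zip(single_idx, slots):
        assignment[names[pi]].append(symbols[gi])

    # stable within-pathway order: as assigned (multi first, then fill)
    return GeneSetCollection(
        {n: assignment[n] for n in names},
        provenance={n: "synthetic" for n in names},
    )


def simulate_screen(config: SimulationConfig) -> SyntheticScreen:
    """Generate a synthetic screen from a validated configuration.

    Deterministic for fixed (config, seed): gene sets are built first,
    then latent essential-fractions, planted overrides, latent states,
    scores and the missing mask, in that fixed order.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.target_unique_genes
    n_lines = config.n_cell_lines

    width = max(4, len(str(n_genes)))
    symbols = [f"RCD{i + 1:0{width}d}" for i in range(n_genes)]
    genes = [GeneID(symbol=s, entrez=100_000 + i + 1)
             for i, s in enumerate(symbols)]

    gene_sets = _build_gene_sets(
        rng, config.pathway_sizes, n_genes, config.target_multi_pathway,
        symbols)

    # --- latent essential-fractions by category ---------------------------
    m = config.boundary_margin
    counts = _apportion(n_genes, np.asarray(config.category_mix))
    categories = np.concatenate([
        np.full(counts[0], 0),   # AEG
        np.full(counts[1], 1),   # PEG
        np.full(counts[2], 2),   # REG
    ])
    categories = categories[rng.permutation(n_genes)]
    p = np.empty(n_genes)
    p[categories == 0] = rng.uniform(0.9 + m, 1.0, (categories == 0).sum())
    p[categories == 1] = rng.uniform(0.1 + m, 0.9 - m, (categories == 1).sum())
    p[categories == 2] = rng.uniform(0.0, 0.1 - m, (categories == 2).sum())

    # --- cell lines and cancer types --------------------------------------
    type_counts = config.resolve_cancer_type_counts()
    cancer_types = np.repeat(list(type_counts), list(type_counts.values()))
    model_ids = [f"ACH-SY{i + 1:04d}" for i in range(n_lines)]
    annotations = CellLineTable(pd.DataFrame({
        CellLineTable.MODEL_ID: model_ids,
        CellLineTable.CANCER_TYPE: cancer_types,
    }))

    # --- planted pathway overrides ----------------------------------------
    sym_index = {s: i for i, s in enumerate(symbols)}
    membership = gene_sets.membership_counts()
    planted_flag = np.zeros(n_genes, dtype=bool)
    prob = np.tile(p, (n_lines, 1))  # (line, gene) essential probability
    planted_members: set[str] = set()
    for block_spec in config.planted_bimodal:
        planted_members.update(gene_sets.genes(block_spec.pathway))
    for block_spec in config.planted_bimodal:
        members = list(gene_sets.genes(block_spec.pathway))
        exclusive = [g for g in members
                     if membership[g] == 1 and not planted_flag[sym_index[g]]]
        pool = exclusive or [g for g in members if not planted_flag[sym_index[g]]]
        if len(pool) < block_spec.n_genes:
            raise ConfigError(
                f"planted pathway {block_spec.pathway!r}: cannot select "
                f"{block_spec.n_genes} genes")
        chosen = rng.choice(len(pool), size=block_spec.n_genes, replace=False)
        chosen_syms = [pool[i] for i in sorted(chosen)]
        block = np.isin(cancer_types, block_spec.cancer_types)
        block_frac = block.mean()
        for g in chosen_syms:
            gi = sym_index[g]
            planted_flag[gi] = True
            prob[:, gi] = np.where(block, block_spec.high_p, block_spec.low_p)
            p[gi] = block_frac * block_spec.high_p + (1 - block_frac) * block_spec.low_p
        # remaining members drop to the rarely-essential regime
        for g in members:
            gi = sym_index[g]
            if not planted_flag[gi]:
                p[gi] = rng.uniform(0.0, 0.1 - m)
                prob[:, gi] = p[gi]

    # --- latent states, scores, missingness -------------------------------
    states = rng.random((n_lines, n_genes)) < prob
    if config.score_mode == "separated":
        ess = rng.uniform(*config.essential_range, (n_lines, n_genes))
        non = rng.uniform(*config.nonessential_range, (n_lines, n_genes))
    else:
        ess = rng.normal(config.mu_essential, config.sigma_essential,
                         (n_lines, n_genes))
        non = rng.normal(config.mu_nonessential, config.sigma_nonessential,
                         (n_lines, n_genes))
    scores = np.where(states, ess, non)
    if config.missing_rate > 0:
        missing = rng.random((n_lines, n_genes)) < config.missing_rate
        scores = np.where(missing, np.nan, scores)

    labels = [g.label for g in genes]
    frame = pd.DataFrame(scores, index=pd.Index(model_ids), columns=labels)
    matrix = FitnessMatrix(frame, genes)
    latent = pd.DataFrame(states, index=frame.index, columns=labels)

    thresholds = ClassificationThresholds()
    truth = pd.DataFrame({
        "gene_symbol": symbols,
        "entrez": [g.entrez for g in genes],
        "p_g": p,
        "true_category": [categorize_frequency(float(v), thresholds).value
                          for v in p],
        "planted": planted_flag,
    })
    logger.info(
        "simulated screen: %d lines x %d genes (%s mode), %d pathways, "
        "union %d, multi-pathway %d",
        n_lines, n_genes, config.score_mode, len(gene_sets),
        len(gene_sets.union_symbols()),
        len(gene_sets.multi_pathway_symbols()))
    return SyntheticScreen(matrix=matrix, gene_sets=gene_sets,
                           annotations=annotations, truth=truth,
                           latent_states=latent, config=config)


def write_screen(screen: SyntheticScreen, out_dir: str | Path) -> dict[str, Path]:
    """Write a screen in the exact on-disk formats the readers consume."""
    from . import io_formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": io_formats.write_fitness_matrix(
            screen.matrix, out_dir / "matrix.csv"),
        "gene_sets": io_formats.write_gene_sets_gmt(
            screen.gene_sets, out_dir / "pathways.gmt"),
        "annotations": io_formats.write_cell_annotations(
            screen.annotations, out_dir / "annotations.csv"),
    }
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        screen.truth.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = truth_path
    return paths


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the latent truth of one screen.

    Accuracy is computed over non-planted genes whose p_g is at least
    ``margin`` away from both category bounds; near-boundary and planted
    genes are tallied separately. ``max_abs_freq_vs_latent`` compares the
    pipeline's frequency with the latent empirical essential fraction over
    evaluable cells (zero in separated mode).
    """

    n_genes: int
    n_margin: int
    n_near_boundary: int
    n_planted: int
    margin: float
    accuracy: float
    confusion: dict[tuple[str, str], int]
    mean_abs_freq_error: float
    max_abs_freq_vs_latent: float


def recovery_report(
    screen: SyntheticScreen,
    classification: pd.DataFrame,
    margin: float | None = None,
) -> RecoveryReport:
    """Confusion counts, category accuracy and frequency error vs truth."""
    if margin is None:
        margin = screen.config.boundary_margin
    truth = screen.truth
    merged = truth.merge(
        classification[["gene_symbol", "frequency", "category",
                        "n_evaluable", "n_essential"]],
        on="gene_symbol", how="left", validate="one_to_one")
    if merged["category"].isna().any():
        missing = merged.loc[merged["category"].isna(), "gene_symbol"].tolist()
        raise ValidationError(
            f"classification does not cover screen genes: {missing[:10]}")

    # latent empirical fraction over evaluable (non-missing) cells
    evaluable = screen.matrix.scores.notna().to_numpy()
    states = screen.latent_states.to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        latent_frac = (states & evaluable).sum(axis=0) / evaluable.sum(axis=0)
    max_dev = float(np.nanmax(np.abs(
        merged["frequency"].to_numpy(dtype=float) - latent_frac)))

    not_planted = ~merged["planted"].to_numpy(dtype=bool)
    pg = merged["p_g"].to_numpy(dtype=float)
    in_margin = (np.abs(pg - 0.1) >= margin) & (np.abs(pg - 0.9) >= margin)
    eligible = not_planted & in_margin

    sub = merged[eligible]
    confusion: dict[tuple[str, str], int] = {}
    for true_cat, pred_cat in zip(sub["true_category"], sub["category"]):
        key = (true_cat, pred_cat)
        confusion[key] = confusion.get(key, 0) + 1
    correct = int((sub["true_category"] == sub["category"]).sum())
    n_margin = int(eligible.sum())
    accuracy = correct / n_margin if n_margin else float("nan")
    mean_err = float(np.mean(np.abs(
        sub["frequency"].to_numpy(dtype=float) - sub["p_g"].to_numpy())))

    return RecoveryReport(
        n_genes=len(merged),
        n_margin=n_margin,
        n_near_boundary=int((not_planted & ~in_margin).sum()),
        n_planted=int((~not_planted).sum()),
        margin=float(margin),
        accuracy=accuracy,
        confusion=confusion,
        mean_abs_freq_error=mean_err,
        max_abs_freq_vs_latent=max_dev,
    )
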