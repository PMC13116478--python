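"""Essentiality calling and the always/partially/rarely-essential trichotomy.

A gene is called *essential* in a cell line when its fitness-effect score is
strictly below the cutoff (default -1: knocking the gene out costs at least
as much growth as the median known-essential gene). Per gene, the
essentiality frequency is the proportion of evaluable (non-missing) cell
lines with an essential call, and the trichotomy is:

* always essential (AEG): frequency strictly greater than 0.90,
* rarely essential (REG): frequency strictly less than 0.10,
* partially essential (PEG): the closed interval [0.10, 0.90].

Boundary comparisons use exact rationals (n_essential / n_evaluable against
fractional bounds), so a gene essential in exactly 90% of lines is a PEG
regardless of float rounding.  A gene's category is a global property of its
frequency across all cell lines — pathway summaries reuse the global
category, they never re-classify per pathway.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import FitnessMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "ClassificationThresholds",
    "EssentialityCalls",
    "call_essentiality",
    "essentiality_frequency",
    "categorize_frequency",
    "classify_genes",
    "summarize_pathways",
    "global_category_counts",
    "GlobalCounts",
]


class Category(str, enum.Enum):
    """Essentiality-frequency trichotomy."""

    AEG = "always_essential"
    PEG = "partially_essential"
    REG = "rarely_essential"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_fraction(x: float | int | str | Fraction) -> Fraction:
    # str(float) round-trips the shortest decimal, so Fraction("0.9") == 9/10
    # rather than the binary float nearest 0.9
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Score cutoff and frequency bounds for the trichotomy.

    ``score_cutoff`` is on the fitness-effect scale (essential iff score
    strictly below it); ``aeg_bound`` and ``reg_bound`` are frequency
    fractions compared exactly.
    """

    score_cutoff: float = -1.0
    aeg_bound: Fraction = field(default=Fraction(9, 10))
    reg_bound: Fraction = field(default=Fraction(1, 10))

    def __post_init__(self) -> None:
        object.__setattr__(self, "aeg_bound", _as_fraction(self.aeg_bound))
        object.__setattr__(self, "reg_bound", _as_fraction(self.reg_bound))
        if not (0 < self.reg_bound < self.aeg_bound < 1):
            raise ValidationError(
                f"need 0 < reg_bound < aeg_bound < 1, got "
                f"{self.reg_bound}, {self.aeg_bound}"
            )
        if not np.isfinite(self.score_cutoff):
            raise ValidationError("score_cutoff must be finite")


@dataclass
class EssentialityCalls:
    """Per-(cell line, gene) essential / non-essential / missing calls.

    ``calls`` is a pandas nullable-boolean frame on the same axes as the
    source matrix: True = essential, False = non-essential, NA = the score
    was missing.
    """

    calls: pd.DataFrame
    thresholds: ClassificationThresholds

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def gene_labels(self) -> list[str]:
        return list(self.calls.columns)


def call_essentiality(
    matrix: FitnessMatrix,
    thresholds: ClassificationThresholds | None = None,
) -> EssentialityCalls:
    """Binary essentiality calls: essential iff score < cutoff (strict).

    Missing scores propagate to missing calls. A score exactly at the
    cutoff is non-essential.
    """
    thresholds = thresholds or ClassificationThresholds()
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("cannot call essentiality on an empty matrix")
    values = matrix.scores
    calls = (values < thresholds.score_cutoff).astype("boolean")
    calls = calls.mask(values.isna())
    return EssentialityCalls(calls=calls, thresholds=thresholds)


def essentiality_frequency(
    gene_calls: pd.Series | np.ndarray | list,
) -> tuple[Fraction, int, int]:
    """(frequency, n_evaluable, n_essential) for one gene's calls.

    Missing calls are excluded from the denominator; a gene with no
    evaluable call has no defined frequency and raises.
    """
    s = pd.Series(gene_calls, dtype="boolean")
    n_evaluable = int(s.notna().sum())
    if n_evaluable == 0:
        name = getattr(gene_calls, "name", None)
        raise ValidationError(
            f"gene {name!r} has no evaluable calls; frequency undefined"
        )
    n_essential = int((s == True).sum())  # noqa: E712 - NA-aware comparison
    return Fraction(n_essential, n_evaluable), n_evaluable, n_essential


def categorize_frequency(
    frequency: Fraction | float,
    thresholds: ClassificationThresholds | None = None,
) -> Category:
    """Map an essentiality frequency to its category (exact comparison)."""
    thresholds = thresholds or ClassificationThresholds()
    f = _as_fraction(frequency)
    if not (0 <= f <= 1):
        raise ValidationError(f"frequency must be in [0, 1], got {f}")
    if f > thresholds.aeg_bound:
        return Category.AEG
    if f < thresholds.reg_bound:
        return Category.REG
    return Category.PEG


def classify_genes(
    matrix: FitnessMatrix,
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene classification table for every gene with >= 1 evaluable call.

    Returns a DataFrame with columns ``gene_symbol``, ``entrez``,
    ``n_evaluable``, ``n_essential``, ``frequency``, ``category``, in the
    matrix's gene order.  Genes whose scores are all missing are dropped
    from the table and logged; ``df.attrs["all_missing_genes"]`` lists them.
    """
    thresholds = thresholds or ClassificationThresholds()
    calls = call_essentiality(matrix, thresholds)
    notna = calls.calls.notna().to_numpy()
    essential = calls.calls.fillna(False).to_numpy(dtype=bool)
    n_evaluable = notna.sum(axis=0)
    n_essential = essential.sum(axis=0)

    rows = []
    all_missing: list[str] = []
    for i, gene in enumerate(matrix.genes):
        if n_evaluable[i] == 0:
            all_missing.append(gene.symbol)
            continue
        freq = Fraction(int(n_essential[i]), int(n_evaluable[i]))
        rows.append({
            "gene_symbol": gene.symbol,
            "entrez": gene.entrez,
            "n_evaluable": int(n_evaluable[i]),
            "n_essential": int(n_essential[i]),
            "frequency": float(freq),
            "category": categorize_frequency(freq, thresholds).value,
        })
    df = pd.DataFrame(
        rows,
        columns=["gene_symbol", "entrez", "n_evaluable", "n_essential",
                 "frequency", "category"],
    )
    df.attrs["all_missing_genes"] = all_missing
    if all_missing:
        logger.warning("%d genes had no evaluable scores: %s",
                       len(all_missing), all_missing[:10])
    logger.info("classified %d genes (%d AEG, %d PEG, %d REG)",
                len(df),
                int((df["category"] == Category.AEG.value).sum()),
                int((df["category"] == Category.PEG.value).sum()),
                int((df["category"] == Category.REG.value).sum()))
    return df


def _category_of(classification: pd.DataFrame) -> dict[str, str]:
    symbols = classification["gene_symbol"]
    if symbols.duplicated().any():
        dupes = symbols[symbols.duplicated()].unique().tolist()
        raise ValidationError(
            f"ambiguous gene symbols in classification: {dupes}; "
            "symbol-based pathway matching requires unique symbols"
        )
    return dict(zip(symbols, classification["category"]))


def summarize_pathways(
    classification: pd.DataFrame,
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Per-pathway AEG/PEG/REG counts over genes present in the matrix.

    Pathway genes absent from the classification go to ``missing_genes``
    and are excluded from the counts, so ``n_aeg + n_peg + n_reg ==
    n_present`` always holds. A pathway with no matched gene yields a row
    with ``n_present == 0`` plus a warning.
    """
    category_of = _category_of(classification)
    rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in category_of]
        missing = [g for g in members if g not in category_of]
        cats = [category_of[g] for g in present]
        if not present:
            logger.warning("pathway %r matched no genes in the matrix", name)
        if missing:
            logger.info("pathway %r: %d annotated genes absent from matrix: %s",
                        name, len(missing), missing[:10])
        rows.append({
            "pathway": name,
            "n_annotated": len(members),
            "n_present": len(present),
            "n_aeg": sum(c == Category.AEG.value for c in cats),
            "n_peg": sum(c == Category.PEG.value for c in cats),
            "n_reg": sum(c == Category.REG.value for c in cats),
            "missing_genes": missing,
        })
    return pd.DataFrame(
        rows,
        columns=["pathway", "n_annotated", "n_present", "n_aeg", "n_peg",
                 "n_reg", "missing_genes"],
    )


@dataclass
class GlobalCounts:
    """Deduplicated category totals over the union of pathway genes.

    ``unique`` counts each categorized gene once regardless of how many
    pathways it belongs to; ``pathway_sums`` counts it once per pathway
    membership (the column sums of the per-pathway summary).
    """

    unique: dict[str, int]
    pathway_sums: dict[str, int]
    n_union: int
    n_multi_pathway: int
    n_categorized: int
    uncategorized_genes: list[str]


def global_category_counts(
    classification: pd.DataFrame,
    gene_sets: GeneSetCollection,
) -> GlobalCounts:
    """Unique AEG/PEG/REG totals over all pathway genes, plus pathway-level sums.

    A gene in several pathways contributes once to the unique totals (its
    category is global) and once per membership to the pathway-level sums.
    """
    category_of = _category_of(classification)
    union = gene_sets.union_symbols()
    unique = {c.value: 0 for c in Category}
    uncategorized = []
    for g in union:
        cat = category_of.get(g)
        if cat is None:
            uncategorized.append(g)
        else:
            unique[cat] += 1
    summary = summarize_pathways(classification, gene_sets)
    pathway_sums = {
        Category.AEG.value: int(summary["n_aeg"].sum()),
        Category.PEG.value: int(summary["n_peg"].sum()),
        Category.REG.value: int(summary["n_reg"].sum()),
    }
    return GlobalCounts(
        unique=unique,
        pathway_sums=pathway_sums,
        n_union=len(union),
        n_multi_pathway=len(gene_sets.multi_pathway_symbols()),
        n_categorized=len(union) - len(uncategorized),
        uncategorized_genes=uncategorized,
    )
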