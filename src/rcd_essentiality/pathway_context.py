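"""Per-cell-line pathway essentiality fractions, separation, enrichment.

For each cell line and pathway, the pathway essentiality fraction is the
number of AEG/PEG-category pathway genes called essential in that line,
divided by the number of pathway genes present in the matrix (all
categories). Most pathways show a fairly constant fraction across lines; a
pathway whose fraction distribution splits into distinct low/high groups is
flagged by a deterministic one-dimensional Otsu rule, and the high-group
lines are then tested for cancer-type enrichment: a cancer type is enriched
when strictly more than half of its lines fall in the selected group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .essentiality import Category, EssentialityCalls
from .types import CellLineTable, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayFractionProfile",
    "pathway_fraction_profile",
    "SeparationConfig",
    "SeparationResult",
    "otsu_split",
    "detect_separation",
    "cancer_type_enrichment",
]


@dataclass
class PathwayFractionProfile:
    """Cell lines x pathways matrix of essentiality fractions in [0, 1].

    ``meta`` holds per-pathway ``n_present`` (the denominator) and
    ``n_aeg_peg`` (the maximum attainable numerator), so every fraction is
    bounded by ``n_aeg_peg / n_present``.
    """

    fractions: pd.DataFrame
    meta: pd.DataFrame  # index = pathway, columns = n_present, n_aeg_peg

    @property
    def pathways(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.fractions.index)


def pathway_fraction_profile(
    calls: EssentialityCalls,
    classification: pd.DataFrame,
    gene_sets: GeneSetCollection,
) -> PathwayFractionProfile:
    """Per-(cell line, pathway) essentiality fraction.

    Numerator: pathway genes whose *global* category is AEG or PEG and
    whose call in that line is essential (missing calls count as
    non-essential). Denominator: all pathway genes present in the matrix,
    REGs included. Pathways with no present gene are excluded with a
    warning.
    """
    category_of = dict(zip(classification["gene_symbol"],
                           classification["category"]))
    symbol_of_label = {}
    for label in calls.gene_labels:
        # label is "SYMBOL (ENTREZ)" or a bare symbol
        symbol_of_label[label.split(" (")[0]] = label
    essential = calls.calls.fillna(False)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in category_of and g in symbol_of_label]
        if not present:
            logger.warning("pathway %r has no genes in the matrix; skipped", name)
            continue
        aeg_peg = [g for g in present
                   if category_of[g] in (Category.AEG.value, Category.PEG.value)]
        if aeg_peg:
            labels = [symbol_of_label[g] for g in aeg_peg]
            numer = essential[labels].to_numpy(dtype=float).sum(axis=1)
        else:
            numer = np.zeros(len(calls.cell_line_ids))
        cols[name] = numer / len(present)
        meta_rows.append({"pathway": name, "n_present": len(present),
                          "n_aeg_peg": len(aeg_peg)})

    fractions = pd.DataFrame(cols, index=pd.Index(calls.cell_line_ids,
                                                  name="model_id"))
    meta = pd.DataFrame(meta_rows,
                        columns=["pathway", "n_present", "n_aeg_peg"]
                        ).set_index("pathway")
    return PathwayFractionProfile(fractions=fractions, meta=meta)


@dataclass(frozen=True)
class SeparationConfig:
    """Settings for the Otsu-based separation rule.

    ``min_score`` is the minimum between-group / total variance ratio at
    the best split. The best-split ratio of *unimodal* data is itself
    substantial (0.75 for a uniform distribution, about 0.64 for a
    Gaussian), so the default 0.85 sits above anything unimodal while
    two-regime profiles score near 1. ``min_group`` requires both groups to
    contain at least that many cell lines.
    """

    min_score: float = 0.85
    min_group: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_score <= 1):
            raise ValidationError("min_score must be in (0, 1]")
        if self.min_group < 1:
            raise ValidationError("min_group must be >= 1")


@dataclass
class SeparationResult:
    """Outcome of the separation test for one pathway."""

    pathway: str
    separated: bool
    split_value: float | None
    separation_score: float
    selected_lines: tuple[str, ...]  # upper group, original line order


def otsu_split(values: np.ndarray) -> tuple[float | None, float, int]:
    """Best two-class split of 1-D values by between-group variance.

    Returns ``(threshold, score, n_upper)`` where *threshold* is the
    midpoint of the gap at the best split (None if the values are
    constant), *score* is between-group variance over total variance at
    that split, and *n_upper* is the size of the upper group. Only splits
    between distinct values are considered; ties in score keep the split
    with the larger lower group (lower index first in the sorted order).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    total_var = float(x.var())
    if n < 2 or total_var == 0.0:
        return None, 0.0, 0
    csum = np.cumsum(x)
    k = np.arange(1, n)  # lower group = x[:k]
    w0 = k / n
    w1 = 1.0 - w0
    mu0 = csum[:-1] / k
    mu1 = (csum[-1] - csum[:-1]) / (n - k)
    between = w0 * w1 * (mu0 - mu1) ** 2
    valid = x[1:] > x[:-1]  # split must separate distinct values
    if not valid.any():
        return None, 0.0, 0
    between = np.where(valid, between, -np.inf)
    best = int(np.argmax(between))  # first max -> larger... lower k first
    score = float(between[best] / total_var)
    threshold = float((x[best] + x[best + 1]) / 2.0)
    return threshold, score, n - (best + 1)


def detect_separation(
    profile: PathwayFractionProfile,
    config: SeparationConfig | None = None,
) -> dict[str, SeparationResult]:
    """Flag pathways whose fraction distribution splits into two groups.

    A pathway is *separated* when the best Otsu split explains at least
    ``min_score`` of the total variance and both groups hold at least
    ``min_group`` lines; its ``selected_lines`` are the upper group.
    Constant profiles are never separated.
    """
    config = config or SeparationConfig()
    n_lines = len(profile.cell_line_ids)
    if n_lines < 10:
        raise ValidationError(
            f"separation detection needs >= 10 cell lines, got {n_lines}"
        )
    results: dict[str, SeparationResult] = {}
    lines = np.asarray(profile.cell_line_ids)
    for name in profile.pathways:
        vals = profile.fractions[name].to_numpy(dtype=float)
        threshold, score, n_upper = otsu_split(vals)
        separated = (
            threshold is not None
            and score >= config.min_score
            and n_upper >= config.min_group
            and (vals.size - n_upper) >= config.min_group
        )
        if separated:
            selected = tuple(lines[vals > threshold])
        else:
            selected = ()
        results[name] = SeparationResult(
            pathway=name,
            separated=bool(separated),
            split_value=threshold if separated else None,
            separation_score=score,
            selected_lines=selected,
        )
        logger.info("pathway %r: separation score %.3f -> %s",
                    name, score, "separated" if separated else "not separated")
    return results


def cancer_type_enrichment(
    selected: set[str] | frozenset[str] | list[str] | tuple[str, ...],
    annotations: CellLineTable,
    enrich_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-cancer-type fraction of selected cell lines.

    One row per cancer type with >= 1 annotated line: ``n_selected``,
    ``n_total``, ``fraction`` and ``enriched`` (fraction strictly above
    *enrich_threshold*). Selected IDs absent from the annotation table are
    dropped with a warning; rows sort by fraction descending then type
    name. An empty selection yields a valid all-zero table.
    """
    selected = set(selected)
    annotated_ids = set(annotations.model_ids)
    unknown = selected - annotated_ids
    if unknown:
        logger.warning("%d selected lines missing from annotations, dropped: %s",
                       len(unknown), sorted(unknown)[:10])
    selected &= annotated_ids

    table = annotations.table
    rows = []
    for cancer_type, group in table.groupby(CellLineTable.CANCER_TYPE, sort=True):
        ids = set(group[CellLineTable.MODEL_ID])
        n_sel = len(ids & selected)
        n_tot = len(ids)
        frac = n_sel / n_tot
        rows.append({
            "cancer_type": cancer_type,
            "n_selected": n_sel,
            "n_total": n_tot,
            "fraction": frac,
            "enriched": frac > enrich_threshold,
        })
    df = pd.DataFrame(rows, columns=["cancer_type", "n_selected", "n_total",
                                     "fraction", "enriched"])
    df = df.sort_values(["fraction", "cancer_type"],
                        ascending=[False, True]).reset_index(drop=True)
    return df
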