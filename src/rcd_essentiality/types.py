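"""Core containers for CRISPR gene-dependency analysis.

The in-memory model mirrors what the pipeline reads from disk: a gene
fitness-effect matrix (cell lines x genes, DepMap ``CRISPRGeneEffect``
layout), a named collection of pathway gene sets, and a cell-line
annotation table mapping model IDs to cancer types.  Scores are real-valued
fitness effects where values below the essentiality cutoff (-1 by
convention) mark a gene as essential in that cell line; gaps in the screen
are explicit missing values, never zeros.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GeneID",
    "FitnessMatrix",
    "GeneSetCollection",
    "CellLineTable",
]


@dataclass(frozen=True, order=True)
class GeneID:
    """A gene key: HGNC-style symbol plus optional Entrez ID.

    The (symbol, entrez) pair is the unique gene key within one matrix;
    symbols alone may in principle collide across Entrez IDs.
    """

    symbol: str
    entrez: int | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be a non-empty string")
        if any(ch.isspace() for ch in self.symbol):
            raise ValidationError(f"gene symbol contains whitespace: {self.symbol!r}")
        if self.entrez is not None and self.entrez < 1:
            raise ValidationError(f"entrez ID must be >= 1, got {self.entrez}")

    @property
    def label(self) -> str:
        """DepMap column-header form, e.g. ``"TP53 (7157)"``."""
        if self.entrez is None:
            return self.symbol
        return f"{self.symbol} ({self.entrez})"


class FitnessMatrix:
    """Gene fitness-effect scores for cell lines x genes.

    Parameters
    ----------
    scores
        DataFrame indexed by model ID with one float column per gene
        (column labels are the DepMap-style gene labels). NaN means the
        (cell line, gene) pair was not measured.
    genes
        GeneID per column, in column order.
    """

    def __init__(self, scores: pd.DataFrame, genes: Sequence[GeneID]):
        genes = tuple(genes)
        if scores.shape[1] != len(genes):
            raise ValidationError(
                f"{scores.shape[1]} score columns but {len(genes)} gene IDs"
            )
        ids = scores.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell-line IDs: {dupes}")
        keys = [(g.symbol, g.entrez) for g in genes]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int | None]] = set()
            dup = [k for k in keys if k in seen or seen.add(k)]  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate gene keys: {sorted(set(dup))}")
        values = scores.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            raise ValidationError("scores must be finite or missing; found +/-inf")
        self.scores = scores.astype(float)
        self.genes = genes

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def gene_labels(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        """(n cell lines, n genes)."""
        return self.scores.shape

    @property
    def n_missing(self) -> int:
        return int(self.scores.isna().to_numpy().sum())

    def symbol_column(self, symbol: str) -> str | None:
        """Column label for a gene symbol, or None if absent.

        Raises if the symbol maps to more than one (symbol, entrez) key —
        matching pathway genes by bare symbol is then ambiguous.
        """
        hits = [lbl for g, lbl in zip(self.genes, self.scores.columns) if g.symbol == symbol]
        if len(hits) > 1:
            raise ValidationError(f"gene symbol {symbol!r} is ambiguous in this matrix")
        return hits[0] if hits else None

    def equals(self, other: "FitnessMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.scores.index.equals(other.scores.index)
            and self.scores.equals(other.scores)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"FitnessMatrix({n} cell lines x {m} genes, {self.n_missing} missing)"


class GeneSetCollection:
    """Named pathway gene sets; overlaps between pathways are allowed.

    Within-pathway duplicates are removed at construction, keeping first
    occurrence order so file order round-trips.
    """

    def __init__(
        self,
        pathways: Mapping[str, Iterable[str]],
        provenance: Mapping[str, str] | None = None,
    ):
        self._pathways: dict[str, tuple[str, ...]] = {}
        for name, symbols in pathways.items():
            if not name:
                raise ValidationError("pathway name must be non-empty")
            if name in self._pathways:
                raise ValidationError(f"duplicate pathway name: {name!r}")
            deduped = list(dict.fromkeys(symbols))
            if not deduped:
                raise ValidationError(f"pathway {name!r} has an empty gene set")
            self._pathways[name] = tuple(deduped)
        self.provenance = dict(provenance or {})

    @property
    def names(self) -> list[str]:
        return list(self._pathways)

    def genes(self, name: str) -> tuple[str, ...]:
        return self._pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self._pathways

    def __len__(self) -> int:
        return len(self._pathways)

    def items(self):
        return self._pathways.items()

    def union_symbols(self) -> list[str]:
        """All distinct symbols across pathways, first-seen order."""
        return list(dict.fromkeys(s for genes in self._pathways.values() for s in genes))

    def membership_counts(self) -> dict[str, int]:
        """Symbol -> number of pathways it belongs to."""
        counts: dict[str, int] = {}
        for genes in self._pathways.values():
            for s in genes:
                counts[s] = counts.get(s, 0) + 1
        return counts

    def multi_pathway_symbols(self) -> list[str]:
        return [s for s, c in self.membership_counts().items() if c >= 2]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneSetCollection({len(self)} pathways, "
            f"{len(self.union_symbols())} unique genes)"
        )


@dataclass
class CellLineTable:
    """Model ID -> cancer-type label, one row per cell line."""

    table: pd.DataFrame = field(repr=False)

    MODEL_ID = "model_id"
    CANCER_TYPE = "cancer_type"

    def __post_init__(self) -> None:
        required = {self.MODEL_ID, self.CANCER_TYPE}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
        ids = self.table[self.MODEL_ID]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate model IDs in annotations: {dupes}")
        if (self.table[self.CANCER_TYPE].astype(str).str.len() == 0).any():
            raise ValidationError("cancer type labels must be non-empty")
        self.table = self.table[[self.MODEL_ID, self.CANCER_TYPE]].reset_index(drop=True)

    @property
    def model_ids(self) -> list[str]:
        return self.table[self.MODEL_ID].tolist()

    def cancer_type_of(self) -> dict[str, str]:
        return dict(zip(self.table[self.MODEL_ID], self.table[self.CANCER_TYPE]))

    def __len__(self) -> int:
        return len(self.table)
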