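"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* Fitness matrix: CSV in the DepMap ``CRISPRGeneEffect`` dialect — first
  column holds model IDs (header cell empty or named), remaining headers are
  ``"SYMBOL (ENTREZ)"`` gene labels, cells are floats with empty/``NA``/
  ``NaN`` marking unmeasured pairs.
* Pathway gene sets: standard GMT (tab-separated: name, description,
  member symbols).
* Cell-line annotations: CSV with configurable model-ID and cancer-type
  column names (DepMap ``Model.csv`` names by default).
* Outputs: UTF-8, LF-terminated TSVs with fixed column order plus a JSON
  run manifest.

Readers fail loudly: duplicate keys, malformed labels and non-numeric cells
raise :class:`~rcd_essentiality.errors.ParseError` with coordinates rather
than being coerced. Row and column order is preserved from file order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError, SchemaError
from .types import CellLineTable, FitnessMatrix, GeneID, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "parse_gene_label",
    "read_fitness_matrix",
    "write_fitness_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_cell_annotations",
    "write_cell_annotations",
    "write_outputs",
    "validate_manifest",
    "file_sha256",
]

_GENE_LABEL_RE = re.compile(r"^(?P<symbol>\S+)\s*\((?P<entrez>\d+)\)$")

#: cell contents treated as missing scores (exact match after stripping)
MISSING_TOKENS = frozenset({"", "NA", "NaN"})


def parse_gene_label(label: str) -> GeneID:
    """Parse a DepMap-style ``"SYMBOL (ENTREZ)"`` column header.

    Leading/trailing whitespace is stripped; the Entrez part must be a
    parenthesized positive integer.
    """
    if not isinstance(label, str) or not label.strip():
        raise ParseError(f"empty or non-string gene label: {label!r}")
    m = _GENE_LABEL_RE.match(label.strip())
    if m is None:
        raise ParseError(
            f"malformed gene label {label!r}: expected 'SYMBOL (ENTREZ)'"
        )
    entrez = int(m.group("entrez"))
    if entrez < 1:
        raise ParseError(f"malformed gene label {label!r}: entrez must be >= 1")
    return GeneID(symbol=m.group("symbol"), entrez=entrez)


def read_fitness_matrix(path: str | Path) -> FitnessMatrix:
    """Read a gene fitness-effect matrix in the DepMap CSV dialect.

    Empty, ``NA`` and ``NaN`` cells become missing scores; any other
    non-numeric cell raises with its (model ID, gene label) coordinates.
    """
    path = Path(path)
    # parse the header ourselves: pandas silently renames duplicate columns
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
    genes = [parse_gene_label(c) for c in header[1:]]
    keys = [(g.symbol, g.entrez) for g in genes]
    if len(set(keys)) != len(keys):
        seen: set[tuple[str, int | None]] = set()
        dup = sorted({k for k in keys if k in seen or seen.add(k)})  # type: ignore[func-returns-value]
        raise ParseError(f"{path}: duplicate gene keys: {dup}")

    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                          skiprows=1, header=None, index_col=0)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(1, len(genes) + 1),
                           index=pd.Index([], dtype=str), dtype=str)
    if raw.shape[1] != len(genes):
        raise ParseError(
            f"{path}: header has {len(genes)} gene columns but data rows "
            f"have {raw.shape[1]}")
    raw.columns = [g.label for g in genes]
    raw.index = raw.index.astype(str).str.strip()
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate model IDs: {dupes}")

    stripped = raw.apply(lambda col: col.str.strip())
    missing_np = stripped.isin(MISSING_TOKENS).to_numpy()
    cells = np.where(missing_np, "nan", stripped.to_numpy(dtype=object))

    def _bad_cell(r: int, c: int) -> ParseError:
        return ParseError(
            f"{path}: non-numeric cell {stripped.iat[r, c]!r} at "
            f"row {raw.index[r]!r}, column {raw.columns[c]!r}")

    try:
        # numpy's parser is correctly rounded, so written floats round-trip
        values = cells.astype(np.float64)
    except ValueError:
        for r in range(cells.shape[0]):
            for c in range(cells.shape[1]):
                try:
                    float(cells[r, c])
                except ValueError:
                    raise _bad_cell(r, c) from None
        raise  # pragma: no cover - unreachable
    bad = np.isnan(values) & ~missing_np  # catches stray 'nan' spellings
    if bad.any():
        r, c = (int(v[0]) for v in np.nonzero(bad))
        raise _bad_cell(r, c)
    numeric = pd.DataFrame(values, index=raw.index,
                           columns=[g.label for g in genes])
    matrix = FitnessMatrix(numeric, genes)
    logger.info(
        "read %s: %d cell lines x %d genes, %d missing cells",
        path, matrix.shape[0], matrix.shape[1], matrix.n_missing,
    )
    return matrix


def write_fitness_matrix(matrix: FitnessMatrix, path: str | Path) -> Path:
    """Write a matrix back in the same DepMap CSV dialect (empty cell = missing)."""
    path = Path(path)
    df = matrix.scores.copy()
    df.index.name = None
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, lineterminator="\n")
    return path


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read pathway gene sets from a GMT file.

    One pathway per line: name, description, then member symbols, all
    tab-separated. Within-pathway duplicate symbols are removed (first
    occurrence kept); duplicate pathway names are an error.
    """
    path = Path(path)
    pathways: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *symbols = fields
            name = name.strip()
            if not name:
                raise ParseError(f"{path}:{lineno}: empty pathway name")
            if name in pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            members = [s.strip() for s in symbols if s.strip()]
            if not members:
                raise ParseError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = members
            provenance[name] = desc
    collection = GeneSetCollection(pathways, provenance)
    logger.info(
        "read %s: %d pathways, %d unique genes, %d in >1 pathway",
        path, len(collection), len(collection.union_symbols()),
        len(collection.multi_pathway_symbols()),
    )
    return collection


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection.items():
            desc = collection.provenance.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


def read_cell_annotations(
    path: str | Path,
    model_id_col: str = "ModelID",
    cancer_type_col: str = "OncotreePrimaryDisease",
) -> CellLineTable:
    """Read a cell-line annotation CSV (model ID -> cancer type).

    Column names default to the DepMap model-table convention and are
    configurable. Rows whose cancer type is an unknown label are kept
    verbatim; duplicate model IDs are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (model_id_col, cancer_type_col):
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {col!r}; found {list(df.columns)}"
            )
    table = df[[model_id_col, cancer_type_col]].rename(
        columns={model_id_col: CellLineTable.MODEL_ID,
                 cancer_type_col: CellLineTable.CANCER_TYPE}
    )
    if table[CellLineTable.MODEL_ID].duplicated().any():
        dupes = table[CellLineTable.MODEL_ID][
            table[CellLineTable.MODEL_ID].duplicated()
        ].unique().tolist()
        raise ParseError(f"{path}: duplicate model IDs: {dupes}")
    result = CellLineTable(table)
    logger.info("read %s: %d annotated cell lines", path, len(result))
    return result


def write_cell_annotations(
    table: CellLineTable,
    path: str | Path,
    model_id_col: str = "ModelID",
    cancer_type_col: str = "OncotreePrimaryDisease",
) -> Path:
    path = Path(path)
    out = table.table.rename(
        columns={CellLineTable.MODEL_ID: model_id_col,
                 CellLineTable.CANCER_TYPE: cancer_type_col}
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# pipeline outputs


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


MANIFEST_REQUIRED_KEYS = ("tool", "version", "created", "seed", "config",
                          "inputs", "outputs")


def validate_manifest(manifest: Mapping[str, Any]) -> None:
    """Check a run manifest against the shipped schema (docs/manifest-schema)."""
    missing = [k for k in MANIFEST_REQUIRED_KEYS if k not in manifest]
    if missing:
        raise SchemaError(f"manifest missing keys: {missing}")
    if not isinstance(manifest["outputs"], list):
        raise SchemaError("manifest 'outputs' must be a list")
    for entry in manifest["outputs"]:
        for k in ("name", "path", "sha256"):
            if k not in entry:
                raise SchemaError(f"manifest output entry missing {k!r}: {entry}")
    if not isinstance(manifest["inputs"], dict):
        raise SchemaError("manifest 'inputs' must be a mapping path -> sha256")


def write_outputs(
    classification: pd.DataFrame,
    summaries: pd.DataFrame,
    fractions: pd.DataFrame,
    out_dir: str | Path,
    *,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
    input_hashes: Mapping[str, str] | None = None,
    extra_outputs: Sequence[tuple[str, Path]] = (),
    created: str = "",
) -> dict[str, Any]:
    """Write the core result tables plus a JSON run manifest.

    Writes ``classification.tsv``, ``pathway_summary.tsv``,
    ``pathway_fractions.tsv`` and ``manifest.json`` into *out_dir* and
    returns the manifest dict. ``extra_outputs`` lets the pipeline register
    additional files (separation report, enrichment table, plot sidecars)
    so the manifest lists every file written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    class_path = out_dir / "classification.tsv"
    _write_tsv(classification, class_path)

    summ = summaries.copy()
    if "missing_genes" in summ.columns:
        summ["missing_genes"] = summ["missing_genes"].map(
            lambda v: ";".join(v) if isinstance(v, (list, tuple)) else str(v)
        )
    summary_path = out_dir / "pathway_summary.tsv"
    _write_tsv(summ, summary_path)

    frac = fractions.reset_index().rename(columns={"index": "model_id"})
    frac_path = out_dir / "pathway_fractions.tsv"
    _write_tsv(frac, frac_path)

    outputs = [
        ("classification", class_path),
        ("pathway_summary", summary_path),
        ("pathway_fractions", frac_path),
        *((name, Path(p)) for name, p in extra_outputs),
    ]
    manifest: dict[str, Any] = {
        "tool": "rcd-essentiality",
        "version": __version__,
        "created": created,
        "seed": seed,
        "config": dict(config or {}),
        "inputs": dict(input_hashes or {}),
        "outputs": [
            {
                "name": name,
                "path": str(p.relative_to(out_dir)) if p.is_relative_to(out_dir)
                        else str(p),
                "sha256": file_sha256(p),
            }
            for name, p in outputs
        ],
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    validate_manifest(manifest)
    logger.info("wrote %d output files to %s", len(outputs) + 1, out_dir)
    return manifest
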