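"""Readers, writers and validated containers for the pipeline's tabular formats.

The pipeline's central objects are a gene × sample CPM matrix, a clinical
metadata table, a stress-responsive gene panel (each gene annotated with the
direction its expression is expected to move under stress), and gene-set
collections in GMT format used by the overrepresentation stage.

Gene identifiers are matched case-insensitively after whitespace trimming,
and panel entries may carry an alias (protein symbols such as PSD95 are
common in the stress literature while count matrices use gene symbols such
as DLG4).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class FormatError(ValueError):
    """A file does not parse under the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


# --------------------------------------------------------------------------
# gene panel


class Direction(str, enum.Enum):
    """Expected direction of a panel gene's expression under stress."""

    UP = "UP"
    DOWN = "DOWN"
    VARIABLE = "VARIABLE"


@dataclass(frozen=True)
class PanelEntry:
    symbol: str
    direction: Direction
    alias: str | None = None


class GenePanel:
    """Stress-responsive gene panel with per-gene stress directions.

    Invariants: symbols are unique (case-insensitive); labeling and
    stress-index use require at least one UP and one DOWN entry, which is
    checked at the point of use rather than at construction so that purely
    descriptive panels remain representable.
    """

    def __init__(self, entries: Iterable[PanelEntry]):
        entries = list(entries)
        seen: set[str] = set()
        for e in entries:
            key = e.symbol.strip().casefold()
            if not key:
                raise ValidationError("empty gene symbol in panel")
            if key in seen:
                raise ValidationError(f"duplicate panel gene symbol: {e.symbol!r}")
            seen.add(key)
        self.entries: list[PanelEntry] = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenePanel) and self.entries == other.entries

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def genes_with(self, direction: Direction) -> list[str]:
        return [e.symbol for e in self.entries if e.direction is direction]

    def resolve(self, matrix_genes: Sequence[str]) -> dict[str, str]:
        """Map each panel symbol to the matching matrix gene id.

        Matching is case-insensitive on the trimmed symbol, falling back to
        the entry's alias. Raises ``ValidationError`` naming every panel gene
        absent from the matrix.
        """
        lookup = {g.strip().casefold(): g for g in matrix_genes}
        out: dict[str, str] = {}
        missing: list[str] = []
        for e in self.entries:
            hit = lookup.get(e.symbol.strip().casefold())
            if hit is None and e.alias:
                hit = lookup.get(e.alias.strip().casefold())
            if hit is None:
                missing.append(e.symbol)
            else:
                out[e.symbol] = hit
        if missing:
            raise ValidationError(
                "panel genes missing from expression matrix: " + ", ".join(missing)
            )
        return out


def read_panel(path: str | Path) -> GenePanel:
    """Read a gene panel from YAML (``genes:`` list) or plain text lines.

    The plain-text dialect is one gene per line: ``SYMBOL DIRECTION [ALIAS]``,
    whitespace-separated, ``#`` comments allowed. Direction must be one of
    UP / DOWN / VARIABLE (case-insensitive).
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError:
        doc = None
    if isinstance(doc, dict) and "genes" in doc:
        entries = []
        for item in doc["genes"]:
            if not isinstance(item, dict) or "symbol" not in item or "direction" not in item:
                raise FormatError("panel YAML entries need 'symbol' and 'direction'")
            entries.append(
                PanelEntry(
                    symbol=str(item["symbol"]).strip(),
                    direction=_parse_direction(str(item["direction"])),
                    alias=(str(item["alias"]).strip() if item.get("alias") else None),
                )
            )
        return GenePanel(entries)
    # plain-line dialect
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"panel line {lineno}: missing direction column: {raw!r}")
        entries.append(
            PanelEntry(
                symbol=fields[0],
                direction=_parse_direction(fields[1]),
                alias=fields[2] if len(fields) > 2 else None,
            )
        )
    return GenePanel(entries)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    doc = {
        "genes": [
            {
                "symbol": e.symbol,
                "direction": e.direction.value,
                **({"alias": e.alias} if e.alias else {}),
            }
            for e in panel.entries
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _parse_direction(token: str) -> Direction:
    try:
        return Direction(token.strip().upper())
    except ValueError:
        raise ValidationError(
            f"unknown stress direction {token!r}; expected UP, DOWN or VARIABLE"
        ) from None


#: The 19-gene stress-responsive panel used throughout: cytokines and
#: superoxide dismutases rise under stress, neurotrophic/synaptic genes fall,
#: and a third class has inconsistent reported direction.
def default_stress_panel() -> GenePanel:
    up = ["IL1B", "IL6", "IFNG", "TNF", "SOD1", "SOD2", "SOD3"]
    down = ["BDNF", "IL10", "DLG4", "SYP", "SNCA", "SNCB", "SNCG"]
    variable = ["APOA1", "APOA2", "NR3C1", "S100B", "SLC6A4"]
    aliases = {"DLG4": "PSD95", "NR3C1": "GR", "SLC6A4": "5HTT"}
    entries = (
        [PanelEntry(g, Direction.UP, aliases.get(g)) for g in up]
        + [PanelEntry(g, Direction.DOWN, aliases.get(g)) for g in down]
        + [PanelEntry(g, Direction.VARIABLE, aliases.get(g)) for g in variable]
    )
    return GenePanel(entries)


# --------------------------------------------------------------------------
# expression matrix


class ExpressionMatrix:
    """Gene × sample matrix of non-negative CPM values.

    Wraps a pandas DataFrame (genes in rows). Invariants: no negative
    entries, no duplicate gene or sample ids.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            gene = values.index[np.where(arr < 0)[0][0]]
            raise ValidationError(f"negative expression value (gene {gene!r})")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.shape == other.values.shape
            and list(self.values.index) == list(other.values.index)
            and list(self.values.columns) == list(other.values.columns)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy())
        )


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix.

    ``tsv``: genes in rows, first column gene ids, header row of sample ids.
    ``mtx``: MatrixMarket file with sidecar ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` name files next to it (one id per line).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df)
    if fmt == "mtx":
        mat = mmread(str(path))
        genes = _read_lines(path.parent / f"{path.stem}.genes.txt")
        samples = _read_lines(path.parent / f"{path.stem}.samples.txt")
        arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if arr.shape != (len(genes), len(samples)):
            raise FormatError(
                f"MTX shape {arr.shape} inconsistent with {len(genes)} gene / "
                f"{len(samples)} sample names"
            )
        return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        matrix.values.to_csv(path, sep="\t", index_label="gene")
        return
    if fmt == "mtx":
        mmwrite(str(path), coo_matrix(matrix.values.to_numpy()))
        _write_lines(path.parent / f"{path.stem}.genes.txt", matrix.gene_ids)
        _write_lines(path.parent / f"{path.stem}.samples.txt", matrix.sample_ids)
        return
    raise ValueError(f"unknown expression format {format!r}")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar name file: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _write_lines(path: Path, lines: Iterable[str]) -> None:
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# sample metadata

DIAGNOSES = ("SZ", "CONTROL")
SEXES = ("F", "M")
FAMILY_HISTORY = ("present", "absent", "unknown")
DEATH_CATEGORIES = ("inflammatory", "non_inflammatory", "malignancy")

_METADATA_COLUMNS = [
    "diagnosis",
    "age_years",
    "sex",
    "rin",
    "pmi_hours",
    "cpz_eq_mg",
    "family_history",
    "death_category",
]


class SampleMetadata:
    """Per-sample clinical covariates (diagnosis, age, sex, RIN, PMI, CPZ-eq,
    family-history flag, cause-of-death category).

    Missing values are explicit: numeric columns use NaN, family history uses
    the literal ``unknown``. RIN must be positive when present.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if table.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        bad = set(table["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise ValidationError(f"unknown diagnosis values: {sorted(bad)}")
        bad = set(table["sex"]) - set(SEXES)
        if bad:
            raise ValidationError(f"unknown sex values: {sorted(bad)}")
        bad = set(table["family_history"]) - set(FAMILY_HISTORY)
        if bad:
            raise ValidationError(f"unknown family_history values: {sorted(bad)}")
        dc = table["death_category"].dropna()
        bad = set(dc) - set(DEATH_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown death_category values: {sorted(bad)}")
        rin = pd.to_numeric(table["rin"], errors="raise")
        if (rin.dropna() <= 0).any():
            raise ValidationError("RIN must be > 0 when present")
        self.table = table.loc[:, _METADATA_COLUMNS].copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])

    def require_match(self, matrix: ExpressionMatrix) -> None:
        if set(self.sample_ids) != set(matrix.sample_ids):
            raise ValidationError("metadata sample ids do not match expression matrix")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample")


# --------------------------------------------------------------------------
# gene sets (GMT)


class GeneSetCollection:
    """Named gene sets (order-preserving); names unique, members non-empty."""

    def __init__(self, sets: Iterable[tuple[str, Iterable[str]]]):
        self.sets: dict[str, frozenset[str]] = {}
        for name, members in sets:
            if name in self.sets:
                raise ValidationError(f"duplicate gene-set name: {name!r}")
            members = frozenset(str(m) for m in members)
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")
            self.sets[name] = members

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``."""
    sets = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
        name, _desc, *members = fields
        sets.append((name, [m for m in members if m]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(members)])
        for name, members in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
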