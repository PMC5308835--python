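"""Input containers and file readers.

Expression matrices arrive either as GEO Series Matrix files (the matrix
table between the ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
markers) or as plain TSV (first row sample ids, first column feature ids).
Values are assumed to be log-scale intensities already; an explicit opt-in
``log2`` transform is available but nothing is auto-detected, because a
silent transform would corrupt every downstream correlation.

Feature annotations map platform feature ids (e.g. Affymetrix probesets) to
gene symbols; symbols are uppercased on load so cross-platform matching is a
deterministic case-insensitive exact match.

Interaction evidence is an undirected edge list over gene symbols with a
``direct``/``indirect`` relation attribute, an open substitute for curated
interaction knowledge bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Tokens treated as missing values (case-insensitive). GEO Series Matrix
#: files use "null"; plain TSVs in the wild use NA/NaN/empty.
MISSING_TOKENS = frozenset({"null", "na", "nan", ""})


@dataclass
class ExpressionMatrix:
    """Features x samples grid of log-scale expression values.

    ``values`` is a float DataFrame indexed by feature id with sample ids as
    columns; missing cells are NaN.
    """

    dataset_id: str
    values: pd.DataFrame
    log_scale: bool = True

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate feature ids: {dups[:10]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        if self.values.shape[1] < 3:
            raise ValidationError(
                f"need at least 3 samples, got {self.values.shape[1]}"
            )
        if self.values.shape[0] < 1:
            raise ValidationError("expression matrix has no features")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureAnnotation:
    """Mapping feature_id -> gene symbol (uppercased; "" if unannotated)."""

    symbols: dict[str, str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def symbol_of(self, feature_id: str) -> str:
        return self.symbols.get(feature_id, "")

    def features_for_symbol(self, symbol: str) -> list[str]:
        symbol = symbol.upper()
        return sorted(f for f, s in self.symbols.items() if s == symbol and s)

    @classmethod
    def identity(cls, gene_ids) -> "FeatureAnnotation":
        """Annotation where each feature id is its own (uppercased) symbol."""
        return cls({g: g.upper() for g in gene_ids})


@dataclass
class InteractionEvidence:
    """Undirected gene-gene edges with a direct/indirect relation label.

    Edges are keyed by the sorted endpoint pair; duplicates collapse keeping
    ``direct`` if any record said direct. No self-loops.
    """

    relations: dict[tuple[str, str], str] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, relation: str = "direct") -> bool:
        """Add an undirected edge; returns False (and warns) on self-loops."""
        if relation not in ("direct", "indirect"):
            raise ValidationError(f"unknown relation {relation!r}")
        a, b = a.upper(), b.upper()
        if a == b:
            logger.warning("dropping self-loop edge on %s", a)
            return False
        key = self._key(a, b)
        prev = self.relations.get(key)
        if prev == "direct":
            return True
        self.relations[key] = "direct" if relation == "direct" or prev == "direct" else relation
        return True

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.relations)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.relations:
            out.add(a)
            out.add(b)
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a.upper(), b.upper()) in self.relations

    def relation(self, a: str, b: str) -> str:
        return self.relations[self._key(a.upper(), b.upper())]

    def neighbors(self, gene: str) -> set[str]:
        gene = gene.upper()
        out = set()
        for a, b in self.relations:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def __len__(self) -> int:
        return len(self.relations)


def _parse_cell(token: str) -> float:
    token = token.strip().strip('"')
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value {token!r}") from exc


def _build_matrix(
    dataset_id: str,
    header: list[str],
    rows: list[tuple[str, list[float]]],
    source: str,
) -> ExpressionMatrix:
    if not rows:
        raise ValidationError(f"{source}: empty data section")
    n = len(header)
    data = np.empty((len(rows), n), dtype=float)
    ids = []
    for i, (fid, vals) in enumerate(rows):
        ids.append(fid)
        data[i] = vals
    df = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=header)
    return ExpressionMatrix(dataset_id=dataset_id, values=df)


def read_series_matrix(path, dataset_id: str | None = None, log2: bool = False) -> ExpressionMatrix:
    """Read the matrix table of a GEO Series Matrix file.

    Only the section between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is used; other ``!`` metadata lines are
    ignored. Quoted tokens are unquoted; "null"/"NA"/empty cells become NaN.
    """
    path = str(path)
    begin = end = False
    header: list[str] | None = None
    rows: list[tuple[str, list[float]]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            low = line.strip().lower()
            if not begin:
                if low.startswith("!series_matrix_table_begin"):
                    begin = True
                continue
            if low.startswith("!series_matrix_table_end"):
                end = True
                break
            if header is None:
                toks = [t.strip().strip('"') for t in line.split("\t")]
                header = toks[1:]
                continue
            if not line.strip():
                continue
            toks = line.split("\t")
            if len(toks) != len(header) + 1:
                raise FormatError(
                    f"{path}: ragged row at line {lineno}: expected "
                    f"{len(header) + 1} columns, got {len(toks)}"
                )
            fid = toks[0].strip().strip('"')
            rows.append((fid, [_parse_cell(t) for t in toks[1:]]))
    if not begin:
        raise FormatError(f"{path}: missing !series_matrix_table_begin marker")
    if not end:
        raise FormatError(f"{path}: missing !series_matrix_table_end marker")
    if header is None:
        raise FormatError(f"{path}: matrix table has no header row")
    expr = _build_matrix(dataset_id or path, header, rows, path)
    return apply_log2(expr) if log2 else expr


def read_expression_tsv(path, dataset_id: str | None = None, log2: bool = False) -> ExpressionMatrix:
    """Read a plain TSV expression matrix (header row = sample ids)."""
    path = str(path)
    header: list[str] | None = None
    rows: list[tuple[str, list[float]]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            toks = line.split("\t")
            if header is None:
                header = [t.strip().strip('"') for t in toks[1:]]
                if not header:
                    raise FormatError(f"{path}: header row has no sample ids")
                continue
            if len(toks) != len(header) + 1:
                raise FormatError(
                    f"{path}: ragged row at line {lineno}: expected "
                    f"{len(header) + 1} columns, got {len(toks)}"
                )
            fid = toks[0].strip().strip('"')
            rows.append((fid, [_parse_cell(t) for t in toks[1:]]))
    if header is None:
        raise ValidationError(f"{path}: empty file")
    expr = _build_matrix(dataset_id or path, header, rows, path)
    return apply_log2(expr) if log2 else expr


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix as plain TSV; NaN cells become "NA"."""
    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(expr.sample_ids) + "\n")
        for fid, row in zip(expr.feature_ids, expr.values.to_numpy()):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def apply_log2(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x+1); hard error on negative inputs."""
    vals = expr.values.to_numpy()
    if np.nanmin(vals) < 0:
        raise ValidationError(
            "log2 transform requested but matrix contains negative values"
        )
    return ExpressionMatrix(
        dataset_id=expr.dataset_id,
        values=pd.DataFrame(
            np.log2(vals + 1.0), index=expr.values.index, columns=expr.values.columns
        ),
        log_scale=True,
    )


def read_annotation(path) -> FeatureAnnotation:
    """Read a 2-3 column TSV of feature_id, gene_symbol[, description].

    Lines starting with "#" are skipped. Symbols are uppercased. Duplicate
    feature ids with conflicting symbols are a validation error.
    """
    path = str(path)
    symbols: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    conflicts: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=2 tab-separated columns"
                )
            fid = toks[0].strip().strip('"')
            sym = toks[1].strip().strip('"').upper()
            if fid in symbols:
                if symbols[fid] != sym:
                    conflicts.append(fid)
                continue
            symbols[fid] = sym
            if len(toks) >= 3 and toks[2].strip():
                descriptions[fid] = toks[2].strip().strip('"')
    if conflicts:
        raise ValidationError(
            f"{path}: conflicting symbols for feature ids: {sorted(set(conflicts))[:10]}"
        )
    return FeatureAnnotation(symbols=symbols, descriptions=descriptions)


def read_edge_list(path, dialect: str = "tsv") -> InteractionEvidence:
    """Read interaction evidence.

    dialect="tsv": columns gene_a, gene_b[, relation]; relation defaults to
    "direct". dialect="sif": gene_a relation gene_b. A leading header row
    ("gene_a\\tgene_b...") is skipped in the tsv dialect. Self-loop rows are
    dropped with a warning; malformed rows are format errors.
    """
    if dialect not in ("tsv", "sif"):
        raise ValidationError(f"unknown edge-list dialect {dialect!r}")
    path = str(path)
    ev = InteractionEvidence()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks = [t.strip().strip('"') for t in line.split("\t")]
            if dialect == "tsv":
                if lineno == 1 and toks[0].lower() == "gene_a":
                    continue
                if len(toks) < 2 or not toks[0] or not toks[1]:
                    raise FormatError(f"{path}: malformed edge row at line {lineno}")
                a, b = toks[0], toks[1]
                rel = toks[2] if len(toks) >= 3 and toks[2] else "direct"
            else:
                if len(toks) != 3 or not toks[0] or not toks[2]:
                    raise FormatError(f"{path}: malformed SIF row at line {lineno}")
                a, rel, b = toks
            if rel not in ("direct", "indirect"):
                raise FormatError(
                    f"{path}: line {lineno}: relation must be direct/indirect, got {rel!r}"
                )
            ev.add(a, b, rel)
    return ev


def write_edge_list(ev: InteractionEvidence, path) -> None:
    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\trelation\n")
        for (a, b) in sorted(ev.relations):
            fh.write(f"{a}\t{b}\t{ev.relations[(a, b)]}\n")


def filter_features(
    expr: ExpressionMatrix,
    min_complete_fraction: float = 0.0,
    min_variance: float = 0.0,
) -> ExpressionMatrix:
    """Drop sparse and near-constant features, preserving order.

    Keeps features with at least ``min_complete_fraction`` of samples
    non-missing and sample variance (ddof=1 over non-missing entries) at
    least ``min_variance``. Features with <2 complete values have undefined
    variance and are kept only when min_variance == 0.
    """
    if not 0.0 <= min_complete_fraction <= 1.0:
        raise ValidationError("min_complete_fraction must be in [0, 1]")
    if min_variance < 0:
        raise ValidationError("min_variance must be >= 0")
    vals = expr.values.to_numpy()
    finite = np.isfinite(vals)
    n_obs = finite.sum(axis=1)
    frac_ok = n_obs >= min_complete_fraction * expr.n_samples
    with np.errstate(invalid="ignore"):
        var = np.nanvar(np.where(finite, vals, np.nan), axis=1, ddof=1)
    var_ok = np.where(n_obs >= 2, var >= min_variance, min_variance == 0.0)
    keep = frac_ok & var_ok
    if not keep.any():
        raise ValidationError("filter_features removed every feature")
    return ExpressionMatrix(
        dataset_id=expr.dataset_id,
        values=expr.values.loc[keep],
        log_scale=expr.log_scale,
    )
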