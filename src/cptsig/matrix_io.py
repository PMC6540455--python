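"""Readers and writers for expression matrices, probe annotations and ortholog maps.

All on-disk formats are delimited UTF-8 text with a mandatory header row.
Expression matrices are features x samples; a GEO series-matrix-like dialect
(the expression table fenced by ``!series_matrix_table_begin`` /
``!series_matrix_table_end``) is supported so deposited normalized matrices
can be ingested directly without a full GEO client.

Missing or non-numeric cells are a hard load error: the downstream
correlation screens assume complete matrices, and rejecting holes at load
time keeps every paired sample count ``n`` unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "OrthologMap",
    "RunConfig",
    "MatrixLoadError",
    "read_expression_matrix",
    "read_probe_annotation",
    "read_ortholog_map",
    "write_expression_matrix",
    "write_gene_table",
    "read_gene_table",
    "load_run_config",
]


class MatrixLoadError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with identifiers and provenance tags.

    ``scale_tag`` records whether values are on a log scale (array
    log2 intensities) or a linear scale (RNA-seq CPM, raw intensities);
    several operations refuse the wrong scale rather than guessing.
    """

    data: pd.DataFrame
    scale_tag: Literal["log", "linear"] = "log"
    platform_tag: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise MatrixLoadError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise MatrixLoadError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise MatrixLoadError("non-numeric values in expression matrix")
        if values.size and not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise MatrixLoadError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.scale_tag not in ("log", "linear"):
            raise MatrixLoadError(f"unknown scale_tag {self.scale_tag!r}")

    # -- convenience accessors ---------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[ids], self.scale_tag, self.platform_tag)

    def row(self, feature_id: str) -> np.ndarray:
        return self.data.loc[feature_id].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        feature_ids: Iterable[str],
        sample_ids: Iterable[str],
        values: np.ndarray,
        scale_tag: Literal["log", "linear"] = "log",
        platform_tag: str = "",
    ) -> "ExpressionMatrix":
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=list(feature_ids),
            columns=list(sample_ids),
        )
        return cls(df, scale_tag=scale_tag, platform_tag=platform_tag)


@dataclass
class ProbeAnnotation:
    """Many-to-one probe -> gene-symbol map (several probesets per gene)."""

    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        for probe, sym in self.probe_to_gene.items():
            if not sym:
                raise MatrixLoadError(f"empty gene symbol for probe {probe!r}")

    @property
    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())

    def probes_for(self, gene_symbol: str) -> list[str]:
        return [p for p, g in self.probe_to_gene.items() if g == gene_symbol]

    def __len__(self) -> int:
        return len(self.probe_to_gene)


@dataclass
class OrthologMap:
    """One-to-one symbol pairing between two species after ambiguity reduction."""

    pairs: list[tuple[str, str]]
    species_a: str = "human"
    species_b: str = "mouse"
    n_dropped_ambiguous: int = 0

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in self.pairs:
            if a in seen_a or b in seen_b:
                raise MatrixLoadError(f"symbol appears in more than one pair: {(a, b)}")
            seen_a.add(a)
            seen_b.add(b)

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RunConfig:
    """Run-level configuration mirrored by the CLI flags."""

    r_pair_min: float = 0.5
    r_min: float = 0.5
    p_max: float = 0.01
    k_clusters: int = 3
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.r_pair_min <= 1):
            raise ValueError("r_pair_min must be in (0, 1]")
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must be in (0, 1]")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _strip_ids(ids: Iterable) -> list[str]:
    return [str(x).strip() for x in ids]


def read_expression_matrix(
    path: str | Path,
    dialect: Literal["tsv", "series_matrix"] = "tsv",
    sep: str = "\t",
    scale_tag: Literal["log", "linear"] = "log",
    platform_tag: str = "",
) -> ExpressionMatrix:
    """Load a features x samples matrix from delimited text.

    ``dialect="series_matrix"`` reads only the expression table between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` fence
    lines; other header lines are ignored with a log note.  Feature and
    sample identifiers are whitespace-trimmed and case-sensitive; duplicate
    identifiers and non-numeric or missing cells are load errors that name
    the offending coordinate.
    """
    path = Path(path)
    if dialect == "series_matrix":
        lines = path.read_text(encoding="utf-8").splitlines()
        try:
            start = next(
                i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
            )
            end = next(
                i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise MatrixLoadError(
                f"{path}: series_matrix fence lines not found"
            ) from None
        n_header = sum(1 for l in lines[:start] if l.startswith("!"))
        if n_header:
            logger.info("%s: ignored %d series-matrix header lines", path, n_header)
        table_lines = lines[start + 1 : end]
        from io import StringIO

        raw = pd.read_csv(
            StringIO("\n".join(table_lines)), sep=sep, index_col=0,
            float_precision="round_trip",
        )
        # GEO convention quotes identifiers
        raw.index = [str(i).strip().strip('"') for i in raw.index]
        raw.columns = [str(c).strip().strip('"') for c in raw.columns]
    elif dialect == "tsv":
        raw = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        raw.index = _strip_ids(raw.index)
        raw.columns = _strip_ids(raw.columns)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    bad = raw.columns[~raw.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        numeric = pd.to_numeric(raw[col], errors="coerce")
        row = raw.index[numeric.isna().to_numpy().nonzero()[0][0]]
        raise MatrixLoadError(
            f"{path}: non-numeric value at feature {row!r}, sample {col!r}"
        )
    if raw.isna().to_numpy().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise MatrixLoadError(
            f"{path}: missing value at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    try:
        return ExpressionMatrix(raw.astype(float), scale_tag=scale_tag, platform_tag=platform_tag)
    except MatrixLoadError as exc:
        raise MatrixLoadError(f"{path}: {exc}") from None


def read_probe_annotation(path: str | Path, sep: str = "\t") -> ProbeAnnotation:
    """Load a two-column (probe_id, gene_symbol) table.

    Rows with an empty symbol are dropped (the drop count is logged); a
    probe mapped to two different symbols is an error naming the probe.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise MatrixLoadError(f"{path}: expected two columns (probe_id, gene_symbol)")
    probes = _strip_ids(df.iloc[:, 0])
    genes = _strip_ids(df.iloc[:, 1])
    mapping: dict[str, str] = {}
    n_empty = 0
    for p, g in zip(probes, genes):
        if not g:
            n_empty += 1
            continue
        if p in mapping and mapping[p] != g:
            raise MatrixLoadError(
                f"{path}: probe {p!r} mapped to both {mapping[p]!r} and {g!r}"
            )
        mapping[p] = g
    if n_empty:
        logger.info("%s: dropped %d rows with empty gene symbol", path, n_empty)
    ann = ProbeAnnotation(mapping)
    ann.n_dropped_empty = n_empty  # type: ignore[attr-defined]
    return ann


def read_ortholog_map(
    path: str | Path,
    policy: Literal["strict_one_to_one", "first_wins"] = "strict_one_to_one",
    sep: str = "\t",
) -> OrthologMap:
    """Load a two-column symbol-pair table and reduce it to one-to-one.

    ``strict_one_to_one`` (default) drops every pair involving an ambiguous
    symbol, preventing double-counting in shared-gene intersections;
    ``first_wins`` keeps the first pair seen for each symbol.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise MatrixLoadError(f"{path}: empty ortholog map")
    species_a, species_b = (str(c).strip() for c in df.columns[:2])
    raw_pairs = [
        (a, b)
        for a, b in zip(_strip_ids(df.iloc[:, 0]), _strip_ids(df.iloc[:, 1]))
        if a and b
    ]
    from collections import Counter

    count_a = Counter(a for a, _ in raw_pairs)
    count_b = Counter(b for _, b in raw_pairs)
    pairs: list[tuple[str, str]] = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    n_dropped = 0
    for a, b in raw_pairs:
        if policy == "strict_one_to_one":
            if count_a[a] > 1 or count_b[b] > 1:
                n_dropped += 1
                continue
        elif policy == "first_wins":
            if a in seen_a or b in seen_b:
                n_dropped += 1
                continue
        else:
            raise ValueError(f"unknown policy {policy!r}")
        pairs.append((a, b))
        seen_a.add(a)
        seen_b.add(b)
    if n_dropped:
        logger.info("%s: dropped %d ambiguous ortholog pairs (%s)", path, n_dropped, policy)
    return OrthologMap(pairs, species_a, species_b, n_dropped_ambiguous=n_dropped)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression_matrix(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix so that re-reading reproduces the values bit-exactly."""
    df = m.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_gene_table(result, path: str | Path, sep: str = "\t") -> None:
    """Write a gene table (gene_symbol, r, p, n, passes) for a signature result.

    Accepts a ``SignatureResult`` or any object with ``gene_records`` and
    ``signature_genes`` attributes.  Floats are printed with 17 significant
    digits so a write/read round trip is exact.
    """
    records = result.gene_records
    passing = set(result.signature_genes)
    df = pd.DataFrame(
        {
            "gene_symbol": [rec.feature_id for rec in records],
            "r": [rec.r for rec in records],
            "p": [rec.p for rec in records],
            "n": [rec.n for rec in records],
            "passes": [rec.feature_id in passing for rec in records],
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_gene_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a flat YAML file into a :class:`RunConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise MatrixLoadError(f"{path}: config must be a mapping")
    known = {k: data[k] for k in ("r_pair_min", "r_min", "p_max", "k_clusters", "seed") if k in data}
    paths = {k: v for k, v in data.items() if k not in known}
    return RunConfig(paths=paths, **known)
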