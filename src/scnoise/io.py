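"""Data containers and file readers/writers.

The pipeline operates on a raw integer count matrix (features x cells) in
which ERCC spike-in species are carried alongside endogenous genes and
flagged by the universal ``ERCC-`` id prefix, plus a per-cell metadata table
recording the age group at isolation (2h / 16h / 36h), the replicative
generation at sampling and the total mapped reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPIKEIN_PREFIX = "ERCC-"
AGE_GROUPS = ("2h", "16h", "36h")
#: canonical spike-in pool size added per cell, molecules
DEFAULT_SPIKEIN_TOTAL = 8000.0
#: number of distinct ERCC species in the standard mix
N_SPIKEIN_SPECIES = 92


class ParseError(ValueError):
    """Raised when an input file cannot be parsed in the declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


def is_spikein_id(feature_id: str) -> bool:
    """Spike-in flagging is a pure function of the feature id prefix."""
    return str(feature_id).startswith(SPIKEIN_PREFIX)


@dataclass
class CountMatrix:
    """Raw integer counts, features x cells, with spike-ins flagged.

    Parameters
    ----------
    values
        Non-negative integer array of shape ``(n_features, n_cells)``.
    feature_ids, cell_ids
        Unique string identifiers for rows and columns.
    is_spikein
        Boolean flag per feature; by convention true for ids starting with
        ``ERCC-``.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    is_spikein: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_float = np.asarray(self.values, dtype=float)
            rounded = np.rint(as_float)
            if not np.array_equal(as_float, rounded):
                raise ValidationError(
                    "counts must be integers; fractional values suggest "
                    "pre-normalized input, which is rejected rather than rounded"
                )
            self.values = rounded.astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise ValidationError("counts must be non-negative")
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.feature_ids) != self.values.shape[0]:
            raise ValidationError("feature_ids length does not match matrix rows")
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValidationError("cell_ids length does not match matrix columns")
        for name, ids in (("feature", self.feature_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"{name}_ids are not unique")
        if self.is_spikein is None:
            self.is_spikein = np.array(
                [is_spikein_id(f) for f in self.feature_ids], dtype=bool
            )
        else:
            self.is_spikein = np.asarray(self.is_spikein, dtype=bool)
            if len(self.is_spikein) != len(self.feature_ids):
                raise ValidationError("is_spikein length does not match features")

    # -- basic geometry -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    # -- subsetting ------------------------------------------------------
    def subset_features(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(
            self.values[mask],
            self.feature_ids[mask],
            self.cell_ids,
            self.is_spikein[mask],
        )

    def subset_cells(self, cells: Iterable[str] | np.ndarray) -> "CountMatrix":
        cells = list(cells)
        if len(cells) and isinstance(cells[0], (bool, np.bool_)):
            mask = np.asarray(cells, dtype=bool)
        else:
            index = {c: i for i, c in enumerate(self.cell_ids)}
            missing = [c for c in cells if c not in index]
            if missing:
                raise ValidationError(f"cells absent from count matrix: {missing}")
            mask = np.array([index[c] for c in cells], dtype=int)
        return CountMatrix(
            self.values[:, mask],
            self.feature_ids,
            np.asarray(self.cell_ids)[mask],
            self.is_spikein,
        )

    def endogenous(self) -> "CountMatrix":
        return self.subset_features(~self.is_spikein)

    def spikeins(self) -> "CountMatrix":
        return self.subset_features(self.is_spikein)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_ids)

    # -- i/o --------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.to_numpy(), frame.index.to_numpy(), frame.columns.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "feature_id"
        frame.to_csv(path, sep="\t")


def read_counts(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a raw count matrix.

    ``tsv``: features in rows, first column feature ids, header row of cell
    ids.  ``mtx-triplet``: MatrixMarket coordinate file; sidecar files
    ``<stem>.features.tsv`` and ``<stem>.barcodes.tsv`` (one id per line,
    first column used) must sit next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_counts_tsv(path)
    if dialect == "mtx-triplet":
        return _read_counts_mtx(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path} as TSV: {exc}") from exc
    if frame.empty and frame.columns.empty:
        raise ParseError(f"{path}: empty count matrix")
    non_numeric = frame.columns[
        [not np.issubdtype(d, np.number) for d in frame.dtypes]
    ]
    if len(non_numeric):
        bad = frame[non_numeric[0]]
        row = bad.index[bad.map(lambda v: not str(v).replace(".", "").lstrip("-").isdigit())]
        raise ValidationError(
            f"{path}: non-numeric count in column {non_numeric[0]!r}"
            + (f" (e.g. feature {row[0]!r})" if len(row) else "")
        )
    return CountMatrix.from_frame(frame)


def _read_counts_mtx(path: Path) -> CountMatrix:
    from scipy.io import mmread

    try:
        mat = mmread(str(path))
    except Exception as exc:
        raise ParseError(f"cannot parse {path} as MatrixMarket: {exc}") from exc
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    stem = path.with_suffix("")
    feat_path = Path(str(stem) + ".features.tsv")
    cell_path = Path(str(stem) + ".barcodes.tsv")
    for p in (feat_path, cell_path):
        if not p.exists():
            raise ParseError(f"missing sidecar file {p}")
    features = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).to_numpy()
    cells = pd.read_csv(cell_path, sep="\t", header=None)[0].astype(str).to_numpy()
    return CountMatrix(dense, features, cells)


# -- cell metadata ---------------------------------------------------------

_META_REQUIRED = ("cell_id", "age_group", "generation")


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a cell metadata table.

    Required columns: cell_id, age_group (one of 2h/16h/36h), generation
    (non-negative integer).  Optional: total_mapped_reads.
    """
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValidationError(f"cell metadata missing columns: {missing}")
    meta = meta.copy()
    meta["cell_id"] = meta["cell_id"].astype(str)
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValidationError(f"duplicate cell ids in metadata: {dups}")
    norm = meta["age_group"].astype(str).str.strip().str.lower()
    bad = sorted(set(norm) - set(AGE_GROUPS))
    if bad:
        raise ValidationError(
            f"unknown age_group tokens {bad}; expected one of {AGE_GROUPS}"
        )
    meta["age_group"] = norm
    gen = pd.to_numeric(meta["generation"], errors="raise")
    if (gen < 0).any() or not np.allclose(gen, np.rint(gen)):
        raise ValidationError("generation must be a non-negative integer")
    meta["generation"] = gen.astype(int)
    if "total_mapped_reads" in meta.columns:
        tmr = pd.to_numeric(meta["total_mapped_reads"], errors="raise")
        if (tmr < 0).any():
            raise ValidationError("total_mapped_reads must be non-negative")
        meta["total_mapped_reads"] = tmr.astype(int)
    return meta


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    try:
        meta = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return validate_cell_meta(meta)


# -- gene sets (GMT) -------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named TF target sets: TF name -> member gene ids."""

    sets: dict[str, frozenset[str]]
    source: str = ""
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")


def read_gene_sets(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB member...`` per line.

    Lines with fewer than three fields are skipped with a logged warning;
    duplicate members within a set collapse; a repeated set name is an error
    (ambiguous regulon definition).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sets: dict[str, frozenset[str]] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 fields, skipped", path, lineno)
                n_skipped += 1
                continue
            name = fields[0]
            if name in sets:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene set name {name!r}"
                )
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                logger.warning("%s:%d: set %r has no members, skipped", path, lineno, name)
                n_skipped += 1
                continue
            sets[name] = members
    return GeneSetCollection(sets, source=source or str(path), n_skipped=n_skipped)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, collection.source or "."] + sorted(members)) + "\n")


# -- spike-in reference table ---------------------------------------------


def validate_spikein_table(
    table: pd.DataFrame, expected_total: float | None = None
) -> pd.DataFrame:
    required = ("feature_id", "molecules_per_cell")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"spike-in table missing columns: {missing}")
    table = table.copy()
    table["feature_id"] = table["feature_id"].astype(str)
    mols = pd.to_numeric(table["molecules_per_cell"], errors="raise")
    if (mols <= 0).any():
        raise ValidationError("molecules_per_cell must be positive")
    table["molecules_per_cell"] = mols.astype(float)
    if expected_total is not None and not np.isclose(
        mols.sum(), expected_total, rtol=1e-6
    ):
        raise ValidationError(
            f"spike-in molecules sum to {mols.sum():.4g}, expected {expected_total:.4g}"
        )
    return table


def read_spikein_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    return validate_spikein_table(pd.read_csv(path, sep="\t"))
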