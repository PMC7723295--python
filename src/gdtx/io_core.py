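"""Shared data model and readers/writers for the external formats the pipeline touches.

The on-disk dialects follow 10x Genomics conventions: a count matrix is an
MTX triplet directory (``matrix.mtx`` + ``features.tsv``/``genes.tsv`` +
``barcodes.tsv``, optionally gzipped) with genes as rows and 1-based
MatrixMarket coordinates.  Gene identifiers are opaque case-sensitive
strings; no alias resolution is attempted.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "IntegrityError",
    "DesignError",
    "CountMatrix",
    "NormMatrix",
    "GeneSignature",
    "CuratedGeneSet",
    "BulkSample",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_cell_meta",
    "write_cell_meta",
    "read_gene_sets",
    "write_gene_sets",
    "read_signatures_tsv",
    "write_signatures_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "load_curated_sets",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class IntegrityError(ValueError):
    """A file parses but violates an internal consistency rule."""


class DesignError(ValueError):
    """A simulation design or parameter set is infeasible."""


def _open_text(path: Path | str, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_unique(values: Sequence[str], what: str) -> None:
    if len(set(values)) != len(values):
        seen: set[str] = set()
        dup = next(v for v in values if v in seen or seen.add(v))
        raise IntegrityError(f"duplicate {what}: {dup!r}")


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer counts.

    ``counts`` is genes-by-cells (CSR); ``gene_ids`` and ``barcodes`` label
    rows and columns respectively and must be unique.
    """

    gene_ids: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise IntegrityError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene IDs"
            )
        if n_cells != len(self.barcodes):
            raise IntegrityError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.barcodes, "barcode")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise IntegrityError("negative counts present")
            if not np.allclose(data, np.round(data)):
                raise IntegrityError("non-integral counts present")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            [self.gene_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.gene_ids[i] for i in keep],
            list(self.barcodes),
            self.counts[keep if keep.dtype == bool else keep, :],
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return CountMatrix(
            list(self.gene_ids),
            [self.barcodes[i] for i in idx],
            self.counts[:, idx],
        )


@dataclass
class NormMatrix:
    """Genes x cells matrix of non-negative real (log-normalized) expression."""

    gene_ids: list[str]
    barcodes: list[str]
    values: sp.csr_matrix | np.ndarray

    def __post_init__(self) -> None:
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.barcodes):
            raise IntegrityError("axis labels do not match matrix shape")
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.barcodes, "barcode")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise IntegrityError("non-finite normalized values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneSignature:
    """Named up/down gene sets with signed log-fold-change weights.

    ``up`` maps gene -> weight > 0, ``down`` maps gene -> weight < 0; the two
    key sets are disjoint.
    """

    name: str
    up: dict[str, float] = field(default_factory=dict)
    down: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise IntegrityError(f"genes in both up and down sets: {sorted(overlap)}")
        for g, w in self.up.items():
            if not np.isfinite(w) or w <= 0:
                raise IntegrityError(f"up-gene {g!r} has non-positive weight {w}")
        for g, w in self.down.items():
            if not np.isfinite(w) or w >= 0:
                raise IntegrityError(f"down-gene {g!r} has non-negative weight {w}")

    @property
    def weights(self) -> dict[str, float]:
        """All signed weights (up and down merged)."""
        return {**self.up, **self.down}

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class CuratedGeneSet:
    """A literature-curated, unweighted gene set (e.g. an effector program)."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        self.genes = set(self.genes)


@dataclass
class BulkSample:
    """One bulk-cohort sample: expression, tumour purity, survival outcome."""

    sample_id: str
    expr: dict[str, float]
    purity: float
    time: float
    event: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise IntegrityError(
                f"sample {self.sample_id!r}: purity {self.purity} outside [0, 1]"
            )
        if not self.time > 0:
            raise IntegrityError(
                f"sample {self.sample_id!r}: time {self.time} must be > 0"
            )
        if self.event not in (0, 1):
            raise FormatError(
                f"sample {self.sample_id!r}: event {self.event!r} not in {{0, 1}}"
            )


# ---------------------------------------------------------------------------
# MTX triplet (cellranger dialect)
# ---------------------------------------------------------------------------

_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_MATRIX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")


def _find_one(directory: Path, candidates: Sequence[str], what: str) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FormatError(
        f"no {what} file in {directory} (looked for {', '.join(candidates)})"
    )


def read_mtx_triplet(directory: Path | str) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a 10x-style MTX triplet directory.

    Returns the count matrix and a minimal cell-metadata table (one row per
    barcode; ``cluster``/``donor``/``phase`` columns absent until joined from
    a label table).  MatrixMarket coordinates are 1-based; a 0 index is a
    dialect violation and raises :class:`IntegrityError`.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx_path = _find_one(directory, _MATRIX_NAMES, "matrix.mtx")
    feat_path = _find_one(directory, _FEATURE_NAMES, "features/genes.tsv")
    bc_path = _find_one(directory, _BARCODE_NAMES, "barcodes.tsv")

    with _open_text(feat_path) as fh:
        features = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_text(bc_path) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]

    with _open_text(mtx_path, "rt") as fh:
        try:
            mat = scipy.io.mmread(io.StringIO(fh.read()))
        except ValueError as exc:
            raise IntegrityError(f"{mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.shape[0] != len(features):
        raise IntegrityError(
            f"{mtx_path}: {mat.shape[0]} rows but {len(features)} features"
        )
    if mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"{mtx_path}: {mat.shape[1]} columns but {len(barcodes)} barcodes"
        )
    cm = CountMatrix(features, barcodes, mat)
    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return cm, meta


def write_mtx_triplet(cm: CountMatrix, directory: Path | str) -> None:
    """Write a count matrix as an uncompressed MTX triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = cm.counts.tocoo()
    with open(directory / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(
            (coo.data.astype(np.int64), (coo.row, coo.col)), shape=cm.counts.shape
        ))
    with open(directory / "features.tsv", "wt") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "wt") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")


# ---------------------------------------------------------------------------
# Cell metadata (cluster / donor / phase labels)
# ---------------------------------------------------------------------------

VALID_PHASES = ("G1", "S", "G2M")


def read_cell_meta(path: Path | str) -> pd.DataFrame:
    """Read a cell-label TSV with a ``barcode`` column and any of
    ``donor``/``cluster``/``phase``; indexed by barcode."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns:
        raise FormatError(f"{path}: missing required column 'barcode'")
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise IntegrityError(f"{path}: duplicate barcode {dup!r}")
    if "phase" in df.columns:
        bad = set(df["phase"].dropna()) - set(VALID_PHASES)
        if bad:
            raise FormatError(f"{path}: invalid phase labels {sorted(bad)}")
    return df.set_index("barcode")


def write_cell_meta(meta: pd.DataFrame, path: Path | str) -> None:
    meta.to_csv(path, sep="\t", index=True, index_label="barcode")


# ---------------------------------------------------------------------------
# Gene sets and signatures
# ---------------------------------------------------------------------------

def read_gene_sets(path: Path | str, dialect: str = "gmt") -> list[CuratedGeneSet]:
    """Read curated gene sets.

    ``gmt``: one set per line, ``name<TAB>description<TAB>gene...``.
    ``two_column_tsv``: ``set_name<TAB>gene`` rows (header optional).
    Duplicate genes within a record are collapsed with a logged warning.
    """
    if dialect not in ("gmt", "two_column_tsv"):
        raise ValueError(f"unknown gene-set dialect {dialect!r}")
    sets: list[CuratedGeneSet] = []
    if dialect == "gmt":
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: GMT record needs name, description and "
                        f"at least one gene"
                    )
                name, genes = parts[0], [g for g in parts[2:] if g]
                if not genes:
                    raise FormatError(f"{path}:{lineno}: empty gene list for {name!r}")
                if len(set(genes)) != len(genes):
                    logger.warning(
                        "gene set %r: %d duplicate gene entries collapsed",
                        name, len(genes) - len(set(genes)),
                    )
                sets.append(CuratedGeneSet(name, set(genes)))
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"],
                         dtype=str, comment="#")
        if df["set"].iloc[0] in ("set", "set_name", "name"):  # tolerate header
            df = df.iloc[1:]
        for name, grp in df.groupby("set", sort=False):
            genes = [g for g in grp["gene"] if isinstance(g, str) and g]
            if not genes:
                raise FormatError(f"{path}: empty gene list for set {name!r}")
            if len(set(genes)) != len(genes):
                logger.warning("gene set %r: duplicates collapsed", name)
            sets.append(CuratedGeneSet(str(name), set(genes)))
    return sets


def write_gene_sets(sets: Iterable[CuratedGeneSet], path: Path | str) -> None:
    with open(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_signatures_tsv(path: Path | str) -> list[GeneSignature]:
    """Read weighted signatures from a long TSV: signature, gene, weight."""
    df = pd.read_csv(path, sep="\t", dtype={"signature": str, "gene": str})
    for col in ("signature", "gene", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sigs = []
    for name, grp in df.groupby("signature", sort=False):
        up = {r.gene: float(r.weight) for r in grp.itertuples() if r.weight > 0}
        down = {r.gene: float(r.weight) for r in grp.itertuples() if r.weight < 0}
        sigs.append(GeneSignature(str(name), up, down))
    return sigs


def write_signatures_tsv(sigs: Iterable[GeneSignature], path: Path | str) -> None:
    rows = []
    for s in sigs:
        for g, w in sorted(s.up.items()):
            rows.append((s.name, g, w))
        for g, w in sorted(s.down.items()):
            rows.append((s.name, g, w))
    pd.DataFrame(rows, columns=["signature", "gene", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def load_curated_sets() -> list[CuratedGeneSet]:
    """The five bundled effector gene sets (IFNγ, IL17, cytotoxicity,
    antigen presentation, innate) curated from the γδ T-cell literature."""
    from importlib import resources

    with resources.as_file(
        resources.files("gdtx.data").joinpath("curated_effector_sets.gmt")
    ) as p:
        return read_gene_sets(p, dialect="gmt")


# ---------------------------------------------------------------------------
# Bulk cohort: clinical + expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: Path | str) -> pd.DataFrame:
    """Read a genes-by-samples expression TSV (first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate gene IDs")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: Path | str) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_clinical_tsv(
    clinical_path: Path | str, expression_path: Path | str
) -> list[BulkSample]:
    """Join a clinical TSV (sample_id, purity, time, event) with a
    genes-by-samples expression TSV into :class:`BulkSample` records.

    Rows with non-numeric purity/time, out-of-range purity, or non-binary
    event raise row-numbered errors; nothing is silently dropped.
    """
    clin = pd.read_csv(clinical_path, sep="\t", dtype=str)
    for col in ("sample_id", "purity", "time", "event"):
        if col not in clin.columns:
            raise FormatError(f"{clinical_path}: missing column {col!r}")
    expr = read_expression_tsv(expression_path)
    samples: list[BulkSample] = []
    for i, row in enumerate(clin.itertuples(index=False), 2):  # 1-based + header
        try:
            purity = float(row.purity)
            time = float(row.time)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{clinical_path}: row {i}: non-numeric purity/time"
            ) from exc
        if row.event not in ("0", "1"):
            raise FormatError(
                f"{clinical_path}: row {i}: event {row.event!r} not in {{0, 1}}"
            )
        if row.sample_id not in expr.columns:
            raise IntegrityError(
                f"{clinical_path}: row {i}: sample {row.sample_id!r} absent "
                f"from expression table"
            )
        try:
            samples.append(
                BulkSample(
                    sample_id=row.sample_id,
                    expr=expr[row.sample_id].to_dict(),
                    purity=purity,
                    time=time,
                    event=int(row.event),
                )
            )
        except IntegrityError as exc:
            raise IntegrityError(f"{clinical_path}: row {i}: {exc}") from exc
    return samples


def write_clinical_tsv(samples: Sequence[BulkSample], clinical_path: Path | str,
                       expression_path: Path | str) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "purity": [s.purity for s in samples],
            "time": [s.time for s in samples],
            "event": [s.event for s in samples],
        }
    ).to_csv(clinical_path, sep="\t", index=False)
    genes = sorted({g for s in samples for g in s.expr})
    expr = pd.DataFrame(
        {s.sample_id: [s.expr.get(g, 0.0) for g in genes] for s in samples},
        index=pd.Index(genes, name="gene"),
    )
    write_expression_tsv(expr, expression_path)
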