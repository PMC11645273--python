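"""Reading and writing expression tables, sample metadata, gene sets and models.

The on-disk formats are deliberately plain: delimited text for expression
matrices (genes as rows, header row of sample ids) and metadata, GMT for gene
sets, and schema-versioned JSON for trained models.  A "collection bundle" is
a directory with one expression table per dataset plus a shared metadata
table; it is what the CLI reads and what the simulator writes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORGANS = ("kidney", "heart", "liver", "lung", "other")
PLATFORMS = ("array", "rnaseq_counts")
TISSUES = ("biopsy", "whole_blood", "pbmc", "other")

#: Outcome labels consolidated into the positive (dysfunction) class: the
#: composite rejection phenotype merges T-cell-mediated rejection, antibody-
#: mediated rejection and mixed rejection, plus the generic "AR" annotation.
DEFAULT_POSITIVE_LABELS = ("TCMR", "ABMR", "mixed", "AR", "1", "1.0")

METADATA_COLUMNS = ("sample_id", "dataset_id", "organ", "platform", "tissue", "outcome")

MODEL_SCHEMA_VERSION = 1


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionDataset:
    """One cohort: an expression matrix with aligned outcome labels.

    ``X`` is genes x samples; log2 intensities for ``platform='array'``,
    raw nonnegative integer counts for ``platform='rnaseq_counts'``.
    ``y`` holds the binary outcome (1 = dysfunction phenotype, 0 = stable).
    """

    dataset_id: str
    organ: str
    platform: str
    tissue: str
    genes: list[str]
    samples: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.organ not in ORGANS:
            raise DataError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.platform not in PLATFORMS:
            raise DataError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.tissue not in TISSUES:
            raise DataError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"dataset {self.dataset_id}: duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise DataError(f"dataset {self.dataset_id}: duplicate sample ids")
        if self.X.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"dataset {self.dataset_id}: X shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.y.shape != (len(self.samples),):
            raise DataError(f"dataset {self.dataset_id}: y length mismatch")
        if not np.isin(self.y, [0, 1]).all():
            raise DataError(f"dataset {self.dataset_id}: y must contain only 0/1")
        self.y = self.y.astype(int)
        if self.platform == "rnaseq_counts":
            if (self.X < 0).any():
                raise DataError(f"dataset {self.dataset_id}: negative counts")
            if not np.allclose(self.X, np.round(self.X)):
                raise DataError(f"dataset {self.dataset_id}: non-integer counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def usable_for_training(self) -> bool:
        """True when both outcome classes are present."""
        return len(np.unique(self.y)) == 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.genes, columns=self.samples)


@dataclass
class DatasetCollection:
    """An ordered family of cohorts sharing a gene symbol space."""

    datasets: list[ExpressionDataset]

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(self.datasets) < 1:
            raise DataError("a collection needs at least one dataset")
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate dataset ids: {sorted(ids)}")

    @property
    def k(self) -> int:
        return len(self.datasets)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    def get(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def trainable(self) -> "DatasetCollection":
        """Subset of datasets with both outcome classes present."""
        usable = [d for d in self.datasets if d.usable_for_training]
        if not usable:
            raise DataError("no dataset has both outcome classes")
        return DatasetCollection(usable)

    def subset(self, dataset_ids: Iterable[str]) -> "DatasetCollection":
        wanted = list(dataset_ids)
        return DatasetCollection([self.get(i) for i in wanted])

    def drop(self, dataset_id: str) -> "DatasetCollection":
        kept = [d for d in self.datasets if d.dataset_id != dataset_id]
        return DatasetCollection(kept)

    def gene_intersection(self) -> list[str]:
        """Sorted intersection of gene symbols across all datasets."""
        common = set(self.datasets[0].genes)
        for d in self.datasets[1:]:
            common &= set(d.genes)
        return sorted(common)


@dataclass
class GeneSetLibrary:
    """Named gene sets, e.g. pathways parsed from a GMT file."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")


def _parse_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (ValueError, TypeError):
        for gene in df.index:
            for sample in df.columns:
                v = df.loc[gene, sample]
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise DataError(
                        f"{path}: non-numeric value {v!r} at gene {gene!r}, "
                        f"sample {sample!r}"
                    ) from None
        raise  # pragma: no cover - unreachable


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_by_samples",
    sep: str | None = None,
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Read a delimited expression table into a genes x samples DataFrame.

    Parameters
    ----------
    orientation
        ``"genes_by_samples"`` (rows are genes) or ``"samples_by_genes"``
        (table is transposed on read).  There is no auto-detection: a silent
        transpose is the classic failure mode of expression I/O.
    drop_missing
        If False (strict, default) any missing/non-numeric cell is an error
        naming the offending gene and sample.  If True, genes containing a
        missing value are dropped with a logged count.
    """
    path = Path(path)
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, keep_default_na=False, dtype=str)
    if orientation == "samples_by_genes":
        df = df.T
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"{path}: duplicate gene labels {dups}")
    if df.columns.duplicated().any():
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise DataError(f"{path}: duplicate sample labels {dups}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if drop_missing:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna().any(axis=1)
        if bad.any():
            logger.info("%s: dropped %d gene(s) with missing values", path, bad.sum())
        return numeric.loc[~bad]
    return _parse_numeric(df, path)


def write_expression_table(
    df: pd.DataFrame, path: str | Path, sep: str = "\t"
) -> None:
    df.to_csv(path, sep=sep, index_label="gene")


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    meta = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"{path}: metadata missing required columns {missing}")
    return meta


def coerce_outcome(
    labels: Sequence[str],
    positive_labels: Sequence[str] = DEFAULT_POSITIVE_LABELS,
) -> np.ndarray:
    """Map free-text outcome labels onto the composite binary endpoint.

    Labels in ``positive_labels`` become 1; everything else becomes 0.
    """
    pos = {str(p) for p in positive_labels}
    return np.array([1 if str(v) in pos else 0 for v in labels], dtype=int)


def assemble_collection(
    tables: Sequence[pd.DataFrame] | Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    positive_labels: Sequence[str] = DEFAULT_POSITIVE_LABELS,
) -> DatasetCollection:
    """Assemble one validated :class:`ExpressionDataset` per dataset_id.

    Samples present in the tables but absent from the metadata are dropped
    (count logged); metadata rows without a matching table column are ignored.
    Datasets are ordered by sorted dataset_id so the result is independent of
    the order in which tables are supplied.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise DataError(f"metadata missing required columns {missing}")
    if isinstance(tables, Mapping):
        frames = list(tables.values())
    else:
        frames = list(tables)
    sample_to_frame: dict[str, pd.DataFrame] = {}
    for frame in frames:
        for s in frame.columns:
            sample_to_frame.setdefault(str(s), frame)

    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta = meta[meta["sample_id"].isin(sample_to_frame)]
    if meta.empty:
        raise DataError("no overlap between metadata sample_ids and table columns")
    n_tabled = len(sample_to_frame)
    n_dropped = n_tabled - meta["sample_id"].nunique()
    if n_dropped:
        logger.info("dropped %d sample(s) without metadata", n_dropped)

    datasets = []
    for dataset_id, sub in sorted(meta.groupby("dataset_id"), key=lambda kv: kv[0]):
        for col in ("organ", "platform", "tissue"):
            if sub[col].nunique() != 1:
                raise DataError(
                    f"dataset {dataset_id}: inconsistent {col} annotations"
                )
        sample_ids = list(sub["sample_id"])
        frame = sample_to_frame[sample_ids[0]]
        absent = [s for s in sample_ids if s not in frame.columns]
        if absent:
            raise DataError(
                f"dataset {dataset_id}: samples {absent} span multiple tables"
            )
        y = coerce_outcome(sub["outcome"], positive_labels)
        ds = ExpressionDataset(
            dataset_id=str(dataset_id),
            organ=sub["organ"].iloc[0],
            platform=sub["platform"].iloc[0],
            tissue=sub["tissue"].iloc[0],
            genes=[str(g) for g in frame.index],
            samples=sample_ids,
            X=frame[sample_ids].to_numpy(dtype=float),
            y=y,
        )
        if not ds.usable_for_training:
            logger.info(
                "dataset %s has a single outcome class; kept for prediction only",
                dataset_id,
            )
        datasets.append(ds)
    return DatasetCollection(datasets)


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT gene-set file: name, description, then members, tab-separated.

    Duplicate members within a set are removed (first occurrence kept);
    duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if len(members) < len([g for g in fields[2:] if g]):
                logger.info(
                    "%s:%d: set %s had duplicate members; %d unique kept",
                    path, lineno, name, len(members),
                )
            sets[name] = members
    return GeneSetLibrary(sets=sets, provenance=str(path))


def write_model(model, path: str | Path) -> None:
    """Serialize a trained model to schema-versioned JSON.

    Keys are sorted and floats use Python's shortest round-trip repr, so
    write -> read -> write is byte-identical.
    """
    payload = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_model(path: str | Path):
    from .top import TOPModel

    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise DataError(
            f"{path}: unsupported model schema version {version!r}; "
            f"this build reads version {MODEL_SCHEMA_VERSION}"
        )
    return TOPModel.from_dict(payload["model"])


def write_collection(collection: DatasetCollection, outdir: str | Path) -> None:
    """Write a collection bundle: per-dataset expression TSVs + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in collection.datasets:
        frame = ds.to_frame()
        if ds.platform == "rnaseq_counts":
            frame = frame.astype(int)
        write_expression_table(frame, outdir / f"{ds.dataset_id}.tsv")
        for s, label in zip(ds.samples, ds.y):
            rows.append(
                {
                    "sample_id": s,
                    "dataset_id": ds.dataset_id,
                    "organ": ds.organ,
                    "platform": ds.platform,
                    "tissue": ds.tissue,
                    "outcome": int(label),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_collection(
    bundle_dir: str | Path,
    positive_labels: Sequence[str] = DEFAULT_POSITIVE_LABELS,
) -> DatasetCollection:
    bundle_dir = Path(bundle_dir)
    metadata = read_metadata(bundle_dir / "metadata.tsv")
    tables = [
        read_expression_table(p)
        for p in sorted(bundle_dir.glob("*.tsv"))
        if p.name != "metadata.tsv"
    ]
    return assemble_collection(tables, metadata, positive_labels)
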