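"""Data containers and text I/O for multi-study two-group expression data.

A *study* is a gene x sample expression block comparing two biological
conditions (case vs. control) with replicate samples.  Several studies
sharing one gene universe form a :class:`MultiStudySet`.  Downstream
modelling never touches the raw expression values directly: each study is
reduced to a vector of moderated t-statistics, and those are arranged in a
:class:`TStatMatrix` together with the per-study degrees of freedom and the
alternative-density scale factor.

Expression tables are plain delimited text: first column gene identifier,
header row of sample identifiers, tab-separated by default.  Values are
expected to be normalised and log-transformed already; no transformation is
ever applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


@dataclass
class StudyDataset:
    """One study's expression block and its two-group design.

    ``values`` has shape (G, n_case + n_control); the case columns come
    first, then the control columns (``group_labels`` records the label of
    every column explicitly).
    """

    study_id: str
    values: np.ndarray
    gene_ids: list[str]
    group_labels: list[str]
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"study {self.study_id!r}: values must be 2-D")
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise DataError(f"study {self.study_id!r}: gene_ids length mismatch")
        if n != self.n_case + self.n_control:
            raise DataError(
                f"study {self.study_id!r}: {n} sample columns but "
                f"n_case + n_control = {self.n_case + self.n_control}"
            )
        if self.n_case < 2 or self.n_control < 2:
            raise DataError(
                f"study {self.study_id!r}: insufficient replicates "
                f"(need >= 2 per group, got {self.n_case} cases, "
                f"{self.n_control} controls)"
            )
        if len(self.group_labels) != n:
            raise DataError(f"study {self.study_id!r}: group_labels length mismatch")
        bad = set(self.group_labels) - {CASE, CONTROL}
        if bad:
            raise DataError(f"study {self.study_id!r}: unknown sample label {bad}")
        if self.group_labels.count(CASE) != self.n_case:
            raise DataError(f"study {self.study_id!r}: case label count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"study {self.study_id!r}: missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def case_values(self) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.group_labels) if lab == CASE]
        return self.values[:, idx]

    @property
    def control_values(self) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.group_labels) if lab == CONTROL]
        return self.values[:, idx]

    def subset_genes(self, gene_ids: list[str]) -> "StudyDataset":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [pos[g] for g in gene_ids]
        return StudyDataset(
            study_id=self.study_id,
            values=self.values[rows],
            gene_ids=list(gene_ids),
            group_labels=list(self.group_labels),
            n_case=self.n_case,
            n_control=self.n_control,
        )


@dataclass
class MultiStudySet:
    """An ordered collection of studies sharing one gene universe."""

    studies: list[StudyDataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.studies:
            raise DataError("MultiStudySet needs at least one study")
        ref = self.studies[0].gene_ids
        for s in self.studies[1:]:
            if s.gene_ids != ref:
                raise DataError(
                    f"study {s.study_id!r}: gene ids differ from first study"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.studies[0].gene_ids

    @property
    def n_genes(self) -> int:
        return self.studies[0].n_genes

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]


@dataclass
class TStatMatrix:
    """G x D moderated t-statistics plus per-study density parameters.

    ``df`` is the total degrees of freedom of the null Student-t density
    (prior df + residual df); ``scale_alt`` is the scale factor of the
    alternative density, sqrt(1 + w/v) >= 1.
    """

    t: np.ndarray
    df: np.ndarray
    scale_alt: np.ndarray
    gene_ids: list[str]
    study_ids: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.df = np.asarray(self.df, dtype=float)
        self.scale_alt = np.asarray(self.scale_alt, dtype=float)
        g, d = self.t.shape
        if len(self.gene_ids) != g or len(self.study_ids) != d:
            raise DataError("TStatMatrix: id lengths do not match t shape")
        if self.df.shape != (d,) or self.scale_alt.shape != (d,):
            raise DataError("TStatMatrix: df/scale_alt must be per-study vectors")
        if not np.all(np.isfinite(self.t)):
            g_bad, d_bad = np.argwhere(~np.isfinite(self.t))[0]
            raise DataError(
                f"non-finite t-statistic at gene {self.gene_ids[g_bad]!r}, "
                f"study {self.study_ids[d_bad]!r}"
            )
        if np.any(self.df <= 0):
            raise DataError("TStatMatrix: df must be positive")
        if np.any(self.scale_alt < 1.0):
            raise DataError("TStatMatrix: scale_alt must be >= 1")

    @property
    def n_genes(self) -> int:
        return self.t.shape[0]

    @property
    def n_studies(self) -> int:
        return self.t.shape[1]


# ---------------------------------------------------------------------------
# loading expression tables


def load_expression_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited gene x sample table; first column is the gene id."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns found")
    return df


def load_study(
    path,
    study_id: str,
    case_columns: list[str],
    control_columns: list[str],
    sep: str = "\t",
    drop_missing: bool = False,
) -> StudyDataset:
    """Load one study from a delimited table and a two-group design."""
    df = load_expression_table(path, sep=sep)
    missing_cols = [c for c in case_columns + control_columns if c not in df.columns]
    if missing_cols:
        raise DataError(f"study {study_id!r}: unknown sample columns {missing_cols}")
    sub = df[list(case_columns) + list(control_columns)]
    if sub.isna().any().any():
        if drop_missing:
            before = len(sub)
            sub = sub.dropna(axis=0)
            logger.warning(
                "study %s: dropped %d genes with missing values",
                study_id, before - len(sub),
            )
        else:
            raise DataError(f"study {study_id!r}: missing values present")
    labels = [CASE] * len(case_columns) + [CONTROL] * len(control_columns)
    return StudyDataset(
        study_id=study_id,
        values=sub.to_numpy(dtype=float),
        gene_ids=[str(g) for g in sub.index],
        group_labels=labels,
        n_case=len(case_columns),
        n_control=len(control_columns),
    )


def load_design(path) -> dict:
    """Read a YAML/JSON design file mapping study id -> file and columns."""
    with open(path) as fh:
        design = yaml.safe_load(fh)
    if not isinstance(design, dict) or not design:
        raise DataError(f"{path}: design must be a non-empty mapping")
    return design


def load_multistudy(
    paths: list,
    designs: dict,
    sep: str = "\t",
    drop_missing: bool = False,
) -> MultiStudySet:
    """Load several studies and align them on the shared gene universe.

    ``designs`` maps study id -> {"case_columns": [...],
    "control_columns": [...]}; ``paths`` gives one file per study in the
    same order as ``designs``.  Genes are aligned on the intersection of the
    per-study gene sets, kept in the gene order of the first study; a
    warning is logged when genes are dropped.
    """
    if len(paths) != len(designs):
        raise DataError("one path per design entry required")
    studies = []
    for path, (study_id, d) in zip(paths, designs.items()):
        studies.append(
            load_study(
                path,
                study_id=study_id,
                case_columns=d["case_columns"],
                control_columns=d["control_columns"],
                sep=sep,
                drop_missing=drop_missing,
            )
        )
    return align_studies(studies)


def align_studies(studies: list[StudyDataset]) -> MultiStudySet:
    """Intersect gene universes, preserving the first study's gene order."""
    common = set(studies[0].gene_ids)
    for s in studies[1:]:
        common &= set(s.gene_ids)
    if not common:
        raise DataError("gene universes have empty intersection")
    shared = [g for g in studies[0].gene_ids if g in common]
    n_dropped = max(len(s.gene_ids) for s in studies) - len(shared)
    if any(len(s.gene_ids) != len(shared) for s in studies):
        logger.warning(
            "gene universes differ; keeping %d shared genes (dropped up to %d)",
            len(shared), n_dropped,
        )
    return MultiStudySet(studies=[s.subset_genes(shared) for s in studies])


# ---------------------------------------------------------------------------
# t-statistic matrix I/O

_TSTAT_MAGIC = "# cormotif tstat v1"


def write_tstat(matrix: TStatMatrix, path) -> None:
    """Write a TStatMatrix as TSV with a commented header carrying the
    per-study degrees of freedom and alternative-density scales."""
    with open(path, "w") as fh:
        fh.write(_TSTAT_MAGIC + "\n")
        fh.write("# df:\t" + "\t".join(repr(float(x)) for x in matrix.df) + "\n")
        fh.write(
            "# scale_alt:\t"
            + "\t".join(repr(float(x)) for x in matrix.scale_alt)
            + "\n"
        )
        fh.write("gene_id\t" + "\t".join(matrix.study_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.t):
            fh.write(g + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_tstat(path) -> TStatMatrix:
    """Read a TStatMatrix written by :func:`write_tstat`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _TSTAT_MAGIC:
        raise DataError(f"{path}: not a cormotif t-statistic file")
    header: dict[str, list[float]] = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("#"):
            key, _, rest = line[1:].partition(":")
            header[key.strip()] = [float(x) for x in rest.split()]
        else:
            body_start = i
            break
    for required in ("df", "scale_alt"):
        if required not in header:
            raise DataError(f"{path}: header missing required field {required!r}")
    if body_start is None:
        raise DataError(f"{path}: no data rows")
    cols = lines[body_start].split("\t")
    if cols[0] != "gene_id":
        raise DataError(f"{path}: malformed column header")
    study_ids = cols[1:]
    gene_ids, rows = [], []
    for line in lines[body_start + 1 :]:
        if not line.strip():
            continue
        parts = line.split("\t")
        gene_ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    t = np.asarray(rows, dtype=float)
    bad = np.argwhere(~np.isfinite(t))
    if bad.size:
        g, d = bad[0]
        raise DataError(
            f"{path}: non-finite t for gene {gene_ids[g]!r}, study {study_ids[d]!r}"
        )
    return TStatMatrix(
        t=t,
        df=np.asarray(header["df"]),
        scale_alt=np.asarray(header["scale_alt"]),
        gene_ids=gene_ids,
        study_ids=study_ids,
    )
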