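"""Core data containers and plain-text readers/writers.

Expression matrices are genes x measurements tables (log-intensity or logCPM
units); each measurement column has a metadata row carrying the covariate
value, an optional biological group, and an optional individual identifier
(repeated measurements of one individual in longitudinal designs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_metadata",
    "read_gmt",
]

#: metadata columns with reserved meaning; extra columns pass through freely
META_COLUMNS = ("sample_id", "covariate", "group", "individual")


@dataclass
class ExpressionMatrix:
    """An m-gene x N-measurement expression matrix with per-measurement metadata.

    Parameters
    ----------
    values : (m, N) float array
        Expression on a log scale (or raw counts destined for logCPM).
    gene_ids : sequence of str, unique, length m.
    sample_meta : DataFrame, one row per measurement column
        Recognized columns: ``sample_id``, ``covariate`` (numeric),
        ``group`` (categorical), ``individual``.  Missing expression values
        are rejected, never imputed: the likelihood sums downstream assume
        complete per-gene vectors.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_meta: pd.DataFrame = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = list(self.gene_ids)
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {m} expression rows"
            )
        if len(set(self.gene_ids)) != m:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite expression value at gene "
                f"{self.gene_ids[i]!r}, column {j}: values must be complete"
            )
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"sample_id": [f"s{j}" for j in range(n)]}
            )
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        if len(self.sample_meta) != n:
            raise ValueError(
                f"metadata has {len(self.sample_meta)} rows but the "
                f"expression matrix has {n} measurement columns"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.values.shape[1]

    @property
    def covariate(self) -> np.ndarray:
        if "covariate" not in self.sample_meta:
            raise ValueError("sample metadata has no 'covariate' column")
        x = pd.to_numeric(self.sample_meta["covariate"]).to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError("covariate contains missing/non-finite values")
        return x

    @property
    def group(self) -> np.ndarray:
        if "group" not in self.sample_meta:
            raise ValueError("sample metadata has no 'group' column")
        return self.sample_meta["group"].astype(str).to_numpy()

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        ids = [g for g, keep in zip(self.gene_ids, mask) if keep]
        return ExpressionMatrix(self.values[mask], ids, self.sample_meta.copy())

    def subset_measurements(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            self.values[:, mask],
            self.gene_ids,
            self.sample_meta.loc[mask].reset_index(drop=True),
        )


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes-as-rows expression table (first column ``gene_id``)."""
    sep = {"tsv": "\t", "csv": ","}[format]
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    gene_ids = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~body.isna().to_numpy()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing expression cell at gene "
            f"{gene_ids[i]!r}, column {body.columns[j]!r}"
        )
    meta = pd.DataFrame({"sample_id": body.columns.astype(str)})
    em = ExpressionMatrix(numeric.to_numpy(float), gene_ids, meta)
    logger.info("read expression matrix: %d genes x %d measurements",
                em.n_genes, em.n_measurements)
    return em


def write_expression(em: ExpressionMatrix, path, format: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[format]
    df = pd.DataFrame(
        em.values,
        index=pd.Index(em.gene_ids, name="gene_id"),
        columns=em.sample_meta["sample_id"].astype(str),
    )
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_metadata(path, expression: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read a sample metadata TSV (columns sample_id[, covariate, group, individual])."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must contain a 'sample_id' column")
    if expression is not None:
        ids = expression.sample_meta["sample_id"].astype(str)
        if set(meta["sample_id"]) != set(ids):
            raise ValueError(
                f"metadata sample ids do not match the expression header "
                f"({len(meta)} metadata rows, {len(ids)} measurement columns)"
            )
        meta = meta.set_index("sample_id").loc[ids].reset_index()
    return meta


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), membership resolved against a study's genes."""

    sets: dict

    def __post_init__(self):
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("gene set names must be unique")

    def matched(self, gene_ids) -> "GeneSetCollection":
        """Drop members absent from ``gene_ids`` (logged), keep set order."""
        universe = set(gene_ids)
        out, dropped = {}, 0
        for name, members in self.sets.items():
            kept = [g for g in members if g in universe]
            dropped += len(members) - len(kept)
            out[name] = kept
        if dropped:
            logger.info("dropped %d unmatched gene-set members", dropped)
        return GeneSetCollection(out)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name<TAB>description<TAB>genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets)
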