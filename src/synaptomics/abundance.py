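"""Feature x sample abundance container for TMT reporter-ion quantification.

An :class:`AbundanceMatrix` holds strictly positive grouped abundances for one
brain region at one omics level (protein or phosphopeptide), with per-sample
group/sex metadata parallel to the value columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("PME", "PSE")

#: Non-sample columns recognised in the TSV dialect.
FEATURE_COLUMNS = ("feature_id", "gene_id", "site_label")


class DataError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass
class AbundanceMatrix:
    """Features x samples positive abundances with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature_id, columns are sample names, entries
        strictly positive reporter abundances.
    sample_meta
        DataFrame indexed by sample name with columns ``group`` (PME/PSE),
        ``sex`` and ``region``, parallel to ``values.columns``.
    gene_ids
        Series mapping feature_id -> gene symbol.
    site_labels
        Optional Series mapping feature_id -> phosphosite annotation
        (phosphopeptide level only).
    region
        Brain-region label (e.g. M1).
    level
        "protein" or "phospho".
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_ids: pd.Series
    site_labels: pd.Series | None = None
    region: str = ""
    level: str = "protein"

    def __post_init__(self) -> None:
        if not (self.values.to_numpy() > 0).all():
            raise DataError("abundances must be strictly positive")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise DataError("sample_meta index must parallel value columns")
        groups = set(self.sample_meta["group"].unique())
        if not groups.issubset(set(GROUPS)) or len(groups) != 2:
            raise DataError(f"exactly two group levels {GROUPS} required, got {sorted(groups)}")
        if not self.gene_ids.index.equals(self.values.index):
            raise DataError("gene_ids must be indexed by feature_id parallel to values")
        if self.site_labels is not None and not self.site_labels.index.equals(self.values.index):
            raise DataError("site_labels must be indexed by feature_id parallel to values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self, group: str) -> list[str]:
        """Sample names belonging to one treatment group."""
        mask = self.sample_meta["group"] == group
        return list(self.sample_meta.index[mask])

    def copy_with(self, values: pd.DataFrame) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=values,
            sample_meta=self.sample_meta.copy(),
            gene_ids=self.gene_ids.copy(),
            site_labels=None if self.site_labels is None else self.site_labels.copy(),
            region=self.region,
            level=self.level,
        )

    # ------------------------------------------------------------------ I/O

    def write_tsv(self, path) -> None:
        """Write the matrix in the package TSV dialect.

        Rows are features; leading columns feature_id, gene_id and (for
        phosphopeptides) site_label; remaining columns are samples named
        ``<group>_<sex>_<replicate>``. A header comment records region/level.
        """
        out = pd.DataFrame({"feature_id": self.values.index, "gene_id": self.gene_ids.values})
        if self.site_labels is not None:
            out["site_label"] = self.site_labels.values
        for col in self.values.columns:
            out[col] = self.values[col].values
        with open(path, "w") as fh:
            fh.write(f"# region={self.region}\tlevel={self.level}\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AbundanceMatrix":
        """Read a matrix written by :meth:`write_tsv`.

        Tolerant of extra non-sample columns (as in Proteome Discoverer
        exports): any column that does not parse as ``group_sex_replicate``
        with a known group is ignored.
        """
        region, level = "", "protein"
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].strip().split("\t"):
                key, _, val = tok.partition("=")
                if key.strip() == "region":
                    region = val
                elif key.strip() == "level":
                    level = val
        df = pd.read_csv(path, sep="\t", comment="#")
        if "feature_id" not in df.columns:
            raise DataError(f"{path}: missing feature_id column")
        sample_cols, meta_rows = [], []
        for col in df.columns:
            parts = col.split("_")
            if len(parts) == 3 and parts[0] in GROUPS:
                sample_cols.append(col)
                meta_rows.append({"group": parts[0], "sex": parts[1], "region": region})
        if not sample_cols:
            raise DataError(f"{path}: no sample columns named <group>_<sex>_<replicate>")
        values = df.set_index("feature_id")[sample_cols]
        gene_ids = df.set_index("feature_id")["gene_id"]
        site = None
        if "site_label" in df.columns:
            site = df.set_index("feature_id")["site_label"]
        meta = pd.DataFrame(meta_rows, index=sample_cols)
        return cls(values=values, sample_meta=meta, gene_ids=gene_ids, site_labels=site,
                   region=region, level=level)
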