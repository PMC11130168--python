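"""Shared containers for expression cohorts and gene modules.

Expression values are log2-scale intensities held in a pandas DataFrame with
genes as rows and samples as columns; every sample carries a batch label.
Gene modules are a disjoint partition of a gene universe into named groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GeneModuleSet"]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression with per-sample batch labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns are sample identifiers.
        All entries must be finite.
    batch
        Series of batch labels indexed by sample identifier. If omitted every
        sample is assigned to a single batch ``"batch0"``.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.values.columns, name="batch")
        else:
            self.batch = pd.Series(self.batch)
            if set(self.batch.index) != set(self.values.columns):
                raise ValueError("batch labels must cover exactly the sample identifiers")
            self.batch = self.batch.reindex(self.values.columns)
            self.batch.name = "batch"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.batch.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.batch.loc[samples])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batch.copy())

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column ``gene_id``, remaining columns samples."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, batch: pd.Series | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, batch)


@dataclass
class GeneModuleSet:
    """A disjoint assignment of genes to named modules.

    ``modules`` maps module identifier to its gene list; genes not assigned to
    any module are in ``unassigned``. ``provenance`` records the parameters the
    modules were produced with (adjacency power, connectivity cutoff, cut
    sweep, minimum size).
    """

    modules: dict[str, list[str]]
    unassigned: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, genes in self.modules.items():
            gset = set(genes)
            if len(gset) != len(genes):
                raise ValueError(f"module {mid} lists a gene twice")
            if seen & gset:
                raise ValueError(f"module {mid} overlaps another module")
            seen |= gset
        if seen & set(self.unassigned):
            raise ValueError("unassigned genes overlap module genes")

    @property
    def module_ids(self) -> list[str]:
        return sorted(self.modules, key=self._sort_key)

    @staticmethod
    def _sort_key(mid: str):
        # "M2" < "M10": numeric suffix sorts numerically when present
        digits = "".join(ch for ch in mid if ch.isdigit())
        return (int(digits) if digits else 0, mid)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for mid in self.module_ids:
            out.extend(self.modules[mid])
        return out

    def gene_to_module(self) -> pd.Series:
        pairs = {g: mid for mid in self.module_ids for g in self.modules[mid]}
        return pd.Series(pairs, name="module")

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Two-column TSV (gene, module); unassigned genes get module ``"-"``.

        Provenance is written next to the TSV as ``<path>.provenance.json``.
        """
        path = Path(path)
        rows = [(g, mid) for mid in self.module_ids for g in sorted(self.modules[mid])]
        rows += [(g, "-") for g in sorted(self.unassigned)]
        pd.DataFrame(rows, columns=["gene", "module"]).to_csv(path, sep="\t", index=False)
        with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneModuleSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype=str)
        modules: dict[str, list[str]] = {}
        unassigned: list[str] = []
        for gene, mid in zip(df["gene"], df["module"]):
            if mid == "-":
                unassigned.append(gene)
            else:
                modules.setdefault(mid, []).append(gene)
        prov_path = path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(modules, unassigned, provenance)
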