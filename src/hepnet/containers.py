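"""Core in-memory containers for the heparin-enriched plasma pipeline.

All tabular data is held in pandas objects with ``numpy.nan`` as the single
missing-value sentinel.  Protein identifiers follow the ``UniProtID|GeneSymbol``
convention used by common search-engine exports: the UniProt accession keys
matrix joins, while the (upper-cased) gene symbol is the identity used for
network-module and gene-set matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("raw", "normalized", "log2", "zscore")
DIAGNOSES = ("Control", "AD", "AsymAD")
GREY = "grey"

#: trait columns measured on every plasma donor
TRAIT_COLUMNS = (
    "MoCA",
    "CSF_Abeta42",
    "CSF_tTau",
    "CSF_pTau181",
    "tTau_Abeta_ratio",
    "plasma_pTau181",
)

REQUIRED_SHEET_COLUMNS = ("sample_id", "set_label", "batch_label", "is_gis", "diagnosis")


def split_protein_id(protein_id: str) -> tuple[str, str]:
    """Split ``UniProtID|GeneSymbol`` into (uniprot, SYMBOL).

    Ids without a ``|`` are treated as being their own gene symbol.
    """
    uniprot, sep, symbol = protein_id.partition("|")
    if not sep or not symbol:
        return uniprot, uniprot.upper()
    return uniprot, symbol.upper()


def gene_symbols(protein_ids) -> pd.Index:
    """Upper-cased gene symbols for a sequence of protein ids."""
    return pd.Index([split_protein_id(p)[1] for p in protein_ids])


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance matrix with an explicit scale flag.

    ``data`` is a float DataFrame (rows = protein ids, columns = sample ids);
    missing measurements are ``nan``.  ``scale`` declares the space of the
    values: strictly positive intensities for ``raw``/``normalized``, finite
    log2 abundances for ``log2``, and row-standardized values for ``zscore``.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)
        self.data.index.name = "protein_id"
        self.data.columns.name = None
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy()
        observed = ~np.isnan(vals)
        if self.scale in ("raw", "normalized"):
            if np.any(vals[observed] <= 0):
                raise ValueError(f"{self.scale} matrix contains non-positive observed values")
        else:
            if np.any(~np.isfinite(vals[observed])):
                raise ValueError(f"{self.scale} matrix contains non-finite observed values")

    # -- convenience ------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def symbols(self) -> pd.Index:
        return gene_symbols(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale)

    def to_log2(self) -> "AbundanceMatrix":
        """Log2-transform a raw/normalized matrix (log2 passes through)."""
        if self.scale == "log2":
            return self.copy()
        if self.scale not in ("raw", "normalized"):
            raise ValueError(f"cannot log2-transform a {self.scale} matrix")
        return AbundanceMatrix(np.log2(self.data), "log2")


@dataclass
class SampleSheet:
    """Per-sample study design: set, batch, channel, GIS flag, diagnosis.

    GIS (global internal standard) rows are pooled-reference channels; they
    carry a missing diagnosis.  Extra columns (age, sex, PMI, ...) ride along
    as covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValueError("missing column sample_id")
            df = df.set_index("sample_id")
        for col in REQUIRED_SHEET_COLUMNS[1:]:
            if col not in df.columns:
                raise ValueError(f"missing column {col}")
        df = df.copy()
        df["is_gis"] = df["is_gis"].astype(bool)
        diag = df["diagnosis"].astype(object).replace({"": np.nan, "NA": np.nan, "nan": np.nan})
        diag = diag.where(pd.notna(diag), np.nan)
        bad = diag.dropna()[~diag.dropna().isin(DIAGNOSES)]
        if len(bad):
            raise ValueError(
                f"unknown diagnosis {bad.iloc[0]!r} for sample {bad.index[0]!r}; "
                f"expected one of {DIAGNOSES} or missing"
            )
        gis_with_diag = df.index[df["is_gis"] & diag.notna()]
        if len(gis_with_diag):
            raise ValueError(f"GIS sample {gis_with_diag[0]!r} carries a diagnosis")
        df["diagnosis"] = diag
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def gis_ids(self) -> pd.Index:
        return self.data.index[self.data["is_gis"]]

    def batches(self, set_label: str | None = None) -> list:
        df = self.data if set_label is None else self.data[self.data["set_label"] == set_label]
        return list(dict.fromkeys(df["batch_label"]))

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)].copy())

    def check_matches(self, matrix: AbundanceMatrix) -> None:
        missing = matrix.sample_ids.difference(self.data.index)
        if len(missing):
            raise ValueError(f"samples absent from sheet: {list(missing[:5])}")


@dataclass
class TraitTable:
    """AD biomarker / cognition measurements per sample (missing allowed)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValueError("missing column sample_id")
            df = df.set_index("sample_id")
        df = df.astype(float)
        for col in TRAIT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(TRAIT_COLUMNS)]
        both = df["CSF_tTau"].notna() & df["CSF_Abeta42"].notna() & df["tTau_Abeta_ratio"].notna()
        if both.any():
            expect = df.loc[both, "CSF_tTau"] / df.loc[both, "CSF_Abeta42"]
            rel = np.abs(df.loc[both, "tTau_Abeta_ratio"] - expect) / np.maximum(np.abs(expect), 1e-300)
            if (rel > 1e-9).any():
                bad = rel.index[rel > 1e-9][0]
                raise ValueError(f"tTau_Abeta_ratio inconsistent with components for sample {bad!r}")
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index


@dataclass
class NetworkReference:
    """A reference co-expression network to project a proteome onto.

    ``membership`` maps protein id (or bare gene symbol) -> module id;
    ``eigenproteins`` is the module x sample matrix of module summary
    profiles, each standardized (mean 0, sd 1 with the n-1 denominator).
    """

    membership: pd.Series
    eigenproteins: pd.DataFrame
    module_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = pd.Series(self.membership, dtype="string")
        self.membership.index.name = "protein_id"
        self.eigenproteins = pd.DataFrame(self.eigenproteins).astype(float)
        self.eigenproteins.index.name = "module_id"
        self.eigenproteins.columns.name = None
        allowed = set(self.module_ids) | {GREY}
        bad = set(self.membership.dropna()) - allowed
        if bad:
            raise ValueError(f"membership refers to unknown modules: {sorted(bad)[:5]}")
        vals = self.eigenproteins.to_numpy()
        if vals.shape[1] >= 2:
            mean = vals.mean(axis=1)
            sd = vals.std(axis=1, ddof=1)
            if np.any(np.abs(mean) > 1e-6) or np.any(np.abs(sd - 1.0) > 1e-6):
                raise ValueError("eigenprotein rows must be standardized (mean 0, sd 1)")

    @property
    def module_ids(self) -> list:
        return list(self.eigenproteins.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.eigenproteins.columns

    def module_symbols(self, module_id: str) -> pd.Index:
        """Upper-cased gene symbols of one module's members."""
        members = self.membership.index[self.membership == module_id]
        return gene_symbols(members)

    def membership_by_symbol(self) -> pd.Series:
        """Membership re-keyed by gene symbol (first occurrence wins)."""
        sym = gene_symbols(self.membership.index)
        out = pd.Series(self.membership.to_numpy(), index=sym, dtype="string")
        return out[~out.index.duplicated()]


@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        # upper-case and de-duplicate preserving order
        self.genes = tuple(dict.fromkeys(g.upper() for g in self.genes))


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT-style)."""

    sets: dict = field(default_factory=dict)

    def add(self, set_id: str, description: str, genes) -> None:
        if set_id in self.sets:
            warnings.warn(f"duplicate gene set id {set_id!r}; keeping the last")
        self.sets[set_id] = GeneSet(set_id, description, tuple(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]
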