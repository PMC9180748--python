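"""Tabular I/O and protein-identifier harmonization.

Quantitation tables are delimited text (tab or comma, auto-detected)
with one row per protein and columns::

    accession  gene_symbol  unique_peptides  id_fdr  <sample-1> ... <sample-n>

Annotation catalogs are one file per evidence source with an ``id``
column and an optional ``category`` (bovine: SwissProt/TrEMBL; rat:
EL/Misc) or ``confidence`` column (Compartments, numeric in [0, 5]).

Identifiers from different species and resources are reconciled with
:func:`harmonize_id`: UniProt isoform suffixes are stripped and gene
symbols uppercased, so that human data can be matched against bovine,
rat and mouse resources by symbol when no accession-level mapping
exists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Criterion names of the lysosomal-confidence scoring scheme; every
#: annotation catalog must declare one of these as its source.
CRITERION_NAMES = ("bovine", "rat", "lgdb", "uniprot_kw", "compartments", "hpa", "ncl")

#: Scheme layer of each criterion (1: MS-based lysosomal proteomes,
#: 2: curated localization resources, 3: cross-study NCL evidence).
CRITERION_LAYERS = {
    "bovine": 1,
    "rat": 1,
    "lgdb": 2,
    "uniprot_kw": 2,
    "compartments": 2,
    "hpa": 2,
    "ncl": 3,
}

#: Allowed category vocabulary for categorical sources.
CATEGORY_VOCAB = {
    "bovine": ("TrEMBL", "SwissProt"),
    "rat": ("Misc", "EL"),
}

META_COLUMNS = ("accession", "gene_symbol", "unique_peptides", "id_fdr")

# UniProt accession: 6 or 10 characters, e.g. P12345, Q9NUP9, A0A087WUL8.
_UNIPROT_RE = re.compile(
    r"(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
)
_ISOFORM_RE = re.compile(r"-\d+$")


def harmonize_id(raw_id: str) -> str:
    """Canonicalize a protein accession or gene symbol.

    Whitespace is trimmed and a trailing UniProt isoform suffix
    (``-<digits>``) removed.  Strings matching the UniProt accession
    pattern are left case-intact; anything else is treated as a gene
    symbol and uppercased.  The function is idempotent.
    """
    if raw_id is None or not str(raw_id).strip():
        raise ValueError("empty identifier cannot be harmonized")
    s = str(raw_id).strip()
    s = _ISOFORM_RE.sub("", s)
    if not s:
        raise ValueError(f"identifier {raw_id!r} is empty after isoform stripping")
    if _UNIPROT_RE.fullmatch(s):
        return s
    return s.upper()


@dataclass
class QuantMatrix:
    """Proteins × samples intensity table with a sample→group assignment.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein accession with one column per
        sample.  Missing values are NaN (never zero-filled); observed
        values must be non-negative.
    group_of
        Mapping from every sample id to its experimental group label.
    """

    intensities: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein accessions: {dups}")
        cols = self.intensities.columns
        if cols.has_duplicates:
            raise ValueError(f"duplicate sample ids: {cols[cols.duplicated()].tolist()}")
        unmapped = [s for s in cols if s not in self.group_of]
        if unmapped:
            raise ValueError(f"samples without a group assignment: {unmapped}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            bad = self.intensities.lt(0).any()
            raise ValueError(
                f"negative intensities in samples: {bad[bad].index.tolist()}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass
class AnnotationCatalog:
    """Membership list of one evidence source of the scoring scheme.

    ``entries`` maps canonical ids to the observation the source
    provides: a category string for the bovine and rat proteomes, a
    numeric confidence in [0, 5] for Compartments, and ``True`` for
    plain membership sources (LGDB, UniProt keyword, HPA, NCL).
    """

    source: str
    layer: int
    species: str = "human"
    entries: dict[str, object] = field(default_factory=dict)
    name: str | None = None  # distinguishes e.g. individual NCL studies

    def __post_init__(self) -> None:
        if self.source not in CRITERION_NAMES:
            raise ValueError(
                f"unknown annotation source {self.source!r}; "
                f"expected one of {CRITERION_NAMES}"
            )
        expected_layer = CRITERION_LAYERS[self.source]
        if self.layer != expected_layer:
            raise ValueError(
                f"source {self.source!r} belongs to layer {expected_layer}, "
                f"got {self.layer}"
            )
        for pid, obs in self.entries.items():
            _validate_observation(self.source, pid, obs)
        if self.name is None:
            self.name = self.source

    def __contains__(self, canonical_id: str) -> bool:
        return canonical_id in self.entries


def _validate_observation(source: str, pid: str, obs: object) -> None:
    if source in CATEGORY_VOCAB:
        if obs not in CATEGORY_VOCAB[source]:
            raise ValueError(
                f"unknown category {obs!r} for source {source!r} (id {pid}); "
                f"allowed: {CATEGORY_VOCAB[source]}"
            )
    elif source == "compartments":
        try:
            conf = float(obs)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValueError(
                f"Compartments confidence for {pid} must be numeric, got {obs!r}"
            ) from None
        if not 0.0 <= conf <= 5.0:
            raise ValueError(
                f"Compartments confidence {conf} for {pid} outside [0, 5]"
            )
    else:
        if obs is not True:
            raise ValueError(
                f"source {source!r} is membership-only; entry for {pid} "
                f"must be True, got {obs!r}"
            )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV file, auto-detecting the delimiter from the header."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")


def read_quant_table(
    path: str | Path, group_map: Mapping[str, str]
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Read a protein quantitation table into a validated matrix + metadata.

    Returns the :class:`QuantMatrix` and a ProteinMeta DataFrame indexed
    by accession with columns ``gene_symbol``, ``unique_peptides``,
    ``id_fdr``.  Missing intensity cells are preserved as NaN.
    """
    df = _read_delimited(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample intensity columns found")
    unmapped = [c for c in sample_cols if c not in group_map]
    if unmapped:
        raise ValueError(f"{path}: samples not in group map: {unmapped}")

    if df["accession"].duplicated().any():
        dup = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"{path}: duplicated accession(s): {dup}")

    meta = df[list(META_COLUMNS)].set_index("accession")
    meta["unique_peptides"] = meta["unique_peptides"].astype(int)
    meta["id_fdr"] = meta["id_fdr"].astype(float)
    if (meta["unique_peptides"] < 0).any():
        raise ValueError(f"{path}: negative unique_peptides")
    if ((meta["id_fdr"] < 0) | (meta["id_fdr"] > 1)).any():
        raise ValueError(f"{path}: id_fdr outside [0, 1]")

    intensities = df.set_index("accession")[sample_cols].astype(float)
    matrix = QuantMatrix(intensities, {s: group_map[s] for s in sample_cols})
    return matrix, meta


def write_quant_table(
    path: str | Path, matrix: QuantMatrix, meta: pd.DataFrame
) -> None:
    """Write a quantitation table as TSV (inverse of :func:`read_quant_table`)."""
    meta_out = meta.reindex(matrix.protein_ids)
    out = pd.concat([meta_out, matrix.intensities], axis=1)
    out.index.name = "accession"
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path, source: str, layer: int) -> AnnotationCatalog:
    """Read one evidence source's catalog from a delimited file.

    Ids are harmonized via :func:`harmonize_id`; the category or
    confidence vocabulary is validated against the source.
    """
    df = _read_delimited(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: catalog requires an 'id' column")
    species = str(df["species"].iloc[0]) if ("species" in df.columns and len(df)) else "human"
    entries: dict[str, object] = {}
    for _, row in df.iterrows():
        pid = harmonize_id(row["id"])
        if "category" in df.columns and pd.notna(row.get("category")):
            obs: object = str(row["category"])
        elif "confidence" in df.columns and pd.notna(row.get("confidence")):
            obs = float(row["confidence"])
        else:
            obs = True
        entries[pid] = obs
    return AnnotationCatalog(source=source, layer=layer, species=species, entries=entries)


def write_catalog(path: str | Path, catalog: AnnotationCatalog) -> None:
    """Write a catalog as TSV (inverse of :func:`read_catalog`)."""
    rows = []
    for pid, obs in catalog.entries.items():
        row = {"id": pid, "species": catalog.species}
        if catalog.source in CATEGORY_VOCAB:
            row["category"] = obs
        elif catalog.source == "compartments":
            row["confidence"] = repr(float(obs))  # full precision round trip
        rows.append(row)
    cols = ["id", "species"]
    if catalog.source in CATEGORY_VOCAB:
        cols.append("category")
    elif catalog.source == "compartments":
        cols.append("confidence")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-column gene list (header optional) into a harmonized set."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            tok = line.strip().split("\t")[0].split(",")[0]
            if not tok:
                continue
            if i == 0 and tok.lower() in {"id", "gene", "gene_symbol", "symbol"}:
                continue
            genes.add(harmonize_id(tok))
    return genes
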