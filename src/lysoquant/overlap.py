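"""Cross-model and cross-study overlap of differential proteins.

Layer-3 evidence of the scoring scheme: a protein gains NCL points if
it was also reported in a lysosomal dataset from another NCL disease
model (CLN3/CLN6/CLN7/CLN11 studies, supplied as offline gene lists).
The overlap matrix records, for each of this study's high/very-high
confidence differential proteins, which external datasets also report
it — the data behind a presence heat map.  Matching is by harmonized
gene symbol (cross-species) or accession; direction of dysregulation
is carried when supplied but never affects matching.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from lysoquant.quantio import AnnotationCatalog, harmonize_id
from lysoquant.scoring import TIER_HC, TIER_VHC, ScoringResults


def ncl_match(gene: str, ncl_catalogs: Sequence[AnnotationCatalog]) -> bool:
    """True iff the gene appears in at least one NCL-model catalog."""
    g = harmonize_id(gene)
    return any(g in cat.entries for cat in ncl_catalogs)


def common_deps(dep_sets: Sequence[Iterable[str]]) -> set[str]:
    """Exact intersection of ≥2 harmonized DEP id sets (order-insensitive)."""
    if len(dep_sets) < 2:
        raise ValueError("need at least 2 DEP sets to intersect")
    harmonized = [{harmonize_id(x) for x in s} for s in dep_sets]
    out = harmonized[0]
    for s in harmonized[1:]:
        out &= s
    return out


def build_overlap_matrix(
    own_deps: ScoringResults | pd.DataFrame,
    external_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Presence matrix of own high-confidence DEPs across external datasets.

    ``own_deps`` is a scored table (or :class:`ScoringResults`); only
    tiers HC and vHC enter the matrix.  Returns a boolean DataFrame
    with one row per own protein reported in ≥1 external set and one
    column per external dataset.
    """
    table = own_deps.table if isinstance(own_deps, ScoringResults) else own_deps
    if "tier" in table.columns:
        table = table[table["tier"].isin((TIER_HC, TIER_VHC))]

    ids: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        keys = {harmonize_id(row["accession"])}
        gene = row.get("gene_symbol")
        if isinstance(gene, str) and gene:
            keys.add(harmonize_id(gene))
        label = gene if isinstance(gene, str) and gene else row["accession"]
        ids[harmonize_id(label)] = keys

    ext = {name: {harmonize_id(g) for g in genes} for name, genes in external_sets.items()}
    rows = {}
    for label, keys in ids.items():
        hits = {name: bool(keys & genes) for name, genes in ext.items()}
        if any(hits.values()):
            rows[label] = hits
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(ext))
    matrix.index.name = "id"
    return matrix.astype(bool) if not matrix.empty else matrix
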