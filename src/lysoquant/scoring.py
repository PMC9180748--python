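"""Hierarchical lysosomal-confidence scoring and tier assignment.

Each protein is scored against three layers of evidence for lysosomal
residence:

* **Layer 1** — MS-based lysosomal proteomes: the bovine SWATH dataset
  (TrEMBL match 1 point, SwissProt-reviewed match 2 points) and the rat
  lysosomal proteome (miscellaneous vesicle/granule/multi-localization
  fraction 1 point, endo-lysosome fraction 2 points).
* **Layer 2** — curated localization resources: the combined
  human/mouse lysosomal gene databases (hLGDB/mLGDB, 2 points), the
  reviewed UniProtKB section with the "lysosome" keyword (2 points),
  the Compartments database lysosome confidence banded into points
  (>2 and <4 → 1 point, ≥4 and ≤5 → 2 points), and the Human Protein
  Atlas lysosomal localization call (2 points).
* **Layer 3** — presence in a lysosomal dataset from another NCL
  disease model (2 points).

Totals range 0–14 under the default scheme and map onto confidence
tiers: 6–14 very high (vHC), 3–5 high (HC), 1–2 medium (MC); proteins
scoring 0 are discarded (LOW).  The printed tier bands overlap at 6
points ("3–6" high vs "6–14" very high); the higher tier wins, which
is configurable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from lysoquant.quantio import (
    CATEGORY_VOCAB,
    CRITERION_NAMES,
    AnnotationCatalog,
    harmonize_id,
)

TIER_VHC = "vHC"
TIER_HC = "HC"
TIER_MC = "MC"
TIER_LOW = "LOW"
TIER_ORDER = (TIER_LOW, TIER_MC, TIER_HC, TIER_VHC)


@dataclass(frozen=True)
class ScoringScheme:
    """Point awards and tier bands of the confidence scoring system.

    ``category_points`` holds the per-category awards of the
    categorical layer-1 criteria; ``membership_points`` the award of
    each presence/absence criterion; ``compartments_bands`` the
    ``(low_award, high_award)`` pair for the Compartments confidence
    bands.  Tier minima define the score→tier mapping; the default
    ``vhc_min=6`` resolves the band overlap at 6 points upward.
    """

    category_points: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "bovine": {"TrEMBL": 1, "SwissProt": 2},
            "rat": {"Misc": 1, "EL": 2},
        }
    )
    membership_points: Mapping[str, int] = field(
        default_factory=lambda: {"lgdb": 2, "uniprot_kw": 2, "hpa": 2, "ncl": 2}
    )
    compartments_bands: tuple[int, int] = (1, 2)
    vhc_min: int = 6
    hc_min: int = 3
    mc_min: int = 1
    discard_below: int = 1

    @property
    def criteria(self) -> tuple[str, ...]:
        return CRITERION_NAMES

    def criterion_max(self, criterion: str) -> int:
        if criterion in self.category_points:
            return max(self.category_points[criterion].values())
        if criterion == "compartments":
            return max(self.compartments_bands)
        return self.membership_points[criterion]

    @property
    def max_total(self) -> int:
        """Maximum attainable total (14 under defaults)."""
        return sum(self.criterion_max(c) for c in self.criteria)

    def observation_space(self, criterion: str) -> tuple[object, ...]:
        """All distinct-scoring observations a criterion can take."""
        if criterion in self.category_points:
            return (None, *self.category_points[criterion].keys())
        if criterion == "compartments":
            # representatives of the three confidence bands
            return (None, 3.0, 5.0)
        return (False, True)

    def to_dict(self) -> dict:
        return {
            "category_points": {k: dict(v) for k, v in self.category_points.items()},
            "membership_points": dict(self.membership_points),
            "compartments_bands": list(self.compartments_bands),
            "vhc_min": self.vhc_min,
            "hc_min": self.hc_min,
            "mc_min": self.mc_min,
            "discard_below": self.discard_below,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringScheme":
        known = {
            "category_points",
            "membership_points",
            "compartments_bands",
            "vhc_min",
            "hc_min",
            "mc_min",
            "discard_below",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scoring-scheme keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "compartments_bands" in kwargs:
            kwargs["compartments_bands"] = tuple(kwargs["compartments_bands"])
        return cls(**kwargs)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class ScoreCard:
    """Per-criterion points, total and confidence tier of one protein."""

    accession: str
    points: dict[str, int]
    total: int
    tier: str

    @property
    def retained(self) -> bool:
        return self.tier != TIER_LOW


def compartments_points(
    confidence: float, scheme: ScoringScheme = DEFAULT_SCHEME
) -> int:
    """Band a Compartments lysosome confidence value into points.

    confidence ≤ 2 → 0; 2 < confidence < 4 → low award (1);
    4 ≤ confidence ≤ 5 → high award (2).
    """
    conf = float(confidence)
    if not 0.0 <= conf <= 5.0:
        raise ValueError(f"Compartments confidence {conf} outside [0, 5]")
    low, high = scheme.compartments_bands
    if conf >= 4.0:
        return high
    if conf > 2.0:
        return low
    return 0


def criterion_points(
    scheme: ScoringScheme, criterion: str, observation: object
) -> int:
    """Points awarded by one criterion for one observation.

    ``None``/``False`` (or an omitted criterion) scores 0.  Categorical
    criteria expect a category string, Compartments a numeric
    confidence, membership criteria a boolean.
    """
    if criterion not in scheme.criteria:
        raise ValueError(f"unknown criterion {criterion!r}")
    if observation is None or observation is False:
        return 0
    if criterion in scheme.category_points:
        if isinstance(observation, (set, frozenset, list, tuple)):
            cats = set(observation)
            if len(cats) > 1:
                raise ValueError(
                    f"contradictory categories {sorted(map(str, cats))} "
                    f"for criterion {criterion!r}"
                )
            observation = next(iter(cats))
        table = scheme.category_points[criterion]
        if observation not in table:
            raise ValueError(
                f"unknown category {observation!r} for criterion {criterion!r}; "
                f"allowed: {tuple(table)}"
            )
        return table[observation]
    if criterion == "compartments":
        return compartments_points(observation, scheme)  # type: ignore[arg-type]
    if observation is not True:
        raise ValueError(
            f"criterion {criterion!r} expects a boolean observation, "
            f"got {observation!r}"
        )
    return scheme.membership_points[criterion]


def assign_tier(total: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> str:
    """Map a total score onto a confidence tier."""
    if total < 0:
        raise ValueError(f"negative total score {total}")
    if total >= scheme.vhc_min:
        return TIER_VHC
    if total >= scheme.hc_min:
        return TIER_HC
    if total >= scheme.mc_min:
        return TIER_MC
    return TIER_LOW


def score_protein(
    scheme: ScoringScheme,
    observations: Mapping[str, object],
    accession: str = "",
) -> ScoreCard:
    """Score one protein from its per-criterion observations.

    Criteria absent from ``observations`` are treated as negative.
    """
    unknown = set(observations) - set(scheme.criteria)
    if unknown:
        raise ValueError(f"unknown criteria in observations: {sorted(unknown)}")
    points = {
        c: criterion_points(scheme, c, observations.get(c)) for c in scheme.criteria
    }
    total = sum(points.values())
    return ScoreCard(
        accession=accession, points=points, total=total, tier=assign_tier(total, scheme)
    )


def enumerate_observation_combinations(
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Iterable[dict[str, object]]:
    """Yield every combination of distinct-scoring observations.

    Under the default scheme this is 3×3×2×2×3×2×2 = 432 combinations,
    used by the exhaustive scoring-ceiling check.
    """
    spaces = [scheme.observation_space(c) for c in scheme.criteria]
    for combo in itertools.product(*spaces):
        yield dict(zip(scheme.criteria, combo))


def _merge_category(source: str, existing: object, new: object) -> object:
    """Resolve duplicate categorical annotations by highest award."""
    order = {cat: i for i, cat in enumerate(CATEGORY_VOCAB[source])}
    if existing == new:
        return existing
    warnings.warn(
        f"conflicting {source!r} categories {existing!r}/{new!r}; "
        "keeping the higher-scoring one",
        stacklevel=2,
    )
    return max((existing, new), key=lambda c: order[str(c)])


def observations_from_catalogs(
    accession: str,
    gene_symbol: str | None,
    catalogs: Sequence[AnnotationCatalog],
) -> dict[str, object]:
    """Collect the scoring observations for one protein from catalogs.

    Same-species sources are matched by accession, cross-species ones
    by uppercased gene symbol; both keys are tried against every
    catalog so either convention works.  Multiple catalogs may share a
    source (e.g. per-study NCL lists, or hLGDB and mLGDB both under
    ``lgdb``): membership in any of them counts, Compartments keeps
    the highest confidence, and conflicting layer-1 categories resolve
    to the higher-scoring one with a warning.
    """
    keys = {harmonize_id(accession)}
    if gene_symbol:
        keys.add(harmonize_id(gene_symbol))
    obs: dict[str, object] = {}
    for cat in catalogs:
        hit = None
        for k in keys:
            if k in cat.entries:
                hit = cat.entries[k]
                break
        if hit is None:
            continue
        src = cat.source
        if src in CATEGORY_VOCAB:
            obs[src] = _merge_category(src, obs[src], hit) if src in obs else hit
        elif src == "compartments":
            obs[src] = max(float(hit), float(obs.get(src, 0.0)))
        else:
            obs[src] = True
    return obs


@dataclass
class ScoringResults:
    """Scored table plus tier counts for a set of differential proteins."""

    table: pd.DataFrame  # accession, gene_symbol, per-criterion points, total, tier
    tier_counts: dict[str, int]
    scheme: ScoringScheme

    @property
    def retained(self) -> pd.DataFrame:
        """Proteins above the discard threshold (tiers MC ∪ HC ∪ vHC)."""
        return self.table[self.table["tier"] != TIER_LOW]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            "Lysosomal confidence scoring",
            "=" * 42,
            f"proteins scored       {n}",
            f"scheme maximum        {self.scheme.max_total}",
        ]
        for tier in reversed(TIER_ORDER):
            lines.append(f"tier {tier:<4} count       {self.tier_counts.get(tier, 0)}")
        retained = n - self.tier_counts.get(TIER_LOW, 0)
        frac = f" ({100 * retained / n:.1f}%)" if n else ""
        lines.append(f"retained (score ≥ 1)  {retained}{frac}")
        return "\n".join(lines)


def score_dataset(
    deps: Iterable,
    catalogs: Sequence[AnnotationCatalog],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ScoringResults:
    """Score every differential protein against the annotation catalogs.

    ``deps`` may be DEPRecord-like objects (with ``accession`` and
    ``gene_symbol`` attributes), ``(accession, gene_symbol)`` pairs, or
    bare accessions.  Returns the scored table and the tier counts,
    which partition the input.
    """
    rows = []
    tier_counts = {t: 0 for t in TIER_ORDER}
    for dep in deps:
        if hasattr(dep, "accession"):
            acc, gene = dep.accession, getattr(dep, "gene_symbol", None)
        elif isinstance(dep, (tuple, list)):
            acc, gene = dep[0], dep[1] if len(dep) > 1 else None
        else:
            acc, gene = str(dep), None
        obs = observations_from_catalogs(acc, gene, catalogs)
        card = score_protein(scheme, obs, accession=acc)
        tier_counts[card.tier] += 1
        row = {"accession": acc, "gene_symbol": gene}
        row.update({f"pts_{c}": card.points[c] for c in scheme.criteria})
        row["total"] = card.total
        row["tier"] = card.tier
        rows.append(row)
    cols = (
        ["accession", "gene_symbol"]
        + [f"pts_{c}" for c in scheme.criteria]
        + ["total", "tier"]
    )
    table = pd.DataFrame(rows, columns=cols)
    return ScoringResults(table=table, tier_counts=tier_counts, scheme=scheme)
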