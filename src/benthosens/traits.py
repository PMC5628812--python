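"""Biological-trait scoring, taxon aggregation and the trawl disturbance
indicator (TDI).

Five traits describe a benthic taxon's vulnerability to bottom-trawl
gear — position on/in the substratum, feeding mode, motility, adult
body size and physical fragility — each scored 0 (robust) to 3
(vulnerable). Their sum is the species sensitivity index SI (0-15).

Survey catches are aggregated to a common taxonomic level before
scoring: species collapse to genus, and a group is kept at the lowest
level (genus, family, order, class, division) at which it was observed
in at least ``min_years`` distinct years, pooling all surveys;
divisions failing the rule are dropped. Aggregated groups take the
per-trait maximum over their members (so no single vulnerable trait is
diluted) and are discarded as too heterogeneous when the trait-score
spread and the SI spread both exceed fixed thresholds (SD > 1.5 for
any trait and SD > 2.5 for SI).

The station-level TDI is the biomass-weighted mean SI of a haul's
catch. Biomasses are log(1+B)-transformed before forming proportions
(the raw-biomass variant is available via ``transform="none"``):

    TDI_x = sum_i  w_i * SI_i,   w_i = log1p(B_i) / sum_j log1p(B_j)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_NAMES",
    "TRAIT_SCHEME",
    "MAX_SI",
    "TraitRecord",
    "score_taxon",
    "max_sensitivity_index",
    "AggregationPlan",
    "aggregate_taxa",
    "group_homogeneity",
    "build_group_traits",
    "TDIResult",
    "station_tdi",
    "compute_tdi_table",
    "validate_catch_table",
    "LINEAGE_LEVELS",
    "REMOVED",
]

TRAIT_NAMES = ("position", "feeding", "motility", "size", "fragility")

#: Scoring scheme: trait -> {category label: score}. Note the gaps —
#: feeding has no score 2 and size no score 1; those are not typos but
#: the scheme's actual domains.
TRAIT_SCHEME: dict[str, dict[str, int]] = {
    "position": {
        "deep burrowing": 0,
        "surface burrowing": 1,
        "surface": 2,
        "emergent": 3,
    },
    "feeding": {
        "scavengers": 0,
        "deposit feeders/predators": 1,
        "filter feeders": 3,
    },
    "motility": {
        "highly mobile": 0,
        "mobile": 1,
        "sedentary": 2,
        "sessile": 3,
    },
    "size": {
        "small": 0,
        "medium": 2,
        "large": 3,
    },
    "fragility": {
        "hard shell": 0,
        "flexible": 1,
        "no protection": 2,
        "fragile": 3,
    },
}

TRAIT_DOMAINS: dict[str, frozenset[int]] = {
    t: frozenset(v.values()) for t, v in TRAIT_SCHEME.items()
}

MAX_SI = sum(max(v.values()) for v in TRAIT_SCHEME.values())

LINEAGE_LEVELS = ("genus", "family", "order", "class", "division")

REMOVED = "REMOVED"


def _normalise_label(label: str) -> str:
    return " ".join(label.strip().lower().split())


def _lookup_score(trait: str, label: str) -> int:
    table = TRAIT_SCHEME[trait]
    key = _normalise_label(label)
    # allow the verbose Table-2 style labels ("Sessile (attached)",
    # "Large > 10 cm", "Hard shell, burrow, vermiform, regeneration")
    for canon, score in table.items():
        if key == canon or key.startswith(canon):
            return score
    raise ValueError(
        f"unknown {trait} category {label!r}; valid: {sorted(table)}"
    )


@dataclass(frozen=True)
class TraitRecord:
    """A taxon's five trait scores; ``si`` is their sum (0-15)."""

    taxon_id: str
    position: int
    feeding: int
    motility: int
    size: int
    fragility: int

    def __post_init__(self) -> None:
        for trait in TRAIT_NAMES:
            score = getattr(self, trait)
            if score not in TRAIT_DOMAINS[trait]:
                raise ValueError(
                    f"{trait} score {score} outside its domain "
                    f"{sorted(TRAIT_DOMAINS[trait])}"
                )

    @property
    def si(self) -> int:
        return sum(getattr(self, t) for t in TRAIT_NAMES)

    def scores(self) -> tuple[int, ...]:
        return tuple(getattr(self, t) for t in TRAIT_NAMES)


def score_taxon(taxon_id: str, position: str, feeding: str, motility: str,
                size: str, fragility: str) -> TraitRecord:
    """Score a taxon from its five trait category labels."""
    return TraitRecord(
        taxon_id=taxon_id,
        position=_lookup_score("position", position),
        feeding=_lookup_score("feeding", feeding),
        motility=_lookup_score("motility", motility),
        size=_lookup_score("size", size),
        fragility=_lookup_score("fragility", fragility),
    )


def max_sensitivity_index() -> int:
    """Largest attainable SI: the sum of each trait's maximum score."""
    return MAX_SI


# ---------------------------------------------------------------------------
# Catch tables
# ---------------------------------------------------------------------------

CATCH_COLUMNS = ("station_id", "survey", "year", "taxon_id", "biomass")


def validate_catch_table(catch: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, non-negative biomass and per-haul uniqueness."""
    missing = set(CATCH_COLUMNS) - set(catch.columns)
    if missing:
        raise ValueError(f"catch table missing columns: {sorted(missing)}")
    if (catch["biomass"] < 0).any():
        raise ValueError("biomass must be >= 0")
    dup = catch.duplicated(subset=["station_id", "taxon_id"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (station, taxon) rows in catch table"
        )
    return catch


# ---------------------------------------------------------------------------
# Taxon aggregation (the >= min_years rule)
# ---------------------------------------------------------------------------


@dataclass
class AggregationPlan:
    """Outcome of the level-by-level aggregation walk.

    ``assignments`` maps every input taxon to its retained group label
    (or :data:`REMOVED`); ``group_level`` records the lineage level each
    group was retained at; ``audit`` is a human-readable trace.
    """

    assignments: dict[str, str]
    group_level: dict[str, str]
    audit: list[str] = field(default_factory=list)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for taxon, group in self.assignments.items():
            if group != REMOVED:
                out.setdefault(group, []).append(taxon)
        return out


def aggregate_taxa(catch: pd.DataFrame, taxonomy: pd.DataFrame,
                   min_years: int = 6) -> AggregationPlan:
    """Assign each taxon to the lowest taxonomic level spanning enough years.

    ``taxonomy`` maps ``taxon_id`` to its lineage (columns genus,
    family, order, class, division). For every taxon the walk starts at
    genus and climbs: the taxon is retained at the first level whose
    pooled records — all catch rows of taxa sharing that lineage value,
    all surveys pooled — cover at least ``min_years`` distinct calendar
    years. A taxon whose division still fails is removed.
    """
    validate_catch_table(catch)
    taxonomy = taxonomy.set_index("taxon_id") if "taxon_id" in taxonomy.columns \
        else taxonomy
    for level in LINEAGE_LEVELS:
        if level not in taxonomy.columns:
            raise ValueError(f"taxonomy table missing level {level!r}")
    taxa = sorted(catch["taxon_id"].unique())
    missing = [t for t in taxa if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from the lineage table: {missing[:5]}")

    years_by_taxon = catch.groupby("taxon_id")["year"].agg(set)
    # pooled distinct years per lineage value, per level
    pooled: dict[str, dict[str, set]] = {}
    for level in LINEAGE_LEVELS:
        level_of = taxonomy[level]
        acc: dict[str, set] = {}
        for taxon in taxa:
            acc.setdefault(level_of.loc[taxon], set()).update(
                years_by_taxon.loc[taxon])
        pooled[level] = acc

    assignments: dict[str, str] = {}
    group_level: dict[str, str] = {}
    audit: list[str] = []
    for taxon in taxa:
        placed = False
        for level in LINEAGE_LEVELS:
            group = taxonomy.loc[taxon, level]
            n_years = len(pooled[level][group])
            if n_years >= min_years:
                assignments[taxon] = group
                group_level[group] = level
                audit.append(
                    f"{taxon} -> {group} [{level}] ({n_years} years)")
                placed = True
                break
            audit.append(
                f"{taxon}: {group} [{level}] only {n_years} years, climbing")
        if not placed:
            assignments[taxon] = REMOVED
            audit.append(f"{taxon}: removed (division below {min_years} years)")
    return AggregationPlan(assignments=assignments, group_level=group_level,
                           audit=audit)


def group_homogeneity(members: list[TraitRecord], group_id: str = "",
                      sd_trait: float = 1.5, sd_si: float = 2.5,
                      mode: str = "and") -> TraitRecord | None:
    """Pool member trait records or reject the group as heterogeneous.

    Returns the group :class:`TraitRecord` (per-trait maximum over the
    members, SI recomputed from the pooled scores) or ``None`` when the
    group fails the homogeneity screen: any single trait's SD exceeds
    ``sd_trait`` *and* the SI SD exceeds ``sd_si`` (``mode="or"`` turns
    the conjunction into a disjunction for sensitivity analysis). A
    single member always passes.
    """
    if not members:
        raise ValueError("group has no members")
    if mode not in ("and", "or"):
        raise ValueError("mode must be 'and' or 'or'")
    if len(members) > 1:
        trait_sds = [float(np.std([getattr(m, t) for m in members], ddof=1))
                     for t in TRAIT_NAMES]
        si_sd = float(np.std([m.si for m in members], ddof=1))
        heterogeneous_trait = max(trait_sds) > sd_trait
        heterogeneous_si = si_sd > sd_si
        remove = (heterogeneous_trait and heterogeneous_si) if mode == "and" \
            else (heterogeneous_trait or heterogeneous_si)
        if remove:
            return None
    return TraitRecord(
        taxon_id=group_id or members[0].taxon_id,
        **{t: max(getattr(m, t) for m in members) for t in TRAIT_NAMES},
    )


def build_group_traits(plan: AggregationPlan,
                       species_traits: dict[str, TraitRecord],
                       sd_trait: float = 1.5, sd_si: float = 2.5,
                       mode: str = "and") -> dict[str, TraitRecord]:
    """Apply the homogeneity screen to every retained group of a plan.

    Members lacking a trait record are skipped (taxa with unknown traits
    are excluded from the indicator); groups failing the screen are
    absent from the result.
    """
    out: dict[str, TraitRecord] = {}
    for group, member_ids in sorted(plan.members().items()):
        records = [species_traits[t] for t in member_ids
                   if t in species_traits]
        if not records:
            continue
        pooled = group_homogeneity(records, group_id=group,
                                   sd_trait=sd_trait, sd_si=sd_si, mode=mode)
        if pooled is not None:
            out[group] = pooled
    return out


# ---------------------------------------------------------------------------
# Station TDI
# ---------------------------------------------------------------------------


@dataclass
class TDIResult:
    station_id: str
    tdi: float          # NaN when undefined (zero catch)
    n_taxa: int
    total_weight: float  # sum of transformed biomasses

    @property
    def defined(self) -> bool:
        return math.isfinite(self.tdi)


def _transform_biomass(biomass: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log1p":
        return np.log1p(biomass)
    if transform == "none":
        return biomass.astype(float)
    raise ValueError("transform must be 'log1p' or 'none'")


def station_tdi(haul: pd.DataFrame, si_by_taxon: dict[str, int],
                transform: str = "log1p",
                presence_only_biomass: float | None = None) -> TDIResult:
    """Biomass-weighted mean SI for one haul.

    ``haul`` holds the catch rows of a single station; every taxon must
    have an SI. Zero-biomass rows are presence-only records (colonial or
    encrusting organisms) and receive ``presence_only_biomass``
    (default: the smallest positive biomass in the haul). A haul whose
    transformed total biomass is zero yields an undefined (NaN) TDI,
    never zero.
    """
    station = str(haul["station_id"].iloc[0]) if len(haul) else ""
    unknown = set(haul["taxon_id"]) - set(si_by_taxon)
    if unknown:
        raise ValueError(f"no SI for taxa: {sorted(unknown)[:5]}")
    biomass = haul["biomass"].to_numpy(dtype=float)
    if np.any(biomass == 0):
        positive = biomass[biomass > 0]
        nominal = presence_only_biomass if presence_only_biomass is not None \
            else (float(positive.min()) if positive.size else 0.0)
        biomass = np.where(biomass == 0, nominal, biomass)
    w = _transform_biomass(biomass, transform)
    total = float(w.sum())
    if total <= 0:
        return TDIResult(station_id=station, tdi=float("nan"),
                         n_taxa=len(haul), total_weight=total)
    si = np.array([si_by_taxon[t] for t in haul["taxon_id"]], dtype=float)
    tdi = float((w / total) @ si)
    return TDIResult(station_id=station, tdi=tdi, n_taxa=len(haul),
                     total_weight=total)


def compute_tdi_table(catch: pd.DataFrame, plan: AggregationPlan,
                      group_traits: dict[str, TraitRecord],
                      transform: str = "log1p") -> pd.DataFrame:
    """Station TDI for every haul of a multi-station catch table.

    Rows of removed taxa and of groups dropped by the homogeneity screen
    are excluded; biomass of taxa mapped to one group is summed per haul
    before weighting. Returns a frame indexed by station with columns
    ``tdi``, ``n_taxa``, ``total_weight``.
    """
    validate_catch_table(catch)
    mapped = catch.assign(
        group=catch["taxon_id"].map(plan.assignments)
    )
    mapped = mapped[mapped["group"].isin(group_traits.keys())]
    pooled = (mapped.groupby(["station_id", "group"], as_index=False)
              ["biomass"].sum())
    si_by_group = {g: r.si for g, r in group_traits.items()}
    rows = []
    for station, haul in pooled.groupby("station_id"):
        haul = haul.rename(columns={"group": "taxon_id"})
        res = station_tdi(haul, si_by_group, transform=transform)
        rows.append((station, res.tdi, res.n_taxa, res.total_weight))
    return pd.DataFrame(rows, columns=["station_id", "tdi", "n_taxa",
                                       "total_weight"]).set_index("station_id")
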