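"""Family-level trait-table construction.

Builds the analysis table for the comparative models from three layers of
input records:

1. food-type nutrient examples (several example foods per food type),
2. species-level diet records (which food types adults and juveniles eat,
   plus the species' obligate-symbiont status),
3. family-level metadata (species richness, age, metabolism).

The nutrient pipeline is a five-step median cascade: per-food-type median
over example foods, standardization to amount per gram by the food type's
mean item weight, per-life-stage median over the foods a species eats
(omnivores average over all their foods instead), per-species median over
the two life stages, and finally a per-family median over species.
Medians with an even count use the mean of the two middle order
statistics throughout.

Downstream helpers cover sparse-nutrient masking (drop nutrients missing
in more than a threshold fraction of families), z-transformation, niche
classification from species records, and the binary discretizations the
transition-rate models need (obligate = more than half of sampled species
obligate; nutrient low/high splits at the 25% and 50% across-family
quantiles).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FoodTypeNutrients",
    "SpeciesDietRecord",
    "summarize_food_type",
    "standardize_per_gram",
    "species_profile",
    "family_profile",
    "mask_sparse_nutrients",
    "z_transform",
    "discretize_traits",
    "classify_family_niche",
    "build_family_table",
]

SPECIALIST_NICHES = ("phloem", "xylem", "wood", "blood", "predator", "fungivore")
NICHES = ("herbivore", "omnivore") + SPECIALIST_NICHES + ("other",)
OBLIGATE_STATUSES = ("obligate", "non_obligate", "unresolved")


class MissingFoodError(KeyError):
    pass


@dataclass
class FoodTypeNutrients:
    """Median nutrient profile of one food type across example foods."""

    food_type: str
    per_nutrient_amount: dict[str, float]
    item_weight: float
    n_examples: int

    def __post_init__(self):
        if self.n_examples < 1:
            raise ValueError("need at least one example food")
        if not self.item_weight > 0:
            raise ValueError(f"{self.food_type}: item weight must be positive")
        bad = {k: v for k, v in self.per_nutrient_amount.items()
               if np.isfinite(v) and v < 0}
        if bad:
            raise ValueError(f"{self.food_type}: negative amounts {bad}")


@dataclass
class SpeciesDietRecord:
    species: str
    family: str
    adult_foods: list[str]
    juvenile_foods: list[str]
    obligate_status: str = "non_obligate"
    omnivore: bool = False

    def __post_init__(self):
        if not (self.adult_foods or self.juvenile_foods):
            raise ValueError(f"{self.species}: no foods for either life stage")
        if self.obligate_status not in OBLIGATE_STATUSES:
            raise ValueError(f"bad status {self.obligate_status!r}")


def _median(values) -> float:
    """Median; even counts take the mean of the two middle order stats."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(arr) == 0:
        return float("nan")
    return float(np.median(arr))


def summarize_food_type(
    food_type: str, examples: list[dict[str, float]], weights: list[float]
) -> FoodTypeNutrients:
    """Per-nutrient median over example foods; mean item weight.

    ``examples`` maps nutrient name to amount per item for each example
    food; nutrients absent from an example simply do not contribute to
    that nutrient's median.
    """
    if not examples:
        raise MissingFoodError(f"no example foods for {food_type!r}")
    if len(weights) != len(examples):
        raise ValueError("one weight per example required")
    nutrients = sorted({k for ex in examples for k in ex})
    med = {nut: _median([ex[nut] for ex in examples if nut in ex])
           for nut in nutrients}
    return FoodTypeNutrients(
        food_type=food_type,
        per_nutrient_amount=med,
        item_weight=float(np.mean(weights)),
        n_examples=len(examples),
    )


def standardize_per_gram(food: FoodTypeNutrients) -> dict[str, float]:
    """Divide each nutrient amount by the food type's mean item weight."""
    if not food.item_weight > 0:
        raise ValueError(f"{food.food_type}: non-positive item weight")
    return {k: v / food.item_weight for k, v in food.per_nutrient_amount.items()}


def species_profile(
    record: SpeciesDietRecord,
    foods: dict[str, dict[str, float]],
) -> dict[str, float]:
    """Per-species nutrient profile.

    Per life stage: the median over that stage's food types, except for
    omnivorous species, which average over all their foods; the species
    value is the median of the adult and juvenile values.
    """
    for f in record.adult_foods + record.juvenile_foods:
        if f not in foods:
            raise MissingFoodError(
                f"{record.species}: unknown food type {f!r}"
            )
    nutrients = sorted({k for f in set(record.adult_foods + record.juvenile_foods)
                        for k in foods[f]})

    def stage_value(stage_foods: list[str], nut: str) -> float:
        vals = [foods[f][nut] for f in stage_foods if nut in foods[f]]
        if not vals:
            return float("nan")
        if record.omnivore:
            return float(np.mean(vals))
        return _median(vals)

    out = {}
    for nut in nutrients:
        stage_vals = []
        for stage in (record.adult_foods, record.juvenile_foods):
            if stage:
                stage_vals.append(stage_value(stage, nut))
        out[nut] = _median(stage_vals)
    return out


def family_profile(species_profiles: list[dict[str, float]]) -> dict[str, float]:
    """Per-nutrient median over species; all-missing nutrients become NaN."""
    if not species_profiles:
        raise ValueError("no species profiles")
    nutrients = sorted({k for p in species_profiles for k in p})
    return {nut: _median([p[nut] for p in species_profiles if nut in p])
            for nut in nutrients}


def mask_sparse_nutrients(
    table: pd.DataFrame, nutrient_cols: list[str], threshold: float = 0.30
) -> tuple[list[str], list[str]]:
    """Split nutrients into (kept, dropped) by family-level missingness.

    A nutrient is dropped when its fraction of missing families strictly
    exceeds ``threshold`` (a nutrient missing in exactly 30% of families
    is retained under the default).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    kept, dropped = [], []
    for c in nutrient_cols:
        frac = float(table[c].isna().mean())
        (dropped if frac > threshold else kept).append(c)
    if dropped:
        log.info("dropping sparse nutrients (> %.0f%% missing): %s",
                 100 * threshold, dropped)
    return kept, dropped


def z_transform(values: pd.Series | np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 over non-missing entries (sample sd)."""
    x = np.asarray(values, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = float(np.std(x[obs], ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot z-transform")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - x[obs].mean()) / sd
    return out


def discretize_traits(
    table: pd.DataFrame,
    nutrient_cols: list[str],
    obligate_threshold: float = 0.5,
    quantiles: tuple[float, ...] = (0.25, 0.50),
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Binary codings for the transition-rate models.

    - ``obligate``: 1 iff n_obligate / n_sampled strictly exceeds the
      threshold (default one half).
    - ``<nutrient>_low_q<pct>``: 1 iff the family's value is at or below
      the given across-family quantile (values exactly at the cut count
      as low).  Both the 25% and 50% splits are emitted by default.

    Families with ``n_sampled == 0`` are excluded (with a warning).
    """
    tab = table.copy()
    zero = tab["n_sampled"] <= 0
    if zero.any():
        log.warning("excluding %d families with no sampled species",
                    int(zero.sum()))
        tab = tab[~zero].copy()
    prop = tab["n_obligate"] / tab["n_sampled"]
    out = pd.DataFrame({"family": tab["family"].to_numpy()})
    out["prop_obligate"] = prop.to_numpy()
    out["obligate"] = (prop > obligate_threshold).astype(int).to_numpy()
    for c in nutrient_cols:
        x = tab[c].to_numpy(dtype=float)
        obs = np.isfinite(x)
        for qq in quantiles:
            cut = float(np.quantile(x[obs], qq, method=quantile_method))
            col = np.where(obs, (x <= cut).astype(float), np.nan)
            out[f"{c}_low_q{int(round(qq * 100))}"] = col
    return out


def classify_family_niche(
    species_niches: list[str],
    specialist_majority: float = 0.5,
) -> str:
    """Family feeding niche from its species' niches.

    Omnivore if any species is omnivorous (plant plus animal/detritus
    feeding); a specialist niche (phloem, xylem, wood, blood, predator,
    fungivore) only when most species - strictly more than
    ``specialist_majority`` of classified species - feed exclusively
    there; herbivore when plant-feeding dominates; otherwise "other".
    """
    known = [s for s in species_niches if s in NICHES]
    if not known:
        return "other"
    if any(s == "omnivore" for s in known):
        return "omnivore"
    counts = pd.Series(known).value_counts()
    top, frac = counts.index[0], counts.iloc[0] / len(known)
    if top in SPECIALIST_NICHES:
        return top if frac > specialist_majority else "omnivore"
    return top


@dataclass
class FamilyTableResult:
    table: pd.DataFrame
    dropped_nutrients: list[str]
    provenance: dict

    def write(self, csv_path, sidecar_path=None) -> None:
        self.table.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2)


def build_family_table(
    foods_df: pd.DataFrame,
    species_df: pd.DataFrame,
    families_df: pd.DataFrame,
    missingness_threshold: float = 0.30,
    z_scores: bool = True,
) -> FamilyTableResult:
    """Run the full five-step construction from raw CSV-shaped frames.

    ``foods_df``: columns food_type, example, weight_g, then one column
    per nutrient (amount per item).
    ``species_df``: species, family, adult_foods, juvenile_foods
    (semicolon-separated food types), omnivore (0/1), obligate_status,
    niche (optional species feeding niche).
    ``families_df``: family, species_richness, family_age, metabolism.
    """
    nutrient_cols = [c for c in foods_df.columns
                     if c not in ("food_type", "example", "weight_g")]
    # steps 2-3: median across example foods, then per-gram standardization
    per_gram: dict[str, dict[str, float]] = {}
    for ft, grp in foods_df.groupby("food_type"):
        examples = [
            {n: row[n] for n in nutrient_cols if np.isfinite(row[n])}
            for _, row in grp.iterrows()
        ]
        summary = summarize_food_type(ft, examples, grp["weight_g"].tolist())
        per_gram[ft] = standardize_per_gram(summary)

    # step 4: species profiles; unresolved species drop out of the
    # obligate proportion but still contribute diet information
    fam_profiles: dict[str, list[dict[str, float]]] = {}
    fam_counts: dict[str, list[int]] = {}
    fam_niches: dict[str, list[str]] = {}
    for _, row in species_df.iterrows():
        rec = SpeciesDietRecord(
            species=row["species"],
            family=row["family"],
            adult_foods=_split(row.get("adult_foods", "")),
            juvenile_foods=_split(row.get("juvenile_foods", "")),
            obligate_status=row.get("obligate_status", "non_obligate"),
            omnivore=bool(row.get("omnivore", 0)),
        )
        prof = species_profile(rec, per_gram)
        fam_profiles.setdefault(rec.family, []).append(prof)
        if rec.obligate_status != "unresolved":
            fam_counts.setdefault(rec.family, []).append(
                1 if rec.obligate_status == "obligate" else 0
            )
        niche = row.get("niche")
        if isinstance(niche, str) and niche:
            fam_niches.setdefault(rec.family, []).append(
                "omnivore" if rec.omnivore else niche
            )

    # step 5: family profiles + assembly
    rows = []
    for _, frow in families_df.iterrows():
        fam = frow["family"]
        profs = fam_profiles.get(fam, [])
        nut = family_profile(profs) if profs else {}
        counts = fam_counts.get(fam, [])
        rows.append({
            "family": fam,
            "n_sampled": len(counts),
            "n_obligate": int(sum(counts)),
            "feeding_niche": classify_family_niche(fam_niches.get(fam, [])),
            "species_richness": frow.get("species_richness", np.nan),
            "family_age": frow.get("family_age", np.nan),
            "metabolism": frow.get("metabolism", ""),
            **{n: nut.get(n, np.nan) for n in nutrient_cols},
        })
    table = pd.DataFrame(rows)
    kept, dropped = mask_sparse_nutrients(table, nutrient_cols,
                                          missingness_threshold)
    table = table.drop(columns=dropped)
    if z_scores:
        for c in kept:
            if table[c].notna().sum() >= 2 and table[c].std(skipna=True) > 0:
                table[f"z_{c}"] = z_transform(table[c])
    provenance = {
        "missingness_threshold": missingness_threshold,
        "quantile_method": "linear",
        "dropped_nutrients": dropped,
        "kept_nutrients": kept,
        "n_families": len(table),
        "z_transformed": z_scores,
    }
    return FamilyTableResult(table, dropped, provenance)


def _split(x) -> list[str]:
    if not isinstance(x, str) or not x.strip():
        return []
    return [s.strip() for s in x.split(";") if s.strip()]


def validate_inputs(
    foods_df: pd.DataFrame, species_df: pd.DataFrame, families_df: pd.DataFrame
) -> list[dict]:
    """Schema check; returns one record per violation (row, column, message)."""
    problems = []

    def need(df, cols, name):
        for c in cols:
            if c not in df.columns:
                problems.append({"table": name, "row": None, "column": c,
                                 "message": "missing column"})

    need(foods_df, ["food_type", "example", "weight_g"], "foods")
    need(species_df, ["species", "family"], "species")
    need(families_df, ["family"], "families")
    if "weight_g" in foods_df.columns:
        bad = foods_df.index[~(foods_df["weight_g"] > 0)]
        for i in bad:
            problems.append({"table": "foods", "row": int(i),
                             "column": "weight_g",
                             "message": "non-positive weight"})
    if {"n_sampled", "n_obligate"} <= set(families_df.columns):
        bad = families_df.index[
            families_df["n_obligate"] > families_df["n_sampled"]]
        for i in bad:
            problems.append({"table": "families", "row": int(i),
                             "column": "n_obligate",
                             "message": "more obligate than sampled"})
    return problems
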