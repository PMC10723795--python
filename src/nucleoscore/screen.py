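"""Plate-level aggregation, vehicle normalization, hit calling, enrichment.

The screening readout is the per-cell normality score. Scores are averaged
field-wise, then well-wise ("averages of all fields were calculated for each
well"); well scores are normalized to the vehicle (DMSO) mean; and a
compound is called a hit at a concentration when its well score falls more
than ``k`` vehicle standard deviations below the vehicle mean (k = 2 by
default, one-sided: stress only lowers the score). Hits are categorized by
the concentrations at which they fire, and target-class enrichment among
hits is assessed with the hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellSummary",
    "HitCall",
    "EnrichmentResult",
    "aggregate_wells",
    "vehicle_stats",
    "call_hits",
    "hit_category",
    "target_enrichment",
    "hit_percentages",
]


@dataclass
class WellSummary:
    well_id: str
    compound_id: str
    concentration_um: float
    mean_score: float
    cell_count: int
    n_fields: int
    n_unscored_cells: int = 0
    normalized_score: float = np.nan
    normalized_cell_count: float = np.nan
    is_vehicle: bool = False


@dataclass
class HitCall:
    compound_id: str
    hit_at: frozenset
    category: str
    z_like_deviation: dict[float, float]


@dataclass
class EnrichmentResult:
    target_class: str
    n_library: int
    n_hits: int
    fold_enrichment: float
    p_value: float
    significant: bool


def aggregate_wells(
    per_cell: pd.DataFrame,
    layout: pd.DataFrame,
    *,
    score_column: str = "normality_score",
) -> pd.DataFrame:
    """Two-stage aggregation: per-field means, then per-well means.

    ``per_cell`` needs columns ``well_id, field_id`` and the score column
    (NaN = unscored cell, counted in QC, excluded from means). ``layout``
    maps every imaged well to ``compound_id, concentration_uM, is_vehicle``.
    Fields with zero scored cells are excluded from the well mean and the
    ``n_fields`` count. Normalized columns divide by the vehicle-group mean.
    """
    layout = layout.copy()
    missing = set(per_cell["well_id"].unique()) - set(layout["well_id"])
    if missing:
        raise ValueError(f"wells present in images but absent from layout: {sorted(missing)[:5]}")
    by_field = per_cell.groupby(["well_id", "field_id"])[score_column].agg(["mean", "count"])
    scored_fields = by_field[by_field["count"] > 0]
    per_well_mean = scored_fields.groupby("well_id")["mean"].mean()
    n_fields = scored_fields.groupby("well_id").size()
    scored = per_cell[score_column].notna()
    cell_count = per_cell[scored].groupby("well_id").size()
    unscored = per_cell[~scored].groupby("well_id").size()
    all_wells = per_cell["well_id"].unique()
    wells = pd.DataFrame(
        {
            "well_id": all_wells,
            "mean_score": per_well_mean.reindex(all_wells).to_numpy(),
            "cell_count": cell_count.reindex(all_wells).fillna(0).astype(int).to_numpy(),
            "n_fields": n_fields.reindex(all_wells).fillna(0).astype(int).to_numpy(),
            "n_unscored_cells": unscored.reindex(all_wells).fillna(0).astype(int).to_numpy(),
        }
    )
    wells = wells.merge(
        layout[["well_id", "compound_id", "concentration_uM", "is_vehicle"]],
        on="well_id",
        how="left",
    )
    vehicle = wells[wells["is_vehicle"].astype(bool)]
    if not vehicle.empty:
        score_baseline = vehicle["mean_score"].mean()
        count_baseline = vehicle["cell_count"].mean()
        wells["normalized_score"] = wells["mean_score"] / score_baseline
        wells["normalized_cell_count"] = wells["cell_count"] / count_baseline
    else:
        wells["normalized_score"] = np.nan
        wells["normalized_cell_count"] = np.nan
    return wells


def vehicle_stats(
    wells: pd.DataFrame,
    *,
    score_column: str = "mean_score",
    pool: str = "all_plates",
    plate_column: str = "plate_id",
) -> tuple[float, float] | pd.DataFrame:
    """Sample mean and SD (n-1 denominator) of vehicle well scores.

    ``pool="all_plates"`` (default) pools every vehicle well into one pair
    of statistics — vehicle controls are treated as consistent from plate to
    plate. ``pool="per_plate"`` returns a per-plate table for robustness
    checks.
    """
    vehicle = wells[wells["is_vehicle"].astype(bool)] if "is_vehicle" in wells else wells
    scores = vehicle[score_column].dropna()
    if pool == "per_plate":
        if plate_column not in vehicle.columns:
            raise ValueError(f"per-plate pooling requires a {plate_column!r} column")
        out = (
            vehicle.groupby(plate_column)[score_column]
            .agg(["mean", lambda s: s.std(ddof=1), "count"])
            .reset_index()
        )
        out.columns = [plate_column, "mean", "sd", "n_wells"]
        if (out["n_wells"] < 2).any():
            raise ValueError("each plate needs at least 2 vehicle wells")
        return out
    if pool != "all_plates":
        raise ValueError("pool must be 'all_plates' or 'per_plate'")
    if len(scores) < 2:
        raise ValueError("vehicle statistics require at least 2 vehicle wells")
    return float(scores.mean()), float(scores.std(ddof=1))


def hit_category(hit_at: frozenset) -> str:
    """Map the set of hit concentrations to the screen's categories."""
    if {1.0, 10.0} <= hit_at:
        return "both"
    if 10.0 in hit_at:
        return "10_only"
    if 1.0 in hit_at:
        return "1_only"
    return "none"


def call_hits(
    wells: pd.DataFrame,
    vehicle_mean: float,
    vehicle_sd: float,
    *,
    k: float = 2.0,
    direction: str = "below",
    score_column: str = "mean_score",
) -> list[HitCall]:
    """Call hits at ``k`` vehicle SDs from the vehicle mean.

    ``direction="below"`` (default): hit iff score < mean - k*SD — in the
    screen all hits had scores *lower* than control. ``"two_sided"``:
    hit iff |score - mean| > k*SD. The call is invariant under any common
    affine rescaling of scores and vehicle statistics.
    """
    if vehicle_sd <= 0:
        raise ValueError("vehicle SD must be positive for hit calling")
    if direction not in ("below", "two_sided"):
        raise ValueError("direction must be 'below' or 'two_sided'")
    treated = wells[~wells["is_vehicle"].astype(bool)] if "is_vehicle" in wells else wells
    calls: list[HitCall] = []
    for compound_id, group in treated.groupby("compound_id", sort=False):
        hit_at = set()
        deviations: dict[float, float] = {}
        for _, row in group.iterrows():
            score = row[score_column]
            conc = float(row["concentration_uM"])
            deviation = (score - vehicle_mean) / vehicle_sd
            deviations[conc] = float(deviation)
            if np.isnan(score):
                continue
            if direction == "below":
                is_hit = score < vehicle_mean - k * vehicle_sd
            else:
                is_hit = abs(score - vehicle_mean) > k * vehicle_sd
            if is_hit:
                hit_at.add(conc)
        hit_at = frozenset(hit_at)
        calls.append(
            HitCall(
                compound_id=str(compound_id),
                hit_at=hit_at,
                category=hit_category(hit_at),
                z_like_deviation=deviations,
            )
        )
    return calls


def target_enrichment(
    hit_compounds: list[str],
    library_annotation: pd.DataFrame,
    *,
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Target-class enrichment among hits vs the library (hypergeometric).

    ``library_annotation`` has columns ``compound_id, target_class`` covering
    the whole library. For each class with K library members, the p-value is
    the probability of drawing >= k class members when sampling n hits
    without replacement from the M-compound library:
    ``hypergeom.sf(k - 1, M, K, n)``. Fold enrichment is
    ``(k/n) / (K/M)``. Raw p-values are reported by default; a
    Benjamini-Hochberg flag exists but is off, matching raw-tier reporting.
    """
    annotation = library_annotation.drop_duplicates("compound_id")
    class_of = dict(zip(annotation["compound_id"], annotation["target_class"]))
    unannotated = [c for c in hit_compounds if c not in class_of]
    if unannotated:
        raise ValueError(f"hit compounds missing annotation: {unannotated[:5]}")
    total_library = len(annotation)
    total_hits = len(hit_compounds)
    library_counts = annotation["target_class"].value_counts()
    hit_counts = pd.Series([class_of[c] for c in hit_compounds]).value_counts()
    rows = []
    for target_class, n_library in library_counts.items():
        n_hits = int(hit_counts.get(target_class, 0))
        if total_hits > 0:
            fold = (n_hits / total_hits) / (n_library / total_library)
            p = float(stats.hypergeom.sf(n_hits - 1, total_library, n_library, total_hits))
        else:
            fold, p = 0.0, 1.0
        rows.append(
            {
                "target_class": target_class,
                "n_library": int(n_library),
                "n_hits": n_hits,
                "fold_enrichment": fold,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if correction and not out.empty:
        from statsmodels.stats.multitest import multipletests  # optional path

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value", ignore_index=True)


def hit_percentages(n_both: int, n_high_only: int, n_library: int) -> dict[str, float]:
    """Percent of the library hitting at both concentrations, at the high
    concentration only, and in total (either category)."""
    if n_library <= 0:
        raise ValueError("library size must be positive")
    pct_both = 100.0 * n_both / n_library
    pct_high = 100.0 * n_high_only / n_library
    return {
        "pct_both": pct_both,
        "pct_high_only": pct_high,
        "pct_total": pct_both + pct_high,
    }
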