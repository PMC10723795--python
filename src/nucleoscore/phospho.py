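"""Phosphosite spectral-count filtering and abundance classification.

These are the tabular derivation rules applied downstream of a MudPIT /
QPROT analysis — the mass-spectrometry search itself is an input, not a
computation. Records carry per-replicate spectral counts for phosphosites
in untreated and drug-treated samples, plus per-drug protein-abundance
log-fold-changes and FDRs.

Rules implemented:

* protein abundance classification: *enriched* iff LogFC > 1.5 and
  FDR < 0.05; *depleted* iff LogFC < -1.5 and FDR < 0.05; else *unchanged*;
* phosphosite spectral-count ratio untreated/treated, with 0 replaced by
  0.1 on either side to avoid dividing by zero (a record with both totals
  zero is dropped with a notice);
* site filtering: sites on proteins whose abundance significantly
  *decreased* (FDR < 1e-4, negative LogFC) under any listed drug are
  removed, as are sites where any single untreated replicate has fewer
  than two spectral counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhosphoSiteRecord",
    "classify_abundance",
    "spectra_ratio",
    "filter_decreased_sites",
]

ZERO_REPLACEMENT = 0.1
ABUNDANCE_LOGFC_THRESHOLD = 1.5
ABUNDANCE_FDR_THRESHOLD = 0.05
DECREASE_FDR_THRESHOLD = 1e-4
MIN_UNTREATED_SPECTRA = 2


@dataclass
class PhosphoSiteRecord:
    """One protein phosphosite with replicate spectral counts."""

    protein_id: str
    site: str  # residue + position, e.g. "S123"
    spectra_untreated: tuple[int, ...]
    spectra_treated: dict[str, tuple[int, ...]]  # drug -> per-replicate counts
    is_nucleolar: bool = False
    protein_logfc: dict[str, float] = field(default_factory=dict)  # per drug
    protein_fdr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for counts in (self.spectra_untreated, *self.spectra_treated.values()):
            for c in counts:
                if c < 0 or int(c) != c:
                    raise ValueError("spectral counts must be non-negative integers")


def classify_abundance(logfc: float, fdr: float) -> str:
    """Classify a protein's abundance change: enriched / depleted / unchanged."""
    if not 0 <= fdr <= 1:
        raise ValueError("fdr must lie in [0, 1]")
    if fdr < ABUNDANCE_FDR_THRESHOLD:
        if logfc > ABUNDANCE_LOGFC_THRESHOLD:
            return "enriched"
        if logfc < -ABUNDANCE_LOGFC_THRESHOLD:
            return "depleted"
    return "unchanged"


def spectra_ratio(untreated_total: float, treated_total: float) -> float:
    """Untreated/treated spectral-count ratio with symmetric 0 -> 0.1 replacement.

    Returns NaN when both totals are zero (the record carries no evidence
    and should be dropped by the caller).
    """
    if untreated_total < 0 or treated_total < 0:
        raise ValueError("spectral counts must be non-negative")
    if untreated_total == 0 and treated_total == 0:
        return float("nan")
    numerator = untreated_total if untreated_total > 0 else ZERO_REPLACEMENT
    denominator = treated_total if treated_total > 0 else ZERO_REPLACEMENT
    return numerator / denominator


def filter_decreased_sites(
    records: list[PhosphoSiteRecord] | pd.DataFrame,
    drugs: list[str],
    *,
    untreated_rule: str = "per_replicate",
    decrease_rule: str = "any_drug",
) -> pd.DataFrame:
    """Apply the site filters and derive per-drug spectral-count ratios.

    Parameters
    ----------
    records
        Either :class:`PhosphoSiteRecord` objects or a table with columns
        ``protein_id, site, is_nucleolar``, ``untreated_<i>`` per replicate,
        and per drug ``<drug>_<i>`` (replicate counts), ``<drug>_logfc``,
        ``<drug>_fdr``.
    drugs
        Drug names whose columns/entries must be present.
    untreated_rule
        ``"per_replicate"`` (default, strict): every untreated replicate
        must have >= 2 spectra. ``"total"``: the summed untreated count
        must be >= 2.
    decrease_rule
        ``"any_drug"`` (default): exclude a site when its protein shows a
        significant abundance decrease under any listed drug.
        ``"per_drug"``: keep the site but blank the ratio only for the
        affected drug.

    Returns
    -------
    DataFrame with one row per surviving site: identifiers, per-drug ratios
    ``ratio_<drug>``, the nucleolar flag, and ``decreased_in_all`` marking
    sites with ratio > 1 under every listed drug. Rows removed by each rule
    are reflected in the ``excluded_*`` attrs counters.
    """
    if untreated_rule not in ("per_replicate", "total"):
        raise ValueError("untreated_rule must be 'per_replicate' or 'total'")
    if decrease_rule not in ("any_drug", "per_drug"):
        raise ValueError("decrease_rule must be 'any_drug' or 'per_drug'")
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records, drugs)
    for record in records:
        for drug in drugs:
            if drug not in record.spectra_treated:
                raise ValueError(f"{record.protein_id} {record.site}: missing counts for {drug!r}")
            if drug not in record.protein_fdr or drug not in record.protein_logfc:
                raise ValueError(
                    f"{record.protein_id} {record.site}: missing abundance stats for {drug!r}"
                )

    n_excluded_counts = 0
    n_excluded_decrease = 0
    n_excluded_empty = 0
    rows = []
    for record in records:
        untreated = record.spectra_untreated
        if untreated_rule == "per_replicate":
            low_counts = any(c < MIN_UNTREATED_SPECTRA for c in untreated)
        else:
            low_counts = sum(untreated) < MIN_UNTREATED_SPECTRA
        if low_counts:
            n_excluded_counts += 1
            continue
        decreased = {
            drug: (
                record.protein_fdr[drug] < DECREASE_FDR_THRESHOLD
                and record.protein_logfc[drug] < 0
            )
            for drug in drugs
        }
        if decrease_rule == "any_drug" and any(decreased.values()):
            n_excluded_decrease += 1
            continue
        untreated_total = sum(untreated)
        ratios = {}
        dropped = False
        for drug in drugs:
            if decrease_rule == "per_drug" and decreased[drug]:
                ratios[drug] = float("nan")
                continue
            treated_total = sum(record.spectra_treated[drug])
            ratio = spectra_ratio(untreated_total, treated_total)
            if np.isnan(ratio):
                dropped = True
                break
            ratios[drug] = ratio
        if dropped:
            n_excluded_empty += 1
            continue
        finite = [r for r in ratios.values() if np.isfinite(r)]
        rows.append(
            {
                "protein_id": record.protein_id,
                "site": record.site,
                "is_nucleolar": record.is_nucleolar,
                **{f"ratio_{drug}": ratios[drug] for drug in drugs},
                "decreased_in_all": bool(finite) and all(r > 1 for r in finite),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "site", "is_nucleolar"]
        + [f"ratio_{d}" for d in drugs]
        + ["decreased_in_all"],
    )
    out.attrs["excluded_low_untreated_counts"] = n_excluded_counts
    out.attrs["excluded_protein_decrease"] = n_excluded_decrease
    out.attrs["excluded_no_spectra"] = n_excluded_empty
    return out


def _records_from_frame(frame: pd.DataFrame, drugs: list[str]) -> list[PhosphoSiteRecord]:
    untreated_cols = sorted(
        c for c in frame.columns if c.startswith("untreated_") and c.split("_")[-1].isdigit()
    )
    if not untreated_cols:
        raise ValueError("table needs untreated_<i> replicate columns")
    records = []
    for _, row in frame.iterrows():
        treated = {}
        logfc = {}
        fdr = {}
        for drug in drugs:
            reps = sorted(
                c
                for c in frame.columns
                if c.startswith(f"{drug}_") and c.split("_")[-1].isdigit()
            )
            if not reps:
                raise ValueError(f"table missing replicate columns for drug {drug!r}")
            treated[drug] = tuple(int(row[c]) for c in reps)
            logfc[drug] = float(row[f"{drug}_logfc"])
            fdr[drug] = float(row[f"{drug}_fdr"])
        records.append(
            PhosphoSiteRecord(
                protein_id=str(row["protein_id"]),
                site=str(row["site"]),
                spectra_untreated=tuple(int(row[c]) for c in untreated_cols),
                spectra_treated=treated,
                is_nucleolar=bool(row.get("is_nucleolar", False)),
                protein_logfc=logfc,
                protein_fdr=fdr,
            )
        )
    return records
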