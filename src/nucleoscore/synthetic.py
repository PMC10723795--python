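"""Ground-truthed synthetic images, plates, and FRAP traces.

The generator renders the four nucleolar-stress phenotypes as simple
geometric fields so every analysis stage can be tested without microscope
data:

* ``normal`` — nuclei with 1-4 round nucleoli; the fibrillar-center (FC)
  marker fills the nucleolar cores, the granular-component (GC) marker
  co-localizes with them, and only a small GC fraction is nucleoplasmic.
* ``canonical_stress`` — shrunken round nucleolar remnants with the FC
  marker condensed into small peripheral stress caps (a fraction of the
  diffuse nucleoplasmic FC pool relocates into the caps, raising the FC
  nucleolar/nucleoplasmic ratio) and about half of the GC pool dispersed.
* ``metabolic`` — shrunken but otherwise normally organized nucleoli with
  a mildly increased GC nucleoplasmic fraction.
* ``dissolution`` — the FC marker decompacted into thin curvilinear
  strings (random-walk polylines dilated to ~2 px width) and the GC pool
  almost fully dispersed into the nucleoplasm.

Each synthetic field carries its ground truth: nucleus and nucleolus label
masks, and per-cell noiseless compartment intensity sums computed directly
from the generator's own arrays and masks (so conservation is exact by
construction), together with the analytic normality score.

Noise model: Poisson photon noise on the noiseless signal plus additive
Gaussian read noise — the standard fluorescence-camera model. Identical
parameters (including the seed) produce bit-identical fields.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frap import FRAPTrace, half_time_of_model
from .io import ImageField
from .segmentation import LabelMask, SegmentationParams

__all__ = [
    "PhenotypeParams",
    "SyntheticField",
    "generate_field",
    "generate_plate",
    "generate_frap_trace",
    "two_exp_params_for_half_time",
    "default_analysis_params",
    "write_field_set",
    "PHENOTYPES",
]

PHENOTYPES = ("normal", "canonical_stress", "metabolic", "dissolution")

#: per-phenotype default GC dispersal fraction f (fraction of the GC pool
#: relocated from nucleoli to nucleoplasm) and nucleolus radius in px
_PHENOTYPE_DEFAULTS = {
    "normal": {"gc_dispersal_frac": 0.05, "nucleolus_radius_px": 5.0},
    "canonical_stress": {"gc_dispersal_frac": 0.50, "nucleolus_radius_px": 4.0},
    "metabolic": {"gc_dispersal_frac": 0.15, "nucleolus_radius_px": 3.0},
    "dissolution": {"gc_dispersal_frac": 0.95, "nucleolus_radius_px": 5.0},
}


@dataclass
class PhenotypeParams:
    """Geometry, intensity pools, and noise of one synthetic field.

    Intensity pools are per-nucleus integrated intensities (arbitrary
    units): ``fc_pool`` is the structural FC signal, ``fc_nucleoplasm_pool``
    the diffuse FC pool, ``gc_pool`` the total GC signal of which the
    fraction ``gc_dispersal_frac`` sits in the nucleoplasm.
    """

    phenotype: str = "normal"
    field_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 5
    nucleus_radius_px: float = 22.0
    nucleus_radius_jitter: float = 2.0
    nucleoli_per_nucleus: tuple[int, int] = (2, 3)
    nucleolus_radius_px: float | None = None
    gc_dispersal_frac: float | None = None
    fc_condensation: float = 0.4
    fc_string_length: int = 45
    dna_gain: float = 150.0
    gc_pool: float = 2.0e5
    fc_pool: float = 1.0e5
    fc_nucleoplasm_pool: float = 2.0e4
    poisson_scale: float = 1.0
    gauss_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}; use one of {PHENOTYPES}")
        defaults = _PHENOTYPE_DEFAULTS[self.phenotype]
        if self.gc_dispersal_frac is None:
            self.gc_dispersal_frac = defaults["gc_dispersal_frac"]
        if self.nucleolus_radius_px is None:
            self.nucleolus_radius_px = defaults["nucleolus_radius_px"]
        if not 0.0 <= self.gc_dispersal_frac <= 1.0:
            raise ValueError("gc_dispersal_frac must lie in [0, 1]")
        for name in ("nucleus_radius_px", "nucleolus_radius_px", "dna_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fc_condensation <= 1.0:
            raise ValueError("fc_condensation must lie in [0, 1]")


@dataclass
class SyntheticField:
    """A generated field with its complete ground truth."""

    field: ImageField  # noisy channels: dapi, fc, gc
    noiseless: ImageField
    nuclei: LabelMask
    nucleoli: LabelMask
    truth: pd.DataFrame  # per-cell noiseless compartment sums + analytic score
    params: PhenotypeParams


def default_analysis_params() -> SegmentationParams:
    """Segmentation parameters matched to the synthetic geometry.

    The marker-channel rolling-ball radius is chosen large relative to the
    synthetic nuclei so the flat diffuse nucleoplasmic pools survive
    background subtraction; on real data the radius is scaled to the
    imaging magnification instead.
    """
    return SegmentationParams(
        nucleus_bg_radius=50.0,
        nucleolus_bg_radius=400.0,
        nucleus_area_range_px=(300, 30000),
    )


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_nuclei(params: PhenotypeParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus centers away from borders."""
    h, w = params.field_shape
    placed: list[tuple[float, float, float]] = []
    for _ in range(5000):
        if len(placed) == params.n_nuclei:
            break
        r = params.nucleus_radius_px + rng.uniform(
            -params.nucleus_radius_jitter, params.nucleus_radius_jitter
        )
        margin = r + 4
        if 2 * margin >= min(h, w):
            raise ValueError("nucleus radius too large for the field")
        row = rng.uniform(margin, h - margin)
        col = rng.uniform(margin, w - margin)
        if all(
            math.hypot(row - pr, col - pc) >= r + prr + 6 for pr, pc, prr in placed
        ):
            placed.append((row, col, r))
    if len(placed) < params.n_nuclei:
        raise ValueError("could not place all nuclei without overlap")
    return placed


def _place_nucleoli(center, nucleus_r, n, nucleolus_r, rng):
    # keep nucleoli fully interior; drop to fewer nucleoli if the nucleus
    # cannot geometrically hold the requested count
    max_rad = min(0.65 * nucleus_r, nucleus_r - nucleolus_r - 3)
    if max_rad <= 0:
        raise ValueError("nucleolus radius too large for the nucleus")
    placed: list[tuple[float, float]] = []
    for _ in range(4000):
        if len(placed) == n:
            break
        rad = rng.uniform(0, max_rad)
        theta = rng.uniform(0, 2 * math.pi)
        row = center[0] + rad * math.sin(theta)
        col = center[1] + rad * math.cos(theta)
        if all(
            math.hypot(row - pr, col - pc) >= 2 * nucleolus_r + 3 for pr, pc in placed
        ):
            placed.append((row, col))
    if not placed:
        raise ValueError("could not place any nucleolus inside the nucleus")
    return placed


def _string_mask(shape, center, nucleus_r, length, rng):
    """Random-walk polyline dilated to ~2 px width, kept inside the nucleus."""
    from scipy import ndimage as ndi

    path = np.zeros(shape, dtype=bool)
    row = center[0] + rng.uniform(-0.3, 0.3) * nucleus_r
    col = center[1] + rng.uniform(-0.3, 0.3) * nucleus_r
    heading = rng.uniform(0, 2 * math.pi)
    for _ in range(length):
        path[int(round(row)), int(round(col))] = True
        heading += rng.normal(0, 0.5)
        step_row = row + 1.5 * math.sin(heading)
        step_col = col + 1.5 * math.cos(heading)
        # reflect back toward the centre if the walk strays out of the nucleus
        if math.hypot(step_row - center[0], step_col - center[1]) > 0.75 * nucleus_r:
            heading = math.atan2(center[0] - row, center[1] - col) + rng.normal(0, 0.3)
            step_row = row + 1.5 * math.sin(heading)
            step_col = col + 1.5 * math.cos(heading)
        row, col = step_row, step_col
    return ndi.binary_dilation(path, structure=ndi.generate_binary_structure(2, 2))


def _structure_masks(params, nucleus_center, nucleus_r, rng, shape):
    """Per-nucleus FC-structure component masks, by phenotype."""
    n = int(rng.integers(params.nucleoli_per_nucleus[0], params.nucleoli_per_nucleus[1] + 1))
    r = params.nucleolus_radius_px
    masks: list[np.ndarray] = []
    if params.phenotype == "dissolution":
        masks.append(_string_mask(shape, nucleus_center, nucleus_r, params.fc_string_length, rng))
        return masks
    centers = _place_nucleoli(nucleus_center, nucleus_r, n, r, rng)
    if params.phenotype in ("normal", "metabolic"):
        for c in centers:
            masks.append(_disk_mask(shape, c, r))
    else:  # canonical_stress: peripheral caps on each nucleolar remnant
        cap_r = max(r * 0.55, 2.0)
        for c in centers:
            theta = rng.uniform(0, 2 * math.pi)
            for angle in (theta, theta + math.pi):
                cap_center = (
                    c[0] + r * math.sin(angle),
                    c[1] + r * math.cos(angle),
                )
                masks.append(_disk_mask(shape, cap_center, cap_r))
    return masks


def generate_field(params: PhenotypeParams) -> SyntheticField:
    """Render one synthetic field with ground truth.

    Channels are named ``dapi`` (DNA counterstain), ``fc`` (fibrillar-center
    marker, the segmentation channel), and ``gc`` (granular-component
    marker). The truth table holds, per nucleus, the noiseless integrated
    nucleolar and nucleoplasmic intensities of each channel (sums of the
    noiseless arrays over the ground-truth masks) and the analytic
    normality score derived from them.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.field_shape
    dna = np.zeros(shape)
    fc = np.zeros(shape)
    gc = np.zeros(shape)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nucleolus_labels = np.zeros(shape, dtype=np.int32)
    parent: dict[int, int] = {}
    next_nucleolus = 1
    f = params.gc_dispersal_frac
    condensation = params.fc_condensation if params.phenotype == "canonical_stress" else 0.0

    for nucleus_label, (row, col, nucleus_r) in enumerate(_place_nuclei(params, rng), start=1):
        nucleus = _disk_mask(shape, (row, col), nucleus_r)
        nucleus_labels[nucleus] = nucleus_label
        dna[nucleus] += params.dna_gain
        components = _structure_masks(params, (row, col), nucleus_r, rng, shape)
        structure = np.zeros(shape, dtype=bool)
        for component in components:
            component &= nucleus
            component &= ~structure  # keep components disjoint
            if component.sum() == 0:
                continue
            nucleolus_labels[component] = next_nucleolus
            parent[next_nucleolus] = nucleus_label
            next_nucleolus += 1
            structure |= component
        nucleoplasm = nucleus & ~structure
        area_s = int(structure.sum())
        area_p = int(nucleoplasm.sum())
        if area_s == 0 or area_p == 0:
            raise ValueError("degenerate geometry: empty compartment")
        fc[structure] += (params.fc_pool + condensation * params.fc_nucleoplasm_pool) / area_s
        fc[nucleoplasm] += (1 - condensation) * params.fc_nucleoplasm_pool / area_p
        gc[structure] += (1 - f) * params.gc_pool / area_s
        gc[nucleoplasm] += f * params.gc_pool / area_p

    noiseless = ImageField(
        channels={"dapi": dna, "fc": fc, "gc": gc},
        field_id=f"{params.phenotype}_s{params.seed}",
    )
    noisy_channels = {}
    for name, clean in noiseless.channels.items():
        noisy = clean.copy()
        if params.poisson_scale > 0:
            noisy = rng.poisson(clean * params.poisson_scale) / params.poisson_scale
        if params.gauss_sigma > 0:
            noisy = noisy + rng.normal(0, params.gauss_sigma, size=shape)
        noisy_channels[name] = np.clip(noisy, 0, None)
    noisy = ImageField(channels=noisy_channels, field_id=noiseless.field_id)

    nuclei = LabelMask(labels=nucleus_labels)
    nucleoli = LabelMask(labels=nucleolus_labels, parent=parent)
    truth = _truth_table(noiseless, nuclei, nucleoli)
    return SyntheticField(
        field=noisy,
        noiseless=noiseless,
        nuclei=nuclei,
        nucleoli=nucleoli,
        truth=truth,
        params=params,
    )


def _truth_table(noiseless, nuclei, nucleoli) -> pd.DataFrame:
    """Noiseless per-compartment sums over the generator's own masks."""
    rows = []
    for nucleus_label in range(1, nuclei.n_objects + 1):
        nucleus = nuclei.labels == nucleus_label
        own = [lab for lab, par in nucleoli.parent.items() if par == nucleus_label]
        nucleolar = np.isin(nucleoli.labels, own) & nucleus
        row = {"nucleus_label": nucleus_label, "n_nucleoli": len(own)}
        for name, arr in noiseless.channels.items():
            total = float(arr[nucleus].sum())
            in_nucleoli = float(arr[nucleolar].sum())
            row[f"i_nucleolar_{name}"] = in_nucleoli
            row[f"i_nucleoplasm_{name}"] = total - in_nucleoli
        gc_np = row["i_nucleoplasm_gc"]
        fc_np = row["i_nucleoplasm_fc"]
        fc_no = row["i_nucleolar_fc"]
        if gc_np > 0 and fc_np > 0 and fc_no > 0:
            row["analytic_score"] = (row["i_nucleolar_gc"] / gc_np) / (fc_no / fc_np)
        else:
            row["analytic_score"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate generator


def generate_plate(
    n_compounds: int = 1180,
    hit_fraction: float = 152 / 1180,
    *,
    both_share: float = 83 / 152,
    effect_size_sd: float = 6.0,
    cells_per_well: int = 100,
    n_fields: int = 4,
    n_vehicle_wells: int = 64,
    vehicle_mean: float = 1.0,
    vehicle_sd: float = 0.05,
    cell_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a two-concentration screen with planted hits.

    Each compound is assayed at 1 and 10 µM. Well-level score means are
    Normal(``vehicle_mean``, ``vehicle_sd``²); planted hits are shifted down
    by ``effect_size_sd`` vehicle SDs at 10 µM, and "both"-category hits at
    1 µM as well. Per-cell scores add Normal(0, ``cell_sd``²) noise and are
    split across ``n_fields`` fields. Defaults mirror the screened library:
    1180 compounds of which 83 planted as both-concentration hits and 69 as
    10 µM-only.

    Returns ``(per_cell, layout, truth)`` tables.
    """
    if not 0 <= hit_fraction <= 1:
        raise ValueError("hit_fraction must lie in [0, 1]")
    if n_compounds < 1 or cells_per_well < 1 or n_fields < 1:
        raise ValueError("degenerate plate size")
    rng = np.random.default_rng(seed)
    n_hits = int(round(hit_fraction * n_compounds))
    n_both = int(round(both_share * n_hits))
    categories = ["both"] * n_both + ["10_only"] * (n_hits - n_both)
    categories += ["none"] * (n_compounds - n_hits)
    rng.shuffle(categories)

    layout_rows = []
    truth_rows = []
    cell_rows = []

    def _emit_well(well_id, compound_id, conc, is_vehicle, well_score):
        layout_rows.append(
            {
                "well_id": well_id,
                "compound_id": compound_id,
                "concentration_uM": conc,
                "is_vehicle": is_vehicle,
            }
        )
        scores = well_score + rng.normal(0, cell_sd, size=cells_per_well)
        fields = np.arange(cells_per_well) % n_fields
        for s, fidx in zip(scores, fields):
            cell_rows.append(
                {
                    "well_id": well_id,
                    "field_id": f"{well_id}_f{fidx}",
                    "normality_score": s,
                }
            )

    for v in range(n_vehicle_wells):
        well_score = rng.normal(vehicle_mean, vehicle_sd)
        _emit_well(f"VEH{v:04d}", "DMSO", 0.0, True, well_score)

    for i, category in enumerate(categories):
        compound_id = f"C{i:05d}"
        shift = effect_size_sd * vehicle_sd
        shift_10 = shift if category in ("both", "10_only") else 0.0
        shift_1 = shift if category == "both" else 0.0
        truth_rows.append(
            {
                "compound_id": compound_id,
                "category": category,
                "true_shift_10uM": shift_10,
                "true_shift_1uM": shift_1,
            }
        )
        for conc, shift_c in ((1.0, shift_1), (10.0, shift_10)):
            well_score = rng.normal(vehicle_mean - shift_c, vehicle_sd)
            _emit_well(f"C{i:05d}_{int(conc)}uM", compound_id, conc, False, well_score)

    return (
        pd.DataFrame(cell_rows),
        pd.DataFrame(layout_rows),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# FRAP trace generator


def two_exp_params_for_half_time(
    t_half: float,
    *,
    a1: float = 0.5,
    a2: float = 0.3,
    f0: float = 0.2,
    rate_ratio: float = 8.0,
) -> tuple[float, float, float, float, float]:
    """Two-component parameters (f0, a1, k1, a2, k2) with a given T-half.

    The composite half-time scales inversely with a uniform scaling of both
    rates, so the rates are solved from the half-time at unit slow rate.
    """
    if t_half <= 0 or rate_ratio <= 0:
        raise ValueError("t_half and rate_ratio must be positive")
    base = half_time_of_model(f0, a1, rate_ratio, a2, 1.0)
    k2 = base / t_half
    return f0, a1, rate_ratio * k2, a2, k2


def generate_frap_trace(
    t_half: float = 4.6,
    *,
    model_params: tuple[float, float, float, float, float] | None = None,
    pre_frames: int = 10,
    post_frames: int = 200,
    dt: float = 0.45,
    roi_pre: float = 1000.0,
    whole_pre: float = 5000.0,
    background: float = 50.0,
    acquisition_bleach_rate: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    trace_id: str = "trace",
    group: str = "",
) -> FRAPTrace:
    """Forward-simulate a raw FRAP trace whose normalized curve is the model.

    ``model_params`` is ``(f0, a1, k1, a2, k2)`` in normalized units; when
    omitted it is derived from ``t_half`` (default 4.6 s, the scale of
    GC-protein recovery in unstressed cells). Acquisition photobleaching
    attenuates the ROI and whole-nucleus signals identically by
    ``exp(-rate * t)``, so double normalization removes it exactly. The
    whole-nucleus signal is held constant across the bleach pulse (small-ROI
    approximation). Gaussian noise of SD ``noise_sigma`` (normalized units)
    is added to the ROI signal.
    """
    if model_params is None:
        model_params = two_exp_params_for_half_time(t_half)
    f0, a1, k1, a2, k2 = model_params
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    n = pre_frames + post_frames
    t = np.arange(n) * dt
    t_bleach = t[pre_frames]
    m = np.ones(n)
    post = t[pre_frames:] - t_bleach
    m[pre_frames:] = f0 + a1 * (1 - np.exp(-k1 * post)) + a2 * (1 - np.exp(-k2 * post))
    decay = np.exp(-acquisition_bleach_rate * t)
    roi_amp = roi_pre - background
    whole_amp = whole_pre - background
    f_roi = background + roi_amp * decay * m
    f_whole = background + whole_amp * decay
    if noise_sigma > 0:
        f_roi = f_roi + rng.normal(0, noise_sigma * roi_amp, size=n)
    return FRAPTrace(
        t=t,
        f_roi=f_roi,
        f_bg=np.full(n, background),
        f_whole=f_whole,
        bleach_index=pre_frames,
        trace_id=trace_id,
        group=group,
    )


# ---------------------------------------------------------------------------
# file export


def write_field_set(
    out_dir: str | os.PathLike,
    fields: list[SyntheticField],
    *,
    well_ids: list[str] | None = None,
) -> str:
    """Write synthetic fields as multipage TIFFs plus a manifest CSV.

    Returns the manifest path. Truth tables are written alongside as
    ``truth_<field_id>.csv``.
    """
    from .io import write_field

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, synthetic in enumerate(fields):
        well = well_ids[i] if well_ids else "W01"
        synthetic.field.well_id = well
        name = f"{synthetic.field.field_id}_{i}.tif"
        write_field(synthetic.field, os.path.join(out_dir, name))
        synthetic.truth.to_csv(
            os.path.join(out_dir, f"truth_{synthetic.field.field_id}_{i}.csv"), index=False
        )
        rows.append({"field_id": f"{synthetic.field.field_id}_{i}", "well_id": well, "path": name})
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
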