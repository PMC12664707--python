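"""Cumulative dose-volume histograms, IIDV queries, D_eIIV inversion, and
prescription normalization.

The cumulative DVH is *exact*: it is built from the sorted occupancy-weighted
voxel doses with no histogram binning, so there is no bin-width free
parameter. Queries interpolate linearly between adjacent sorted voxel doses,
which makes ``dose_at_volume`` and the irradiated-isodose-volume curve
mutually inverse on strictly decreasing segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np

from .errors import DegenerateStructureError, DomainError
from .grid import DoseGrid, StructureMask, check_congruent, volume

__all__ = [
    "CumulativeDVH",
    "PlanContext",
    "compute_cdvh",
    "dose_at_volume",
    "dose_at_percent",
    "near_min_near_max",
    "iidv",
    "d_eiiv",
    "rescale_to_coverage",
    "apply_rescale",
    "SMALL_GTV_CC",
    "NEAR_EXTREME_CC",
]

# Volume threshold below which 0.01 cc exceeds 5% of the target and the
# percent-based near-extreme doses (D_95%, D_5%) are used instead.
SMALL_GTV_CC = 0.20
# Absolute volume unit for near-minimum / near-maximum dose reporting.
NEAR_EXTREME_CC = 0.01


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: volume (cc) receiving at least each dose threshold.

    ``thresholds`` are the ascending unique voxel doses (Gy); ``volumes[j]``
    is the occupancy-weighted volume receiving >= ``thresholds[j]``. The curve
    is non-increasing, equals ``total_volume`` at and below the minimum dose,
    and drops to zero beyond the maximum dose.
    """

    thresholds: np.ndarray
    volumes: np.ndarray
    total_volume: float

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise DomainError("thresholds and volumes must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise DomainError("thresholds must be strictly ascending")
        if np.any(np.diff(v) > 1e-12):
            raise DomainError("volumes must be non-increasing")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "total_volume", float(self.total_volume))

    # -- queries ----------------------------------------------------------- #

    def volume_at(self, dose_gy) -> float | np.ndarray:
        """Volume (cc) receiving at least ``dose_gy`` (linear interpolation)."""
        d = np.asarray(dose_gy, dtype=float)
        if np.any(d < 0):
            raise DomainError("dose threshold must be >= 0")
        out = np.interp(d, self.thresholds, self.volumes, left=self.total_volume, right=0.0)
        return float(out) if np.isscalar(dose_gy) or d.ndim == 0 else out

    def dose_at_volume(self, v_cc: float) -> float:
        """Minimum dose (Gy) received by the hottest ``v_cc`` cc.

        On plateaus (uniform-dose regions) the plateau dose itself is
        returned, reading the definition as an infimum.
        """
        if not (0 < v_cc <= self.total_volume * (1 + 1e-12)):
            raise DomainError(
                f"requested volume {v_cc} cc outside (0, total={self.total_volume} cc]"
            )
        v_cc = min(v_cc, self.total_volume)
        if v_cc <= self.volumes[-1]:  # hotter than the hottest resolvable step
            return float(self.thresholds[-1])
        return float(np.interp(v_cc, self.volumes[::-1], self.thresholds[::-1]))

    def dose_at_percent(self, x_pct: float) -> float:
        """Minimum dose (Gy) received by the hottest ``x_pct`` % of the volume."""
        if not (0 < x_pct <= 100):
            raise DomainError(f"percent must lie in (0, 100], got {x_pct}")
        return self.dose_at_volume(x_pct / 100.0 * self.total_volume)

    @property
    def min_dose(self) -> float:
        return float(self.thresholds[0])

    @property
    def max_dose(self) -> float:
        return float(self.thresholds[-1])

    def scaled(self, s: float) -> "CumulativeDVH":
        if not (s > 0):
            raise DomainError(f"scale factor must be > 0, got {s}")
        return replace(self, thresholds=self.thresholds * s)


def compute_cdvh(grid: DoseGrid, mask: StructureMask, refine: int = 1) -> CumulativeDVH:
    """Exact occupancy-weighted cumulative DVH of ``mask`` on ``grid``.

    With ``refine > 1`` the dose field is linearly interpolated onto
    ``refine`` subvoxels per axis and paired with a *re-sharpened* sub-voxel
    occupancy reconstructed from the structure's 0.5-level boundary surface
    (see :func:`~srsmetrics.grid.offset_subvoxel_occupancy`). This resolves
    the pairing of partial boundary occupancy with the sub-voxel dose
    variation across the structure surface, which otherwise smears
    near-extreme dose statistics of small structures by a substantial
    fraction of the per-voxel dose range. Binary masks (e.g. a whole-grid
    evaluation region) have no partial boundary and skip the sharpening.
    The total volume is preserved exactly.
    """
    check_congruent(grid, mask)
    occ = mask.occupancy
    if not (occ > 0).any():
        raise DegenerateStructureError(f"mask {mask.label!r} is empty")
    total_exact = volume(mask)
    dose_field = grid.dose
    vox_cc = grid.voxel_volume_cc
    fractional = bool(((occ > 0) & (occ < 1)).any())
    if refine > 1 and fractional:
        from scipy import ndimage

        from .grid import offset_subvoxel_occupancy

        dose_field = ndimage.zoom(dose_field, refine, order=1, mode="nearest", grid_mode=True)
        occ = offset_subvoxel_occupancy(mask, 0.0, refine)
        vox_cc = vox_cc / refine**3
    sel = occ > 0
    doses = dose_field[sel]
    weights = occ[sel] * vox_cc
    weights *= total_exact / weights.sum()  # volume conservation, exactly
    order = np.argsort(doses, kind="stable")
    doses, weights = doses[order], weights[order]
    uniq, start = np.unique(doses, return_index=True)
    w_per = np.add.reduceat(weights, start)
    total = float(weights.sum())
    # volume receiving >= uniq[j] = total minus everything strictly colder
    vols = total - np.concatenate([[0.0], np.cumsum(w_per)[:-1]])
    return CumulativeDVH(uniq, vols, total)


def dose_at_volume(dvh: CumulativeDVH, v_cc: float) -> float:
    """Module-level convenience wrapper for :meth:`CumulativeDVH.dose_at_volume`."""
    return dvh.dose_at_volume(v_cc)


def dose_at_percent(dvh: CumulativeDVH, x_pct: float) -> float:
    """Module-level convenience wrapper for :meth:`CumulativeDVH.dose_at_percent`."""
    return dvh.dose_at_percent(x_pct)


@dataclass(frozen=True, eq=False)
class PlanContext:
    """A dose grid with its target, derived margin structures and prescription.

    Parameters
    ----------
    grid
        The dose field.
    gtv
        Gross tumor volume mask (nonempty, congruent with ``grid``).
    prescription_dose
        Prescription dose in Gy (> 0).
    coverage_target
        Intended GTV coverage (%) by the prescription dose, or None.
    gtv_plus_2mm, gtv_minus_2mm
        Optional margin structures (2 mm outward / inward boundary offsets).
    evaluation_region
        Region over which irradiated isodose volumes are measured; defaults
        to the whole dose grid (a body mask may be supplied instead).
    """

    grid: DoseGrid
    gtv: StructureMask
    prescription_dose: float
    coverage_target: float | None = None
    gtv_plus_2mm: StructureMask | None = None
    gtv_minus_2mm: StructureMask | None = None
    evaluation_region: StructureMask | None = None
    dvh_refine: int = 3  # subvoxels per axis for DVH accumulation

    def __post_init__(self):
        if not (self.prescription_dose > 0):
            raise DomainError(f"prescription dose must be > 0, got {self.prescription_dose}")
        check_congruent(self.grid, self.gtv)
        if self.gtv.is_empty():
            raise DegenerateStructureError("GTV mask is empty")
        for m in (self.gtv_plus_2mm, self.gtv_minus_2mm, self.evaluation_region):
            if m is not None:
                check_congruent(self.grid, m)
        if self.coverage_target is not None and not (0 < self.coverage_target <= 100):
            raise DomainError(f"coverage target must lie in (0, 100], got {self.coverage_target}")

    @cached_property
    def region(self) -> StructureMask:
        if self.evaluation_region is not None:
            return self.evaluation_region
        return StructureMask(
            np.ones(self.grid.shape),
            label="whole grid",
            spacing=self.grid.spacing,
            origin=self.grid.origin,
        )

    @cached_property
    def region_dvh(self) -> CumulativeDVH:
        # the evaluation region is (near-)binary; center-sampled doses need no
        # sub-voxel pairing, and interpolation would only add chord bias
        return compute_cdvh(self.grid, self.region, refine=1)

    @cached_property
    def gtv_dvh(self) -> CumulativeDVH:
        return compute_cdvh(self.grid, self.gtv, refine=self.dvh_refine)

    @property
    def gtv_volume_cc(self) -> float:
        return self.gtv_dvh.total_volume

    def with_dose_scaled(self, s: float) -> "PlanContext":
        return replace(self, grid=self.grid.scaled(s))


def near_min_near_max(plan: PlanContext) -> tuple[float, float]:
    """Near-minimum and near-maximum GTV dose ``(D_near-min, D_near-max)`` in Gy.

    For GTV > 0.20 cc these are the 0.01 cc unit doses
    ``(D_{V-0.01cc}, D_{0.01cc})``; for GTV <= 0.20 cc (where 0.01 cc exceeds
    5% of the target) the percent doses ``(D_95%, D_5%)`` are used.
    """
    dvh = plan.gtv_dvh
    v = dvh.total_volume
    if v <= SMALL_GTV_CC:
        return dvh.dose_at_percent(95.0), dvh.dose_at_percent(5.0)
    return dvh.dose_at_volume(v - NEAR_EXTREME_CC), dvh.dose_at_volume(NEAR_EXTREME_CC)


def iidv(plan: PlanContext, dose_gy: float) -> float:
    """Irradiated isodose volume (cc): evaluation-region volume receiving >= dose."""
    if dose_gy < 0:
        raise DomainError(f"dose must be >= 0, got {dose_gy}")
    return float(plan.region_dvh.volume_at(dose_gy))


def d_eiiv(plan: PlanContext, target_volume_cc: float) -> float:
    """Dose (Gy) whose irradiated isodose volume equals ``target_volume_cc``.

    This is the objective marginal dose of a structure of that volume: the
    monotone inverse of the region-wide cumulative curve, by linear
    interpolation between sorted voxel doses. On a uniform-dose plateau the
    plateau dose itself is returned.
    """
    dvh = plan.region_dvh
    if not (0 < target_volume_cc <= dvh.total_volume):
        raise DomainError(
            f"target volume {target_volume_cc} cc outside (0, region volume "
            f"{dvh.total_volume} cc]"
        )
    return dvh.dose_at_volume(target_volume_cc)


def rescale_to_coverage(plan: PlanContext) -> float:
    """Scale factor ``s`` that sets GTV coverage at the prescription dose.

    After multiplying the dose field by ``s = PD / D_{c%}(GTV)``, the GTV
    coverage by the prescription dose equals the plan's ``coverage_target``
    percentage.
    """
    if plan.coverage_target is None:
        raise DomainError("plan has no coverage_target set")
    d_cov = plan.gtv_dvh.dose_at_percent(plan.coverage_target)
    if d_cov <= 0:
        raise DomainError(
            f"coverage target {plan.coverage_target}% unattainable: "
            f"D_{plan.coverage_target}% is zero"
        )
    return float(plan.prescription_dose / d_cov)


def apply_rescale(plan: PlanContext) -> PlanContext:
    """Return the plan with its dose field rescaled to the coverage target."""
    return plan.with_dose_scaled(rescale_to_coverage(plan))
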