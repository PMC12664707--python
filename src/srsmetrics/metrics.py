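"""Plan-quality metrics for stereotactic radiosurgery dose distributions.

Heterogeneity indices (HI_mRTOG, HI_ICRU), conformity indices (Paddick CI and
its reciprocal, the PIV/TV ratios), the modified gradient-index family, the
average gradient distance (AGD), isodose spillages, marginal-dose ratios,
coverage, and the linear-quadratic BED with alpha/beta = 10 Gy.

Ratio-based indices (HI, CI, GI) are invariant under global dose scaling;
the Gy- and cc-valued alternatives (D_eIIV, spillages, AGD) are the absolute
counterparts this suite emphasizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .dvh import PlanContext, d_eiiv, iidv, near_min_near_max
from .errors import DegeneratePlanError, DomainError, TruncationWarning
from .grid import equivalent_sphere_radius, volume
from .errors import SrsMetricsError

__all__ = [
    "MetricReport",
    "GradientReference",
    "heterogeneity",
    "conformity",
    "gradient_index",
    "agd",
    "spillage",
    "marginal_ratios",
    "bed10",
    "evaluate_plan",
    "MIN_CONTRACTED_GTV_CC",
]

# A 2 mm contraction is constructed only for GTVs at least this large
# (below it the contracted structure is not meaningful).
MIN_CONTRACTED_GTV_CC = 0.496

#: Symbolic reference doses for gradient indices.
GradientReference = str  # one of the keys of _GRADIENT_REFS below


@dataclass
class MetricReport:
    """Named values of every plan-quality metric for one plan.

    Fields that are not applicable for a plan (e.g. contracted-margin metrics
    for GTVs below 0.496 cc) hold ``None``. ``truncated`` lists metrics whose
    50% isodose volume was clipped by the grid boundary.
    """

    gtv_cc: float
    prescription_dose_gy: float
    # heterogeneity
    hi_mrtog: float | None = None
    hi_icru: float | None = None
    pd_to_nearmax_pct: float | None = None
    d_near_min_gy: float | None = None
    d_near_max_gy: float | None = None
    # conformity
    pci: float | None = None
    rpci: float | None = None
    mpitv: float | None = None
    pitv_d98: float | None = None
    coverage_pd_pct: float | None = None
    # gradient indices
    mgi_deiiv: float | None = None
    mgi_d98: float | None = None
    mgi_dv001: float | None = None
    mgi_plus2_deiiv: float | None = None
    # average gradient distances (mm)
    agd_pd_mm: float | None = None
    agd_deiiv_mm: float | None = None
    # D_eIIV marginal doses (Gy)
    d_eiiv_gtv_gy: float | None = None
    d_eiiv_plus2_gy: float | None = None
    d_eiiv_minus2_gy: float | None = None
    # coverage / spillage (absolute alternatives)
    coverage_deiiv_pct: float | None = None
    spill_deiiv_cc: float | None = None
    spill_piv_cc: float | None = None
    spill_piv_arith_cc: float | None = None
    spill_50piv_cc: float | None = None
    # marginal-dose ratios (%)
    ratio_minus2_pct: float | None = None
    ratio_plus2_pct: float | None = None
    d98_pct_pd: float | None = None
    truncated: list[str] = field(default_factory=list)

    #: mapping from report attributes to the field's customary abbreviations
    ABBREVIATIONS = {
        "gtv_cc": "GTV (cc)",
        "prescription_dose_gy": "PD (Gy)",
        "hi_mrtog": "HI_mRTOG",
        "hi_icru": "HI_ICRU",
        "pd_to_nearmax_pct": "PD to D_near-max (%)",
        "d_near_min_gy": "D_near-min (Gy)",
        "d_near_max_gy": "D_near-max (Gy)",
        "pci": "PCI",
        "rpci": "rPCI",
        "mpitv": "mPITV",
        "pitv_d98": "PITV_D98%",
        "coverage_pd_pct": "GTV coverage by PD (%)",
        "mgi_deiiv": "mGI_DeIIV",
        "mgi_d98": "mGI_D98%",
        "mgi_dv001": "mGI_DV-0.01cc",
        "mgi_plus2_deiiv": "mGI_+2mm_DeIIV",
        "agd_pd_mm": "AGD from PD IDS (mm)",
        "agd_deiiv_mm": "AGD from DeIIV IDS (mm)",
        "d_eiiv_gtv_gy": "GTV D_eIIV (Gy)",
        "d_eiiv_plus2_gy": "GTV+2mm D_eIIV (Gy)",
        "d_eiiv_minus2_gy": "GTV-2mm D_eIIV (Gy)",
        "coverage_deiiv_pct": "GTV coverage by D_eIIV (%)",
        "spill_deiiv_cc": "D_eIIV IIDV spillage (cc)",
        "spill_piv_cc": "PIV spillage (cc)",
        "spill_piv_arith_cc": "PIV minus GTV (cc)",
        "spill_50piv_cc": "50% PIV spillage (cc)",
        "ratio_minus2_pct": "GTV-2mm D_eIIV / GTV D_eIIV (%)",
        "ratio_plus2_pct": "GTV+2mm D_eIIV / GTV D_eIIV (%)",
        "d98_pct_pd": "GTV D_98% / PD (%)",
    }

    def to_dict(self, abbreviated: bool = False) -> dict:
        keys = list(self.ABBREVIATIONS)
        out = {}
        for k in keys:
            name = self.ABBREVIATIONS[k] if abbreviated else k
            out[name] = getattr(self, k)
        out["truncated"] = list(self.truncated)
        return out


# --------------------------------------------------------------------------- #
# heterogeneity                                                               #
# --------------------------------------------------------------------------- #


def heterogeneity(plan: PlanContext) -> tuple[float, float, float]:
    """GTV dose heterogeneity: ``(HI_mRTOG, HI_ICRU, near-min to near-max %)``.

    ``HI_mRTOG = D_near-max / D_near-min`` (0.01 cc units, or D_5%/D_95% for
    GTV <= 0.20 cc); ``HI_ICRU = (D_2% - D_98%) / D_50%``. The percentage is
    the near-minimum dose relative to the near-maximum dose (100%) — the lower
    the value, the more heterogeneous the target dose.
    """
    dvh = plan.gtv_dvh
    d_nmin, d_nmax = near_min_near_max(plan)
    hi_mrtog = d_nmax / d_nmin
    hi_icru = (dvh.dose_at_percent(2.0) - dvh.dose_at_percent(98.0)) / dvh.dose_at_percent(50.0)
    pd_to_nearmax = 100.0 * d_nmin / d_nmax
    return float(hi_mrtog), float(hi_icru), float(pd_to_nearmax)


# --------------------------------------------------------------------------- #
# conformity                                                                  #
# --------------------------------------------------------------------------- #


def conformity(plan: PlanContext) -> tuple[float, float, float, float]:
    """Conformity indices ``(PCI, rPCI, mPITV, PITV_D98)`` at the prescription dose.

    With ``TV_PIV`` the GTV volume receiving at least PD and ``PIV`` the
    prescription isodose volume over the evaluation region:

    * ``PCI  = TV_PIV^2 / (V_GTV * V_PIV)`` (Paddick),
    * ``rPCI = 1 / PCI``,
    * ``mPITV = V_PIV / V_GTV``,
    * ``PITV_D98 = IIDV(D_98%) / V_GTV``.

    The footnote identity ``rPCI = mPITV / (TV_PIV/V_GTV)^2`` holds exactly.
    """
    pd = plan.prescription_dose
    v_gtv = plan.gtv_volume_cc
    v_piv = iidv(plan, pd)
    if v_piv <= 0:
        raise DegeneratePlanError("prescription isodose volume is zero")
    tv_piv = float(plan.gtv_dvh.volume_at(pd))
    pci = tv_piv**2 / (v_gtv * v_piv)
    d98 = plan.gtv_dvh.dose_at_percent(98.0)
    pitv_d98 = iidv(plan, d98) / v_gtv
    return float(pci), float(1.0 / pci), float(v_piv / v_gtv), float(pitv_d98)


# --------------------------------------------------------------------------- #
# gradient index and average gradient distance                                #
# --------------------------------------------------------------------------- #


def _reference_dose(plan: PlanContext, reference: str) -> float:
    """Resolve a symbolic gradient-index reference dose to Gy."""
    dvh = plan.gtv_dvh
    v = dvh.total_volume
    if reference in ("deiiv", "deiiv_gtv"):
        return d_eiiv(plan, v)
    if reference == "d98":
        return dvh.dose_at_percent(98.0)
    if reference in ("dv001", "dv-0.01cc"):
        d_nmin, _ = near_min_near_max(plan)
        return d_nmin
    if reference in ("plus2_deiiv", "deiiv_plus2"):
        if plan.gtv_plus_2mm is None:
            raise DomainError("plan has no GTV+2mm structure")
        return d_eiiv(plan, volume(plan.gtv_plus_2mm))
    if reference == "pd":
        return plan.prescription_dose
    raise DomainError(f"unknown gradient reference {reference!r}")


def _check_truncation(plan: PlanContext, half_dose: float, what: str) -> bool:
    if plan.grid.boundary_max() >= half_dose:
        warnings.warn(
            f"{what}: the {half_dose:.3g} Gy isodose volume reaches the grid "
            "boundary; the value is a lower bound",
            TruncationWarning,
            stacklevel=3,
        )
        return True
    return False


def gradient_index(plan: PlanContext, reference: GradientReference = "deiiv") -> float:
    """Modified gradient index: ``IIDV(0.5 d_ref) / IIDV(d_ref)``.

    ``reference`` is one of ``"deiiv"`` (GTV D_eIIV, so the denominator is the
    GTV volume), ``"d98"``, ``"dv001"`` (the near-minimum dose, i.e. the
    original GI at the prescription isodose), or ``"plus2_deiiv"`` (D_eIIV of
    the 2 mm-expanded GTV). Values exceed 1 for any strictly decreasing
    falloff; a clipped 50% isodose raises :class:`TruncationWarning`.
    """
    d_ref = _reference_dose(plan, reference)
    if d_ref <= 0:
        raise DomainError(f"reference dose for {reference!r} is not positive")
    v_ref = iidv(plan, d_ref)
    if v_ref <= 0:
        raise DegeneratePlanError(f"IIDV at reference {reference!r} is zero")
    _check_truncation(plan, 0.5 * d_ref, f"mGI[{reference}]")
    return float(iidv(plan, 0.5 * d_ref) / v_ref)


def agd(plan: PlanContext, reference: str = "pd") -> float:
    """Average gradient distance (mm) from a reference isodose surface.

    The difference between the radii of the spheres equivalent to the
    irradiated isodose volumes of 50% and 100% of the reference dose
    (``"pd"`` for the prescription dose, ``"deiiv"`` for the GTV D_eIIV).
    An absolute-distance alternative to the gradient index; >= 0 for
    monotone-falloff plans.
    """
    d_ref = _reference_dose(plan, reference)
    if d_ref <= 0:
        raise DomainError(f"reference dose for {reference!r} is not positive")
    v100 = iidv(plan, d_ref)
    v50 = iidv(plan, 0.5 * d_ref)
    if v100 <= 0 or v50 <= 0:
        raise DegeneratePlanError(f"IIDV at reference {reference!r} is zero")
    _check_truncation(plan, 0.5 * d_ref, f"AGD[{reference}]")
    return float(equivalent_sphere_radius(v50) - equivalent_sphere_radius(v100))


# --------------------------------------------------------------------------- #
# spillage, marginal ratios, coverage                                         #
# --------------------------------------------------------------------------- #


def spillage(plan: PlanContext, dose_gy: float) -> float:
    """Volume (cc) receiving >= ``dose_gy`` that lies outside the GTV.

    Set-theoretic, occupancy-weighted: region IIDV minus the GTV volume
    receiving the dose. Measures the normal-tissue exposure of an isodose
    volume.
    """
    if dose_gy < 0:
        raise DomainError(f"dose must be >= 0, got {dose_gy}")
    inside = float(plan.gtv_dvh.volume_at(dose_gy))
    return max(0.0, iidv(plan, dose_gy) - inside)


def marginal_ratios(plan: PlanContext) -> tuple[float | None, float | None, float]:
    """Margin-structure D_eIIV ratios and D_eIIV coverage.

    Returns ``(ratio_minus2 %, ratio_plus2 %, coverage_DeIIV %)`` where each
    ratio is the margin structure's D_eIIV relative to the GTV D_eIIV (100%)
    and the coverage is the GTV fraction receiving at least the GTV D_eIIV.
    A missing margin structure yields ``None`` (not applicable), e.g. the
    2 mm contraction for GTV < 0.496 cc.
    """
    d_gtv = d_eiiv(plan, plan.gtv_volume_cc)
    ratio_minus2 = ratio_plus2 = None
    if plan.gtv_minus_2mm is not None:
        ratio_minus2 = 100.0 * d_eiiv(plan, volume(plan.gtv_minus_2mm)) / d_gtv
    if plan.gtv_plus_2mm is not None:
        ratio_plus2 = 100.0 * d_eiiv(plan, volume(plan.gtv_plus_2mm)) / d_gtv
    coverage = 100.0 * float(plan.gtv_dvh.volume_at(d_gtv)) / plan.gtv_volume_cc
    return ratio_minus2, ratio_plus2, float(coverage)


def bed10(total_dose_gy: float, fractions: int) -> float:
    """Biologically effective dose (Gy) with alpha/beta = 10 Gy.

    Linear-quadratic: ``n d (1 + d/10)`` with ``d`` the dose per fraction.
    """
    if total_dose_gy < 0:
        raise DomainError(f"total dose must be >= 0, got {total_dose_gy}")
    n = fractions
    if isinstance(n, float) and not n.is_integer():
        raise DomainError(f"fractions must be an integer, got {fractions}")
    n = int(n)
    if n < 1:
        raise DomainError(f"fractions must be >= 1, got {fractions}")
    d = total_dose_gy / n
    return float(n * d * (1.0 + d / 10.0))


# --------------------------------------------------------------------------- #
# full report                                                                 #
# --------------------------------------------------------------------------- #


def evaluate_plan(plan: PlanContext) -> MetricReport:
    """Compute every plan-quality metric; deterministic for a fixed plan.

    Metrics whose prerequisites are absent (margin structures under the
    0.496 cc rule) are reported as ``None`` rather than raising.
    """
    pd = plan.prescription_dose
    v_gtv = plan.gtv_volume_cc
    rep = MetricReport(gtv_cc=v_gtv, prescription_dose_gy=pd)

    d_nmin, d_nmax = near_min_near_max(plan)
    rep.d_near_min_gy, rep.d_near_max_gy = d_nmin, d_nmax
    rep.hi_mrtog, rep.hi_icru, rep.pd_to_nearmax_pct = heterogeneity(plan)

    rep.pci, rep.rpci, rep.mpitv, rep.pitv_d98 = conformity(plan)
    rep.coverage_pd_pct = 100.0 * float(plan.gtv_dvh.volume_at(pd)) / v_gtv
    rep.d98_pct_pd = 100.0 * plan.gtv_dvh.dose_at_percent(98.0) / pd

    rep.d_eiiv_gtv_gy = d_eiiv(plan, v_gtv)
    if plan.gtv_plus_2mm is not None:
        rep.d_eiiv_plus2_gy = d_eiiv(plan, volume(plan.gtv_plus_2mm))
    if plan.gtv_minus_2mm is not None:
        rep.d_eiiv_minus2_gy = d_eiiv(plan, volume(plan.gtv_minus_2mm))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", TruncationWarning)
        rep.mgi_deiiv = gradient_index(plan, "deiiv")
        rep.mgi_d98 = gradient_index(plan, "d98")
        rep.mgi_dv001 = gradient_index(plan, "dv001")
        if plan.gtv_plus_2mm is not None:
            try:
                rep.mgi_plus2_deiiv = gradient_index(plan, "plus2_deiiv")
            except SrsMetricsError:
                rep.mgi_plus2_deiiv = None
        rep.agd_pd_mm = agd(plan, "pd")
        rep.agd_deiiv_mm = agd(plan, "deiiv")
    seen = set()
    for w in caught:
        name = str(w.message).split(":", 1)[0]
        if issubclass(w.category, TruncationWarning) and name not in seen:
            seen.add(name)
            rep.truncated.append(name)
            warnings.warn(w.message, TruncationWarning, stacklevel=2)

    rep.ratio_minus2_pct, rep.ratio_plus2_pct, rep.coverage_deiiv_pct = marginal_ratios(plan)

    rep.spill_deiiv_cc = spillage(plan, rep.d_eiiv_gtv_gy)
    rep.spill_piv_cc = spillage(plan, pd)
    rep.spill_piv_arith_cc = iidv(plan, pd) - v_gtv
    rep.spill_50piv_cc = spillage(plan, 0.5 * pd)
    return rep
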