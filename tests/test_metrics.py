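"""Plan-quality metrics: indices, AGD, spillage, marginal ratios, BED."""

import dataclasses
import math

import numpy as np
import pytest

from srsmetrics.dvh import PlanContext, d_eiiv, iidv
from srsmetrics.errors import DomainError, TruncationWarning
from srsmetrics.grid import DoseGrid, StructureMask, ball_mask, volume
from srsmetrics.metrics import (
    agd,
    bed10,
    conformity,
    evaluate_plan,
    gradient_index,
    heterogeneity,
    marginal_ratios,
    spillage,
)
from srsmetrics.phantom import PhantomSpec, RadialDoseModel, make_radial_plan, oracle
from .conftest import make_lattice


def perfect_spherical_plan(r_gtv=6.0, pd=20.0, falloff=3.0, n=31):
    """Dose exactly PD on every GTV voxel, falling steeply outside.

    The GTV is the *binary* set of voxel centers within ``r_gtv``, so the
    prescription isodose region coincides with the target voxel-exactly:
    ideal conformity and a perfectly uniform target dose.
    """
    lat = make_lattice(n)
    z = lat.axis_coords(0)[:, None, None]
    y = lat.axis_coords(1)[None, :, None]
    x = lat.axis_coords(2)[None, None, :]
    r = np.sqrt(z**2 + y**2 + x**2)
    inside = r <= r_gtv
    gtv = StructureMask(inside.astype(float), label="GTV", spacing=lat.spacing, origin=lat.origin)
    dose = np.where(inside, pd, pd * np.exp(-falloff * (r - r_gtv)))
    grid = DoseGrid(dose, spacing=lat.spacing, origin=lat.origin)
    return PlanContext(grid=grid, gtv=gtv, prescription_dose=pd, dvh_refine=1)


class TestHeterogeneity:
    def test_uniform_target_dose(self):
        plan = perfect_spherical_plan()
        hi_mrtog, hi_icru, pct = heterogeneity(plan)
        assert hi_mrtog == pytest.approx(1.0, abs=1e-9)
        assert hi_icru == pytest.approx(0.0, abs=1e-9)
        assert pct == pytest.approx(100.0)

    def test_center_boost_matches_closed_form(self):
        # k = p (D_c/D_b - 1) makes the radial profile slope-continuous at the
        # boundary, so the near-minimum dose is clean of voxel kink smearing
        spec = PhantomSpec(
            gtv_volume_cc=7.0, center_dose_ratio=2.0, interior_exponent=1.0,
            falloff_exponent=1.0, prescription_isodose_fraction=0.85,
        )
        plan = make_radial_plan(spec)
        hi_mrtog, hi_icru, pct = heterogeneity(plan)
        assert hi_mrtog == pytest.approx(oracle(spec, "hi_mrtog").value, rel=0.02)
        assert pct == pytest.approx(oracle(spec, "pd_to_nearmax_pct").value, rel=0.02)

    def test_icru_compresses_range_on_heterogeneous_plans(self, offset_plan):
        hi_mrtog, hi_icru, _ = heterogeneity(offset_plan)
        # the 2%-98% window understates the full near-extreme spread
        assert hi_icru < hi_mrtog - 1.0


class TestConformity:
    def test_perfect_plan_all_indices_one(self):
        plan = perfect_spherical_plan()
        pci, rpci, mpitv, pitv_d98 = conformity(plan)
        for v in (pci, rpci, mpitv, pitv_d98):
            assert v == pytest.approx(1.0, abs=0.05)

    def test_footnote_identity_exact(self, offset_plan):
        pci, rpci, mpitv, _ = conformity(offset_plan)
        tvpiv = offset_plan.gtv_dvh.volume_at(offset_plan.prescription_dose)
        coverage_ratio = tvpiv / offset_plan.gtv_volume_cc
        assert pci * rpci == pytest.approx(1.0, rel=1e-12)
        assert rpci * coverage_ratio**2 == pytest.approx(mpitv, rel=1e-12)

    def test_pitv_at_deiiv_reference_is_one(self, offset_plan):
        d_star = d_eiiv(offset_plan, offset_plan.gtv_volume_cc)
        assert iidv(offset_plan, d_star) / offset_plan.gtv_volume_cc == pytest.approx(
            1.0, abs=1e-3
        )


class TestGradientIndex:
    @pytest.mark.parametrize("k", [2.0, 3.0, 4.0, 6.0])
    def test_power_law_falloff_is_2_pow_3_over_k(self, k):
        spec = PhantomSpec(
            gtv_volume_cc=4.0, center_dose_ratio=1.5, falloff_exponent=k,
            prescription_isodose_fraction=0.85,
        )
        plan = make_radial_plan(spec)
        for ref in ("deiiv", "d98", "dv001", "plus2_deiiv"):
            assert gradient_index(plan, ref) == pytest.approx(2 ** (3 / k), rel=0.03)

    def test_k3_gives_two(self, powerlaw_plan):
        assert gradient_index(powerlaw_plan, "deiiv") == pytest.approx(2.0, rel=0.03)

    def test_ordering_follows_reference_coverage(self):
        # with curved falloff the GI decreases as the reference dose falls
        # (i.e. as the reference IDS over-covers the target)
        spec = PhantomSpec(
            gtv_volume_cc=7.0, center_dose_ratio=1.8, falloff_exponent=3.0,
            falloff_curvature=2.1, dose_center_offset_mm=0.7,
        )
        plan = make_radial_plan(spec)
        refs = ["deiiv", "d98", "dv001", "plus2_deiiv"]
        doses = {
            "deiiv": d_eiiv(plan, plan.gtv_volume_cc),
            "d98": plan.gtv_dvh.dose_at_percent(98),
            "dv001": plan.gtv_dvh.dose_at_volume(plan.gtv_volume_cc - 0.01),
            "plus2_deiiv": d_eiiv(plan, volume(plan.gtv_plus_2mm)),
        }
        assert doses["deiiv"] > doses["d98"] > doses["dv001"] > doses["plus2_deiiv"]
        gis = [gradient_index(plan, r) for r in refs]
        assert all(a > b for a, b in zip(gis, gis[1:]))

    def test_truncation_warned(self):
        # a shallow 1/r falloff whose half-prescription isodose lies beyond
        # the grid boundary must be flagged, not silently reported
        lat = make_lattice(19)  # half-extent 9 mm
        z = lat.axis_coords(0)[:, None, None]
        y = lat.axis_coords(1)[None, :, None]
        x = lat.axis_coords(2)[None, None, :]
        r = np.maximum(np.sqrt(z**2 + y**2 + x**2), 0.5)
        dose = np.minimum(20.0 * 5.0 / r, 40.0)
        grid = DoseGrid(dose, spacing=lat.spacing, origin=lat.origin)
        gtv = ball_mask(lat, radius_mm=5.0, label="GTV")
        plan = PlanContext(grid=grid, gtv=gtv, prescription_dose=20.0, dvh_refine=1)
        with pytest.warns(TruncationWarning):
            gradient_index(plan, "deiiv")


class TestAgd:
    def test_closed_form_k3_radius10(self):
        # prescription isodose ball of radius 10 mm, falloff exponent 3:
        # AGD = 10 (2^(1/3) - 1) = 2.599 mm
        k = 3.0
        r_pd = 10.0
        frac = 0.85
        radius = r_pd * frac ** (1 / k)  # boundary radius giving r(PD) = 10
        spec = PhantomSpec(
            gtv_radius_mm=radius, center_dose_ratio=1.5, falloff_exponent=k,
            prescription_isodose_fraction=frac,
        )
        plan = make_radial_plan(spec)
        assert agd(plan, "pd") == pytest.approx(10.0 * (2 ** (1 / 3) - 1), abs=0.1)

    def test_degenerate_step_dose_gives_zero(self):
        # a step dose field: the 50% and 100% isodose volumes coincide
        plan = perfect_spherical_plan(falloff=50.0)
        assert agd(plan, "pd") == pytest.approx(0.0, abs=0.1)

    def test_deiiv_agd_exceeds_pd_agd_when_deiiv_higher(self):
        spec = PhantomSpec(
            gtv_volume_cc=7.0, center_dose_ratio=1.8, falloff_exponent=3.0,
            falloff_curvature=2.1, dose_center_offset_mm=0.8,
        )
        plan = make_radial_plan(spec)
        assert d_eiiv(plan, plan.gtv_volume_cc) > plan.prescription_dose
        assert agd(plan, "deiiv") > agd(plan, "pd")

    def test_agd_gi_equivalent_sphere_relation(self, powerlaw_plan):
        # mGI and AGD describe the same geometry through the equivalent-sphere
        # map: mGI = (1 + AGD/r100)^3 when both IIDVs are balls
        from srsmetrics.grid import equivalent_sphere_radius

        gi = gradient_index(powerlaw_plan, "deiiv")
        a = agd(powerlaw_plan, "deiiv")
        r100 = equivalent_sphere_radius(
            iidv(powerlaw_plan, d_eiiv(powerlaw_plan, powerlaw_plan.gtv_volume_cc))
        )
        assert gi == pytest.approx((1 + a / r100) ** 3, rel=0.01)


class TestSpillage:
    def test_piv_inside_gtv_spills_nothing(self):
        plan = perfect_spherical_plan()
        # at a dose above PD the isodose region is empty outside the target
        assert spillage(plan, plan.prescription_dose * 1.01) == 0.0

    def test_concentric_shell_volume(self, powerlaw_spec, powerlaw_plan):
        model = RadialDoseModel(powerlaw_spec)
        d = 0.6 * model.Db
        shell = model.iidv_cc(d) - powerlaw_plan.gtv_volume_cc
        assert spillage(powerlaw_plan, d) == pytest.approx(shell, rel=0.02)

    def test_spillage_at_deiiv_equals_uncovered_gtv(self, offset_plan):
        d_star = d_eiiv(offset_plan, offset_plan.gtv_volume_cc)
        spill = spillage(offset_plan, d_star)
        uncovered = offset_plan.gtv_volume_cc - offset_plan.gtv_dvh.volume_at(d_star)
        assert spill == pytest.approx(uncovered, rel=1e-6, abs=1e-9)


class TestMarginalRatios:
    def test_radial_ratio_matches_dose_profile(self, powerlaw_spec, powerlaw_plan):
        model = RadialDoseModel(powerlaw_spec)
        _, ratio_plus2, _ = marginal_ratios(powerlaw_plan)
        want = 100.0 * model.dose_at(model.R + 2.0) / model.Db
        assert ratio_plus2 == pytest.approx(want, rel=0.02)

    def test_uniform_dose_ratios_100(self):
        lat = make_lattice(31)
        grid = DoseGrid(np.full(lat.shape, 20.0), spacing=lat.spacing, origin=lat.origin)
        gtv = ball_mask(lat, radius_mm=6.0, label="GTV")
        plan = PlanContext(
            grid=grid, gtv=gtv, prescription_dose=20.0,
            gtv_plus_2mm=ball_mask(lat, radius_mm=8.0),
            gtv_minus_2mm=ball_mask(lat, radius_mm=4.0),
        )
        rm2, rp2, cov = marginal_ratios(plan)
        assert rm2 == pytest.approx(100.0)
        assert rp2 == pytest.approx(100.0)
        assert cov == pytest.approx(100.0)

    def test_small_target_minus2_not_applicable(self):
        spec = PhantomSpec(gtv_volume_cc=0.04, falloff_exponent=3.0, center_dose_ratio=1.3)
        plan = make_radial_plan(spec)
        assert plan.gtv_minus_2mm is None
        rm2, rp2, _ = marginal_ratios(plan)
        assert rm2 is None
        assert rp2 is not None


class TestBed10:
    @pytest.mark.parametrize(
        "dose, n, expected",
        [(20.0, 1, 60.0), (0.0, 3, 0.0), (30.0, 3, 60.0), (25.0, 5, 37.5)],
    )
    def test_linear_quadratic_values(self, dose, n, expected):
        assert bed10(dose, n) == pytest.approx(expected)

    def test_non_integer_fractions_rejected(self):
        with pytest.raises(DomainError):
            bed10(20.0, 2.5)
        with pytest.raises(DomainError):
            bed10(20.0, 0)


class TestEvaluatePlan:
    def test_perfect_plan_report(self):
        rep = evaluate_plan(perfect_spherical_plan())
        assert rep.pci == pytest.approx(1.0, abs=0.05)
        assert rep.hi_mrtog == pytest.approx(1.0, abs=1e-6)
        assert rep.spill_piv_cc == pytest.approx(0.0, abs=0.05)

    def test_every_oracle_metric_within_tolerance(self, offset_spec, offset_plan):
        rep = evaluate_plan(offset_plan)
        for name in (
            "gtv_cc", "prescription_dose_gy", "d_eiiv_gtv_gy", "d_eiiv_plus2_gy",
            "d_eiiv_minus2_gy", "mgi_deiiv", "mgi_d98", "mgi_dv001", "mgi_plus2_deiiv",
            "agd_pd_mm", "agd_deiiv_mm", "spill_deiiv_cc", "spill_piv_cc",
            "spill_50piv_cc", "coverage_deiiv_pct", "coverage_pd_pct",
            "ratio_plus2_pct", "ratio_minus2_pct", "hi_mrtog", "hi_icru",
            "pd_to_nearmax_pct", "pci", "rpci", "mpitv", "pitv_d98", "d98_pct_pd",
        ):
            o = oracle(offset_spec, name)
            assert o.matches(getattr(rep, name)), (
                f"{name}: got {getattr(rep, name)}, expected {o.value} "
                f"(rel {o.rel_tol}, abs {o.abs_tol})"
            )

    def test_ratio_metrics_invariant_under_dose_scaling(self, offset_plan):
        scaled = dataclasses.replace(
            offset_plan,
            grid=offset_plan.grid.scaled(1.37),
            prescription_dose=offset_plan.prescription_dose * 1.37,
        )
        a, b = evaluate_plan(offset_plan), evaluate_plan(scaled)
        # exact in real arithmetic; scaling perturbs float near-ties in the
        # sorted dose list, so agreement is asserted to 1e-4 relative
        for name in ("hi_mrtog", "hi_icru", "pci", "rpci", "mpitv", "pitv_d98",
                     "mgi_deiiv", "mgi_d98", "mgi_dv001", "pd_to_nearmax_pct",
                     "ratio_plus2_pct", "ratio_minus2_pct", "agd_pd_mm"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-4), name
        for name in ("d_eiiv_gtv_gy", "d_near_min_gy", "d_near_max_gy"):
            assert getattr(b, name) == pytest.approx(getattr(a, name) * 1.37, rel=1e-4), name

    def test_report_dict_uses_documented_abbreviations(self, offset_plan):
        rep = evaluate_plan(offset_plan)
        d = rep.to_dict(abbreviated=True)
        assert "PCI" in d and "mGI_DeIIV" in d and "AGD from PD IDS (mm)" in d
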