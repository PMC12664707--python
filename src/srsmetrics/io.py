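"""Plan readers and writers.

Two interchange formats:

* the *array-plan dialect*: NIfTI arrays (dose + one file per structure) with
  a JSON sidecar holding geometry and prescription metadata. Lossless and
  TPS-independent; this is the package's native format.
* DICOM-RT: an RT Dose / RT Structure Set pair. The dose is loaded on its
  native grid (no resampling); named contours are rasterized to fractional
  voxel occupancy by supersampled point-in-polygon testing. Writing produces
  a minimal but standard-conformant pair, mainly for round-trip testing and
  export to clinical viewers.

All physical quantities are converted to the package conventions on read:
dose in Gy, lengths in mm, volumes in cc, arrays indexed (z, y, x).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dvh import PlanContext
from .errors import LatticeMismatchError, ValidationError
from .grid import DoseGrid, StructureMask

__all__ = [
    "write_array_plan",
    "read_array_plan",
    "write_dicom_rt",
    "read_dicom_rt",
]

_FORMAT = "srsmetrics-array-plan"
_VERSION = 1

_MASK_SLOTS = ("gtv", "gtv_plus_2mm", "gtv_minus_2mm", "evaluation_region")


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in name.lower()).strip("-")


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    # our arrays are (z, y, x); expose x/y/z spacing on the NIfTI diagonal in
    # array-axis order so spacing survives a round trip through nibabel
    aff = np.diag(list(spacing_zyx) + [1.0])
    aff[:3, 3] = origin_zyx
    return aff


def _save_nifti(path: Path, data: np.ndarray, spacing, origin) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data), _affine(spacing, origin))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def write_array_plan(plan: PlanContext, prefix: str | Path) -> Path:
    """Write a plan as NIfTI arrays plus a JSON sidecar.

    Creates ``<prefix>.dose.nii.gz``, ``<prefix>.mask-<name>.nii.gz`` per
    structure, and ``<prefix>.plan.json``; returns the sidecar path.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    lat = plan.grid.lattice
    dose_file = prefix.with_suffix(".dose.nii.gz").name
    _save_nifti(prefix.parent / dose_file, plan.grid.dose, lat.spacing, lat.origin)

    masks = {}
    for slot in _MASK_SLOTS:
        mask: StructureMask | None = getattr(plan, slot, None)
        if slot == "evaluation_region":
            mask = plan.evaluation_region
        if mask is None:
            continue
        fname = f"{prefix.name}.mask-{_slug(slot)}.nii.gz"
        _save_nifti(prefix.parent / fname, mask.occupancy.astype(np.float32), lat.spacing, lat.origin)
        masks[slot] = {"file": fname, "label": mask.label}

    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "units": {"dose": "Gy", "length": "mm", "volume": "cc"},
        "axis_order": "zyx",
        "spacing_mm": list(lat.spacing),
        "origin_mm": list(lat.origin),
        "shape": list(lat.shape),
        "dose_file": dose_file,
        "masks": masks,
        "prescription_dose_gy": plan.prescription_dose,
        "coverage_target_pct": plan.coverage_target,
        "evaluation_region": "evaluation_region" if plan.evaluation_region is not None else "whole grid",
        "dvh_refine": plan.dvh_refine,
    }
    sidecar = prefix.parent / f"{prefix.name}.plan.json"
    sidecar.write_text(json.dumps(doc, indent=2))
    return sidecar


def read_array_plan(sidecar: str | Path) -> PlanContext:
    """Read a plan written by :func:`write_array_plan`.

    Raises :class:`ValidationError` listing the offending fields when the
    document is incomplete or inconsistent.
    """
    import nibabel as nib

    sidecar = Path(sidecar)
    try:
        doc = json.loads(sidecar.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot read plan document {sidecar}: {exc}") from exc

    problems = []
    if doc.get("format") != _FORMAT:
        problems.append("format")
    for key in ("spacing_mm", "origin_mm", "dose_file", "prescription_dose_gy", "masks"):
        if doc.get(key) is None:
            problems.append(key)
    if "gtv" not in doc.get("masks", {}):
        problems.append("masks.gtv")
    if problems:
        raise ValidationError(
            f"invalid plan document {sidecar}: missing/bad fields {problems}", problems
        )

    spacing = tuple(float(v) for v in doc["spacing_mm"])
    origin = tuple(float(v) for v in doc["origin_mm"])
    base = sidecar.parent

    def load(fname):
        return np.asanyarray(nib.load(str(base / fname)).dataobj)

    dose = load(doc["dose_file"])
    grid = DoseGrid(dose, spacing=spacing, origin=origin)

    def load_mask(slot):
        entry = doc["masks"].get(slot)
        if entry is None:
            return None
        occ = load(entry["file"])
        if occ.shape != grid.shape:
            raise ValidationError(
                f"mask {slot!r} shape {occ.shape} does not match dose {grid.shape}",
                [f"masks.{slot}"],
            )
        return StructureMask(occ, label=entry.get("label", slot), spacing=spacing, origin=origin)

    return PlanContext(
        grid=grid,
        gtv=load_mask("gtv"),
        prescription_dose=float(doc["prescription_dose_gy"]),
        coverage_target=doc.get("coverage_target_pct"),
        gtv_plus_2mm=load_mask("gtv_plus_2mm"),
        gtv_minus_2mm=load_mask("gtv_minus_2mm"),
        evaluation_region=load_mask("evaluation_region"),
        dvh_refine=int(doc.get("dvh_refine", 3)),
    )


# --------------------------------------------------------------------------- #
# DICOM-RT                                                                    #
# --------------------------------------------------------------------------- #


def _dicom_base(modality, sop_class, frame_uid):
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "phantom^srsmetrics"
    ds.PatientID = "SRSMETRICS"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = frame_uid
    return ds


_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


def write_dicom_rt(plan: PlanContext, dose_path: str | Path, struct_path: str | Path) -> None:
    """Write the plan as an RT Dose / RT Structure Set pair."""
    from pydicom.dataset import Dataset
    from pydicom.uid import generate_uid

    lat = plan.grid.lattice
    nz, ny, nx = lat.shape
    frame_uid = generate_uid()

    # ---- dose ----
    ds = _dicom_base("RTDOSE", _RTDOSE_CLASS, frame_uid)
    scaling = max(plan.grid.dose.max(), 1e-6) / (2**31 - 1)
    pixels = np.round(plan.grid.dose / scaling).astype(np.uint32)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [f"{lat.spacing[1]:.6f}", f"{lat.spacing[2]:.6f}"]  # row (y), col (x)
    ds.ImagePositionPatient = [f"{lat.origin[2]:.6f}", f"{lat.origin[1]:.6f}", f"{lat.origin[0]:.6f}"]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(i * lat.spacing[0]) for i in range(nz)]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(dose_path), enforce_file_format=True)

    # ---- structures ----
    ss = _dicom_base("RTSTRUCT", _RTSTRUCT_CLASS, frame_uid)
    ss.StructureSetLabel = "srsmetrics"
    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ss.ReferencedFrameOfReferenceSequence = [ref_frame]
    ss.StructureSetROISequence = []
    ss.ROIContourSequence = []
    ss.RTROIObservationsSequence = []

    masks = [plan.gtv]
    for extra in (plan.gtv_plus_2mm, plan.gtv_minus_2mm):
        if extra is not None:
            masks.append(extra)
    for number, mask in enumerate(masks, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = mask.label
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ss.StructureSetROISequence.append(roi)

        contour_seq = []
        for contour in _mask_to_contours(mask):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(contour) // 3
            c.ContourData = [f"{v:.4f}" for v in contour]
            contour_seq.append(c)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ROIDisplayColor = [255, 0, 0]
        rc.ContourSequence = contour_seq
        ss.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = "GTV" if number == 1 else "AVOIDANCE"
        obs.ROIInterpreter = ""
        ss.RTROIObservationsSequence.append(obs)
    ss.save_as(str(struct_path), enforce_file_format=True)


def _mask_to_contours(mask: StructureMask):
    """Axial 0.5-level contours of a mask as flat [x, y, z, ...] mm lists."""
    from skimage.measure import find_contours

    lat = mask.lattice
    out = []
    for iz in range(lat.shape[0]):
        slice_ = mask.occupancy[iz]
        if slice_.max() < 0.5:
            continue
        z = lat.origin[0] + iz * lat.spacing[0]
        for poly in find_contours(slice_, 0.5):
            if len(poly) < 3:
                continue
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            ys = lat.origin[1] + poly[:, 0] * lat.spacing[1]
            xs = lat.origin[2] + poly[:, 1] * lat.spacing[2]
            flat = np.column_stack([xs, ys, np.full(len(xs), z)]).ravel()
            out.append(flat.tolist())
    return out


def read_dicom_rt(
    dose_path: str | Path,
    struct_path: str | Path,
    gtv_name: str = "GTV",
    plus2_name: str | None = None,
    minus2_name: str | None = None,
    prescription_dose: float | None = None,
    coverage_target: float | None = None,
) -> PlanContext:
    """Load an RT Dose / RT Structure Set pair onto the dose's native grid.

    ``prescription_dose`` may be omitted only if the structure set was written
    by this package alongside a plan document; usually it must be supplied.
    Structure names are matched case-insensitively; a missing name raises a
    lookup error listing the available structures.
    """
    import pydicom

    ds = pydicom.dcmread(str(dose_path))
    if ds.SOPClassUID != _RTDOSE_CLASS:
        raise ValidationError(f"{dose_path} is not an RT Dose object")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0], atol=1e-4):
        raise ValidationError("non-uniform GridFrameOffsetVector is not supported")
    spacing = (
        float(dz[0]) if offsets.size > 1 else 1.0,
        float(ds.PixelSpacing[0]),
        float(ds.PixelSpacing[1]),
    )
    ipp = [float(v) for v in ds.ImagePositionPatient]  # (x, y, z)
    origin = (ipp[2] + offsets[0], ipp[1], ipp[0])
    dose = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if dose.ndim == 2:
        dose = dose[None]
    grid = DoseGrid(dose, spacing=spacing, origin=origin)

    ss = pydicom.dcmread(str(struct_path))
    if ss.SOPClassUID != _RTSTRUCT_CLASS:
        raise ValidationError(f"{struct_path} is not an RT Structure Set")
    dose_frame = getattr(ds, "FrameOfReferenceUID", None)
    struct_frame = getattr(ss, "FrameOfReferenceUID", None)
    if dose_frame and struct_frame and dose_frame != struct_frame:
        raise LatticeMismatchError(
            "RT Dose and RT Structure Set reference different frames of reference"
        )

    names = {str(roi.ROIName): int(roi.ROINumber) for roi in ss.StructureSetROISequence}

    def rasterize(name, required):
        if name is None:
            return None
        match = {k.lower(): k for k in names}.get(name.lower())
        if match is None:
            if required:
                raise KeyError(
                    f"structure {name!r} not found; available: {sorted(names)}"
                )
            return None
        number = names[match]
        for rc in ss.ROIContourSequence:
            if int(rc.ReferencedROINumber) == number:
                return _rasterize_roi(rc, grid, label=match)
        raise ValidationError(f"structure {name!r} has no contour data")

    return PlanContext(
        grid=grid,
        gtv=rasterize(gtv_name, required=True),
        prescription_dose=float(prescription_dose) if prescription_dose else float(dose.max()),
        coverage_target=coverage_target,
        gtv_plus_2mm=rasterize(plus2_name, required=False),
        gtv_minus_2mm=rasterize(minus2_name, required=False),
    )


def _rasterize_roi(rc, grid: DoseGrid, label: str, supersample: int = 4) -> StructureMask:
    """Fractional occupancy of CLOSED_PLANAR contours on the dose lattice."""
    from matplotlib.path import Path as MplPath

    lat = grid.lattice
    nz, ny, nx = lat.shape
    occ = np.zeros((nz, ny, nx))
    s = supersample
    # supersampled in-plane sample points (pixel-center offsets)
    off = (np.arange(s) + 0.5) / s - 0.5
    oy, ox = np.meshgrid(off * lat.spacing[1], off * lat.spacing[2], indexing="ij")

    ys = lat.origin[1] + np.arange(ny) * lat.spacing[1]
    xs = lat.origin[2] + np.arange(nx) * lat.spacing[2]

    for contour in getattr(rc, "ContourSequence", []):
        if contour.ContourGeometricType != "CLOSED_PLANAR":
            continue
        pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
        z = pts[:, 2].mean()
        iz = int(round((z - lat.origin[0]) / lat.spacing[0]))
        if not (0 <= iz < nz and abs(lat.origin[0] + iz * lat.spacing[0] - z) < lat.spacing[0] / 2 + 1e-3):
            continue
        path = MplPath(pts[:, :2])  # (x, y)
        xmin, ymin = pts[:, 0].min(), pts[:, 1].min()
        xmax, ymax = pts[:, 0].max(), pts[:, 1].max()
        jsel = np.where((ys >= ymin - lat.spacing[1]) & (ys <= ymax + lat.spacing[1]))[0]
        isel = np.where((xs >= xmin - lat.spacing[2]) & (xs <= xmax + lat.spacing[2]))[0]
        if jsel.size == 0 or isel.size == 0:
            continue
        yy = ys[jsel][:, None, None, None] + oy[None, None]
        xx = xs[isel][None, :, None, None] + ox[None, None]
        pts2 = np.stack(
            [np.broadcast_to(xx, (jsel.size, isel.size, s, s)).ravel(),
             np.broadcast_to(yy, (jsel.size, isel.size, s, s)).ravel()],
            axis=-1,
        )
        inside = path.contains_points(pts2).reshape(jsel.size, isel.size, s, s)
        frac = inside.mean(axis=(2, 3))
        occ[iz][np.ix_(jsel, isel)] += frac
    occ = np.clip(occ, 0.0, 1.0)
    return StructureMask(occ, label=label, spacing=lat.spacing, origin=lat.origin)
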