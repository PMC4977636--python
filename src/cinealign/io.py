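"""Contour-file serialization and DICOM plane-geometry reading.

The contour JSON schema holds, per case, one record per imaging slice with
its plane geometry (the DICOM Image Position (Patient), Image Orientation
(Patient) and Pixel Spacing attributes) and the labeled pixel-coordinate
contour polylines.  Numbers round-trip bit-exactly (full-precision decimal
serialization).  From DICOM files only the three geometry attributes are
read; pixel data are never touched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import SchemaError
from .geometry import Contour2D, ImagePlane, SliceRecord

__all__ = ["read_contours", "write_contours", "read_plane_from_dicom",
           "records_to_dict", "records_from_dict"]

_VIEWS = ("SA", "2CH", "3CH", "4CH")
_LABELS = ("LV", "LA", "AO")


def records_to_dict(records: list[SliceRecord], case_id: str = "case") -> dict:
    return {
        "case_id": case_id,
        "units": "mm; pixel coordinates are 0-based pixel centers",
        "slices": [
            {
                "view": r.view,
                "slice_index": int(r.slice_index),
                "plane": {
                    "position": r.plane.position.tolist(),
                    "row_dir": r.plane.row_dir.tolist(),
                    "col_dir": r.plane.col_dir.tolist(),
                    "spacing": r.plane.spacing.tolist(),
                },
                "contours": [
                    {
                        "label": c.label,
                        "closed": bool(c.closed),
                        "points_px": c.points.tolist(),
                    }
                    for c in r.contours
                ],
            }
            for r in records
        ],
    }


def _require(d: dict, key: str, ctx: str):
    if not isinstance(d, dict) or key not in d:
        raise SchemaError(f"{ctx}.{key}" if ctx else key)
    return d[key]


def records_from_dict(doc: dict) -> list[SliceRecord]:
    slices = _require(doc, "slices", "")
    if not isinstance(slices, list):
        raise SchemaError("slices", "must be a list")
    records = []
    for i, s in enumerate(slices):
        ctx = f"slices[{i}]"
        view = _require(s, "view", ctx)
        if view not in _VIEWS:
            raise SchemaError(f"{ctx}.view", f"unknown view {view!r}")
        idx = _require(s, "slice_index", ctx)
        pd = _require(s, "plane", ctx)
        for fld in ("position", "row_dir", "col_dir", "spacing"):
            _require(pd, fld, f"{ctx}.plane")
        try:
            plane = ImagePlane(pd["position"], pd["row_dir"], pd["col_dir"],
                               pd["spacing"])
        except Exception as exc:
            raise SchemaError(f"{ctx}.plane", str(exc)) from exc
        contours = []
        for j, cd in enumerate(_require(s, "contours", ctx)):
            cctx = f"{ctx}.contours[{j}]"
            label = _require(cd, "label", cctx)
            if label not in _LABELS:
                raise SchemaError(f"{cctx}.label", f"unknown label {label!r}")
            pts = _require(cd, "points_px", cctx)
            try:
                contours.append(Contour2D(np.asarray(pts, float), label,
                                          bool(cd.get("closed", True))))
            except Exception as exc:
                raise SchemaError(f"{cctx}.points_px", str(exc)) from exc
        records.append(SliceRecord(view, int(idx), plane, tuple(contours)))
    return records


def write_contours(records: list[SliceRecord], path, case_id: str = "case") -> None:
    Path(path).write_text(json.dumps(records_to_dict(records, case_id), indent=1))


def read_contours(path) -> list[SliceRecord]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError("<document>", f"not valid JSON: {exc}") from exc
    return records_from_dict(doc)


def read_plane_from_dicom(path) -> ImagePlane:
    """Assemble an ImagePlane from a DICOM file's geometry attributes.

    Reads Image Position (Patient) (0020,0032), Image Orientation (Patient)
    (0020,0037) (first triplet = row direction, second = column direction)
    and Pixel Spacing (0028,0030).  Note the DICOM pixel-spacing ordering:
    the attribute stores (row spacing, column spacing) = (dv, du), which is
    swapped into this package's (du, dv) convention.
    """
    import pydicom

    from .errors import MissingAttributeError

    ds = pydicom.dcmread(str(path), stop_before_pixels=True, force=True)
    tags = {
        "ImagePositionPatient": "(0020,0032)",
        "ImageOrientationPatient": "(0020,0037)",
        "PixelSpacing": "(0028,0030)",
    }
    for keyword, tag in tags.items():
        if getattr(ds, keyword, None) is None:
            raise MissingAttributeError(f"{keyword} {tag}")
    pos = np.asarray([float(x) for x in ds.ImagePositionPatient])
    orient = np.asarray([float(x) for x in ds.ImageOrientationPatient])
    dv, du = (float(x) for x in ds.PixelSpacing)  # DICOM: row spacing first
    return ImagePlane(pos, orient[:3], orient[3:], (du, dv))
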