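"""Macro- and micro-segmentation quantification.

Mean fluorescence intensity (MFI) is total counts per ROI pixel area.
Macro-segmentation works on fresh tissue slices: per-slice tumor and
background MFIs are averaged per tissue type across a patient's slices,
and the tumor-to-background ratio (TBR) is the patient's tumor MFI over
the background MFI, where background means all surrounding healthy
tissue (parenchyma+collagen plus fat; carcinoma in situ belongs to
neither side of the ratio).  Micro-segmentation works on 10-um section
scans with per-component label maps and yields per-component MFIs and
the tumor-to-parenchyma ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BACKGROUND_CLASSES,
    CIS,
    FAT,
    PARENCHYMA,
    TUMOR,
    FluorImage,
    TissueLabelMap,
)


@dataclass
class QuantRecord:
    """Per-patient quantification output at one imaging level."""

    patient_id: str | None
    level: str
    per_region_mfi: list[dict] = field(default_factory=list)
    mfi_by_class: dict[int, float] = field(default_factory=dict)
    tbr: float | None = None
    tumor_to_parenchyma: float | None = None
    flags: list[str] = field(default_factory=list)


def mfi(image: FluorImage | np.ndarray, region: np.ndarray) -> float:
    """Mean counts per pixel over a boolean region mask.

    The integer pixel sum is divided by the pixel count in double
    precision; an empty region is an error, not a NaN.
    """
    counts = image.counts if isinstance(image, FluorImage) else np.asarray(image)
    region = np.asarray(region, dtype=bool)
    if region.shape != counts.shape:
        raise ValueError("region mask shape does not match the image")
    n = int(np.count_nonzero(region))
    if n == 0:
        raise ValueError("empty region")
    total = int(counts[region].astype(np.int64).sum())
    return total / n


def macro_quantify(
    slices: list[tuple[FluorImage, TissueLabelMap]],
    pooled: bool = False,
) -> QuantRecord:
    """Quantify a patient's fresh tissue slices: tumor MFI, background MFI, TBR.

    Per slice the tumor ROI and the (pooled parenchyma+fat) background ROI
    are measured; the patient-level MFI per tissue type is the unweighted
    mean of the per-slice MFIs over slices containing that type
    (``pooled=True`` switches to pooling pixels across slices instead).
    Slices without tumor contribute only background.  TBR is absent
    (flagged) when no slice bears tumor.
    """
    if not slices:
        raise ValueError("at least one slice required")
    rec = QuantRecord(patient_id=slices[0][0].patient_id, level="fresh_slice")
    tumor_mfis: list[float] = []
    bg_mfis: list[float] = []
    tumor_pix = tumor_sum = bg_pix = bg_sum = 0
    for image, label_map in slices:
        idx = image.slice_index
        t_mask = label_map.mask(TUMOR)
        b_mask = label_map.mask(*BACKGROUND_CLASSES)
        if not b_mask.any():
            raise ValueError(f"slice {idx}: no background tissue")
        b = mfi(image, b_mask)
        bg_mfis.append(b)
        bg_sum += int(image.counts[b_mask].astype(np.int64).sum())
        bg_pix += int(b_mask.sum())
        rec.per_region_mfi.append({"slice_index": idx, "tissue_class": "background",
                                   "pixel_count": int(b_mask.sum()), "mfi": b})
        if t_mask.any():
            t = mfi(image, t_mask)
            tumor_mfis.append(t)
            tumor_sum += int(image.counts[t_mask].astype(np.int64).sum())
            tumor_pix += int(t_mask.sum())
            rec.per_region_mfi.append({"slice_index": idx, "tissue_class": TUMOR,
                                       "pixel_count": int(t_mask.sum()), "mfi": t})
    if pooled:
        bg = bg_sum / bg_pix
        tumor = tumor_sum / tumor_pix if tumor_pix else None
    else:
        bg = float(np.mean(bg_mfis))
        tumor = float(np.mean(tumor_mfis)) if tumor_mfis else None
    rec.mfi_by_class["background"] = bg
    if tumor is None:
        rec.flags.append("no_tumor_bearing_slice")
    else:
        rec.mfi_by_class[TUMOR] = tumor
        if bg <= 0:
            raise ZeroDivisionError("background MFI is zero; TBR undefined")
        rec.tbr = tumor / bg
    return rec


def micro_quantify(
    sections: list[tuple[FluorImage, TissueLabelMap]],
) -> QuantRecord:
    """Quantify a patient's 10-um sections per tissue component.

    Per slide each labelled component is measured; the patient mean per
    component is taken over the slides containing it.  Normal tissue is
    fat plus parenchymal tissue including collagen, combined with
    pixel-area weights; the tumor-to-parenchyma ratio divides the tumor
    MFI by the parenchyma+collagen MFI and is flagged when below 1.
    """
    if not sections:
        raise ValueError("at least one section required")
    rec = QuantRecord(patient_id=sections[0][0].patient_id, level="section")
    per_class: dict[int, list[float]] = {}
    pix_by_class: dict[int, int] = {}
    for image, label_map in sections:
        for cls in sorted(set(label_map.code_map) - {0}):
            m = label_map.mask(cls)
            if not m.any():
                continue
            v = mfi(image, m)
            per_class.setdefault(cls, []).append(v)
            pix_by_class[cls] = pix_by_class.get(cls, 0) + int(m.sum())
            rec.per_region_mfi.append({"slice_index": image.slice_index,
                                       "tissue_class": cls,
                                       "pixel_count": int(m.sum()), "mfi": v})
    for cls, vals in per_class.items():
        rec.mfi_by_class[cls] = float(np.mean(vals))
    normal_classes = [c for c in BACKGROUND_CLASSES if c in rec.mfi_by_class]
    if normal_classes:
        w = np.array([pix_by_class[c] for c in normal_classes], dtype=float)
        v = np.array([rec.mfi_by_class[c] for c in normal_classes])
        rec.mfi_by_class["normal"] = float(np.sum(w * v) / np.sum(w))
    if TUMOR in rec.mfi_by_class and PARENCHYMA in rec.mfi_by_class:
        ratio = rec.mfi_by_class[TUMOR] / rec.mfi_by_class[PARENCHYMA]
        rec.tumor_to_parenchyma = ratio
        if ratio < 1:
            rec.flags.append("tumor_below_parenchyma")
    return rec


def whole_section_mfi(section: tuple[FluorImage, TissueLabelMap]) -> float:
    """Mean counts over every labelled (non-zero) pixel of one section."""
    image, label_map = section
    mask = label_map.labels != 0
    if not mask.any():
        raise ValueError("empty region: label map carries no tissue")
    return mfi(image, mask)
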