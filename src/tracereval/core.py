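"""Shared domain types for the tracer-evaluation pipeline.

The pipeline quantifies fluorescence of a tumor-targeted near-infrared
tracer at several ex vivo levels of the same surgical specimen: fresh
tissue slices imaged in a light-tight macroscopic camera, the
formalin-fixed paraffin-embedded (FFPE) blocks cut from them, and
10-um-thick sections scanned on a fluorescence flatbed scanner.  An
image is always a single-channel 16-bit counts array; the tissue
content of an image is described by an integer label map sharing its
shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer tissue codes used by every label map in the pipeline.
TISSUE_CODES: dict[int, str] = {
    0: "outside_tissue",
    1: "tumor",
    2: "carcinoma_in_situ",
    3: "parenchyma_collagen",
    4: "fat",
}

TUMOR = 1
CIS = 2
PARENCHYMA = 3
FAT = 4

#: Macro-level "background" (surrounding healthy tissue): everything that
#: is neither tumor nor carcinoma in situ.
BACKGROUND_CLASSES = (PARENCHYMA, FAT)

#: The four imaging levels, from the operating theatre down to histology.
LEVELS = ("in_vivo", "fresh_slice", "ffpe_block", "section")

MAX_COUNTS = 65535  # 16-bit detector ceiling


@dataclass
class FluorImage:
    """A single-channel fluorescence counts image at a named level.

    ``counts`` is unsigned 16-bit; ``exposure_ms`` and ``gain`` record the
    acquisition settings (the cameras ran at fixed exposure/gain, dropping
    gain only on saturation), ``patient_id`` and ``slice_index`` carry
    provenance so multi-level data can be joined per specimen.
    """

    counts: np.ndarray
    level: str
    exposure_ms: float | None = None
    gain: float | None = None
    patient_id: str | None = None
    slice_index: int | None = None
    pixel_size_mm: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D single-channel image")
        if self.level not in LEVELS:
            raise ValueError(f"unknown imaging level {self.level!r}; expected one of {LEVELS}")
        if self.counts.dtype != np.uint16:
            arr = np.asarray(self.counts)
            if arr.min() < 0 or arr.max() > MAX_COUNTS:
                raise ValueError("counts out of unsigned 16-bit range")
            self.counts = arr.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


@dataclass
class TissueLabelMap:
    """Integer tissue-class image partnered with a FluorImage.

    Every pixel carries exactly one code from :data:`TISSUE_CODES`;
    0 marks pixels outside the tissue.
    """

    labels: np.ndarray
    code_map: dict[int, str] = field(default_factory=lambda: dict(TISSUE_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer image")
        present = np.unique(self.labels)
        unknown = set(present.tolist()) - set(self.code_map)
        if unknown:
            raise ValueError(f"label codes {sorted(unknown)} not in the code map")

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of pixels carrying any of the given codes."""
        return np.isin(self.labels, codes)

    def area_fractions(self) -> dict[int, float]:
        """Per-code pixel-area fractions; always sums to 1 over the image."""
        n = self.labels.size
        return {c: float(np.count_nonzero(self.labels == c)) / n for c in self.code_map}
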