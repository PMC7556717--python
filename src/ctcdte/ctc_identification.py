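"""Detection, marker gating and ranking of putative CTCs in tile scans.

A circulating tumor cell is called by the standard immunofluorescence
definition: a nucleated (DAPI+) cell that is cytokeratin-positive
(epithelial origin), CD45-negative (not a leukocyte), with positive
tubulin staining for downstream scoring and positive androgen receptor
staining confirming prostate-cancer origin.  Candidates also have to pass
simple morphology filters (equivalent diameter and circularity).

Segmentation is deliberately minimal — Otsu threshold on the DAPI channel,
hole filling, connected components, a small-object filter — which is
adequate for well-separated cytospun nuclei.  Nuclei merged into a single
component are flagged, not split; watershed separation is out of scope.
Confirmed CTCs are rank-ordered by cytokeratin intensity and at most
``max_cells_per_timepoint`` (default 20) are selected for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .exceptions import ConfigurationError, ValidationError
from .image_io import CANONICAL_CHANNELS, MultichannelStack
from .synthetic_cytospin import CellGroundTruth

#: Gate outcome labels.
POSITIVITY_LABELS = ("DAPI_pos", "CK_pos", "CD45_pos", "TUB_pos", "AR_pos")

#: Markers that must all be positive for a putative-CTC call.
CTC_REQUIRED = ("DAPI_pos", "CK_pos", "TUB_pos", "AR_pos")

#: Radius (px) of the disk used to erode the nuclear mask before labeling.
_ERODE_RADIUS = 2
_ERODE_DISK = np.hypot(*np.mgrid[-2:3, -2:3]) <= float(_ERODE_RADIUS)


@dataclass(frozen=True)
class CellRecord:
    """One detected object in a tile with morphology, intensities and call."""

    cell_id: str
    centroid_px: tuple[float, float]  # (y, x)
    area_px: int
    equivalent_diameter_um: float
    circularity: float
    channel_mean: Mapping[str, float]
    labels: frozenset[str] = frozenset()
    call: str = "rejected"  # "putative_CTC" | "leukocyte" | "rejected"
    merged_candidate: bool = False


@dataclass(frozen=True)
class GateConfig:
    """Positivity thresholds and morphology filters.

    ``thresholds`` maps channel name to an absolute intensity; a channel
    mean greater than or equal to its threshold counts as positive
    (inclusive boundary).  Thresholds can also be estimated from a tile's
    background as ``k * (median + 3 * MAD)`` via :meth:`from_background`.

    The morphology defaults (equivalent diameter 8-30 um, circularity
    >= 0.5) are configuration, not assay constants; the diameter bounds
    refer to the segmented nuclear component.
    """

    thresholds: Mapping[str, float]
    min_diameter_um: float = 8.0
    max_diameter_um: float = 30.0
    min_circularity: float = 0.5
    max_cells_per_timepoint: int = 20
    min_detect_diameter_um: float = 5.0

    def __post_init__(self) -> None:
        for ch, thr in self.thresholds.items():
            if thr <= 0:
                raise ValidationError(f"threshold for {ch!r} must be > 0, got {thr}")
        if not self.min_diameter_um < self.max_diameter_um:
            raise ValidationError("min_diameter_um must be < max_diameter_um")
        if self.max_cells_per_timepoint < 1:
            raise ValidationError("max_cells_per_timepoint must be >= 1")

    @classmethod
    def from_background(
        cls, tile: MultichannelStack, k: float = 3.0, **kwargs
    ) -> "GateConfig":
        """Estimate per-channel thresholds as ``k * (median + 3 * MAD)``.

        With sparse cells the tile-wide median and MAD are dominated by
        background, so this yields a robust positivity floor per channel.
        """
        thresholds = {}
        for ch in tile.channel_names:
            v = tile.channel(ch).ravel()
            med = float(np.median(v))
            mad = float(np.median(np.abs(v - med)))
            thresholds[ch] = max(k * (med + 3.0 * mad), 1e-6)
        return cls(thresholds=thresholds, **kwargs)


@dataclass(frozen=True)
class ConfusionSummary:
    """Detection performance against ground truth; rates are None when undefined."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_cells(tile: MultichannelStack, gates: GateConfig) -> list[CellRecord]:
    """Segment DAPI-positive objects and measure per-channel mean intensities.

    Returns one record per connected nuclear component whose equivalent
    diameter is at least ``gates.min_detect_diameter_um``; records carry no
    gate labels yet (``call`` stays ``"rejected"`` until :func:`gate_cell`).
    Components larger than ``max_diameter_um`` are kept but flagged as
    merged candidates.
    """
    if "DAPI" not in tile.channel_names:
        raise ConfigurationError("tile has no DAPI channel; cannot segment nuclei")
    planes = {ch: tile.channel(ch).max(axis=0).astype(np.float64)
              for ch in tile.channel_names}
    dapi = planes["DAPI"]

    smoothed = ndimage.gaussian_filter(dapi, sigma=1.0)
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    floor = med + 6.0 * mad
    if smoothed.max() <= floor:
        return []
    thr = max(float(threshold_otsu(smoothed)), floor)
    mask = ndimage.binary_fill_holes(smoothed > thr)
    # Components are labeled on the eroded mask: erosion cuts the thin
    # bridges that soft nuclear edges form between adjacent nuclei, so
    # only substantially overlapping nuclei stay merged (and get
    # flagged).  Measurements are taken over the eroded nucleus core,
    # which also reduces edge contamination of the channel means; the
    # equivalent diameter is compensated for the erosion radius.
    mask = ndimage.binary_erosion(mask, structure=_ERODE_DISK)
    labeled = cc_label(mask)

    px = tile.pixel_size_um
    diam_comp_um = 2.0 * _ERODE_RADIUS * px
    min_area = np.pi * (
        max(gates.min_detect_diameter_um - diam_comp_um, 1e-6) / 2.0 / px
    ) ** 2
    records: list[CellRecord] = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        eq_diam_um = region.equivalent_diameter_area * px + diam_comp_um
        perimeter = max(region.perimeter, 1e-9)
        circularity = min(4.0 * np.pi * region.area / perimeter**2, 1.0)
        obj = labeled == region.label
        means = {ch: float(planes[ch][obj].mean()) for ch in tile.channel_names}
        records.append(
            CellRecord(
                cell_id=f"obj_{len(records):04d}",
                centroid_px=tuple(float(c) for c in region.centroid),
                area_px=int(region.area),
                equivalent_diameter_um=float(eq_diam_um),
                circularity=float(circularity),
                channel_mean=means,
                merged_candidate=bool(eq_diam_um > gates.max_diameter_um),
            )
        )
    return records


# ---------------------------------------------------------------------------
# gating and selection
# ---------------------------------------------------------------------------


def gate_cell(record: CellRecord, gates: GateConfig) -> CellRecord:
    """Assign positivity labels and the final call to one record.

    A record is a putative CTC iff DAPI, CK, TUB and AR are positive, CD45
    is negative, and the morphology filters pass; a DAPI+/CD45+ record is
    a leukocyte; everything else is rejected.  Channel mean >= threshold
    counts as positive (inclusive boundary); channels without a configured
    threshold are treated as negative.
    """
    labels = set()
    for ch in CANONICAL_CHANNELS:
        thr = gates.thresholds.get(ch)
        if thr is not None and record.channel_mean.get(ch, 0.0) >= thr:
            labels.add(f"{ch}_pos")
    morphology_ok = (
        gates.min_diameter_um <= record.equivalent_diameter_um <= gates.max_diameter_um
        and record.circularity >= gates.min_circularity
    )
    if (
        all(lbl in labels for lbl in CTC_REQUIRED)
        and "CD45_pos" not in labels
        and morphology_ok
    ):
        call = "putative_CTC"
    elif "DAPI_pos" in labels and "CD45_pos" in labels:
        call = "leukocyte"
    else:
        call = "rejected"
    return replace(record, labels=frozenset(labels), call=call)


def gate_cells(records: Sequence[CellRecord], gates: GateConfig) -> list[CellRecord]:
    """Gate every record (convenience vectorization of :func:`gate_cell`)."""
    return [gate_cell(r, gates) for r in records]


def rank_and_select(
    records: Sequence[CellRecord], gates: GateConfig
) -> list[CellRecord]:
    """Rank putative CTCs by CK intensity (descending) and cap the selection.

    At most ``gates.max_cells_per_timepoint`` cells are returned; ties in
    CK mean are broken by ``cell_id`` ascending, so the output order is
    deterministic and independent of input ordering.
    """
    ctcs = [r for r in records if r.call == "putative_CTC"]
    ctcs.sort(key=lambda r: (-r.channel_mean.get("CK", 0.0), r.cell_id))
    return ctcs[: gates.max_cells_per_timepoint]


# ---------------------------------------------------------------------------
# ground-truth comparison
# ---------------------------------------------------------------------------


def confirm_against_truth(
    called: Sequence[CellRecord],
    truth: Sequence[CellGroundTruth],
    pixel_size_um: float = 1.0,
) -> ConfusionSummary:
    """Match putative-CTC calls to ground-truth CTC centroids.

    A call is a true positive if its centroid lies within one true cell
    radius of an unmatched ground-truth CTC (greedy nearest match); calls
    without a match are false positives, unmatched true CTCs are false
    negatives.  This replaces the manual operator validation step of the
    real assay, which has no algorithmic definition.
    """
    true_ctcs = [t for t in truth if t.kind == "CTC" and t.centroid_px is not None]
    unmatched = set(range(len(true_ctcs)))
    tp = fp = 0
    for rec in called:
        best_j, best_d = None, np.inf
        for j in unmatched:
            t = true_ctcs[j]
            d = float(np.hypot(rec.centroid_px[0] - t.centroid_px[0],
                               rec.centroid_px[1] - t.centroid_px[1]))
            radius_px = t.diameter_um / 2.0 / pixel_size_um
            if d <= radius_px and d < best_d:
                best_j, best_d = j, d
        if best_j is None:
            fp += 1
        else:
            tp += 1
            unmatched.discard(best_j)
    return ConfusionSummary(tp=tp, fp=fp, fn=len(unmatched))


__all__ = [
    "POSITIVITY_LABELS",
    "CTC_REQUIRED",
    "CellRecord",
    "GateConfig",
    "ConfusionSummary",
    "detect_cells",
    "gate_cell",
    "gate_cells",
    "rank_and_select",
    "confirm_against_truth",
]
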