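"""Cell segmentation, stress-granule detection and donut-ratio V5
enrichment scoring.

The quantification stage mirrors a CellProfiler-style per-image analysis:

1. nuclei are thresholded (Otsu) in the Hoechst channel and grown into
   cytoplasm by nearest-nucleus expansion up to ``cytoplasm_radius_px``;
   border-touching cells are discarded;
2. transfected cells are called on mean cytoplasmic V5, either by a global
   Otsu split of the per-cell means or as ``k`` sigma above an
   untransfected/background reference;
3. cytoplasmic TIAL1 spots are detected by difference-of-Gaussians
   band-pass plus a per-cell relative intensity threshold, with an area
   band filter;
4. each granule's V5 enrichment ratio is the median V5 inside the spot
   over the median V5 in the surrounding donut (default 5 px wide,
   excluding all granule pixels and anything outside the owning cell's
   cytoplasm); granules with ratio strictly greater than 1.2 are classed
   V5-enriched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import difference_of_gaussians, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk
from skimage.segmentation import expand_labels

from .synthetic.scenes import ImageScene

__all__ = [
    "SegmentationParams",
    "CellRecord",
    "GranuleRecord",
    "ImageSummary",
    "segment_cells",
    "classify_transfection",
    "detect_granules",
    "score_v5_enrichment",
    "quantify_image",
    "quantify_experiment",
    "match_detections_to_truth",
]


@dataclass(frozen=True)
class SegmentationParams:
    nucleus_min_area_px: int = 40
    cytoplasm_radius_px: float = 20.0
    spot_min_area_px: int = 5
    spot_max_area_px: int = 250
    spot_detection_sigma_px: float = 2.0
    spot_threshold_k: float = 1.3
    v5_positive_method: str = "k_sigma_over_untransfected"
    v5_k: float = 4.0
    #: relative floor on the k-sigma margin so the call stays meaningful
    #: when the reference is (near-)noiseless
    v5_min_contrast: float = 0.10
    donut_width_px: int = 5
    donut_gap_px: int = 0
    enrichment_ratio_threshold: float = 1.2

    def validate(self) -> None:
        if self.donut_width_px < 1:
            raise ValueError("donut_width_px must be >= 1")
        if self.enrichment_ratio_threshold <= 0:
            raise ValueError("enrichment_ratio_threshold must be positive")
        if self.spot_min_area_px > self.spot_max_area_px:
            raise ValueError("spot area band must satisfy min <= max")
        if self.v5_positive_method not in ("otsu_global", "k_sigma_over_untransfected"):
            raise ValueError(f"unknown v5_positive_method {self.v5_positive_method!r}")


@dataclass
class CellRecord:
    cell_id: int
    nucleus_centroid: tuple[float, float]
    nucleus_area: int
    cytoplasm_area: int
    mean_v5: float
    is_transfected: bool | None = None


@dataclass
class GranuleRecord:
    granule_id: int
    cell_id: int
    pixel_count: int
    median_tial1: float
    median_v5_spot: float = np.nan
    median_v5_donut: float = np.nan
    enrichment_ratio: float = np.nan
    is_v5_enriched: bool | None = None
    donut_empty: bool = False
    pixels: tuple = field(default=(), repr=False)  # (rows, cols)


def segment_cells(
    scene: ImageScene, params: SegmentationParams
) -> tuple[list[CellRecord], dict[str, np.ndarray]]:
    """Segment nuclei and assign cytoplasm; returns cell records plus the
    nucleus/cell label images (border-touching cells removed)."""
    params.validate()
    if "nuclei" not in scene.channels:
        raise KeyError("scene has no 'nuclei' channel")
    nuc = scene.channels["nuclei"]
    if np.ptp(nuc) == 0:
        empty = np.zeros(nuc.shape, dtype=np.int32)
        return [], {"nucleus": empty, "cell": empty.copy()}

    thr = threshold_otsu(nuc)
    mask = ndimage.binary_fill_holes(nuc > thr)
    labels, _ = ndimage.label(mask)
    # area filter (strictly below the minimum is discarded)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= params.nucleus_min_area_px)
    keep = keep[keep > 0]
    nucleus_labels = np.where(np.isin(labels, keep), labels, 0).astype(np.int32)

    cell_labels = expand_labels(nucleus_labels, distance=params.cytoplasm_radius_px)

    # discard cells whose cytoplasm touches the image border
    border = np.concatenate(
        [cell_labels[0, :], cell_labels[-1, :], cell_labels[:, 0], cell_labels[:, -1]]
    )
    for lab in np.unique(border[border > 0]):
        cell_labels[cell_labels == lab] = 0
        nucleus_labels[nucleus_labels == lab] = 0

    # relabel sequentially
    old = np.unique(nucleus_labels)
    old = old[old > 0]
    remap = np.zeros(cell_labels.max() + 1, dtype=np.int32)
    remap[old] = np.arange(1, len(old) + 1)
    nucleus_labels = remap[nucleus_labels]
    cell_labels = remap[cell_labels]

    v5 = scene.channels.get("v5")
    cells = []
    for prop in regionprops(nucleus_labels):
        cid = prop.label
        cyto = (cell_labels == cid) & (nucleus_labels == 0)
        mean_v5 = float(v5[cyto].mean()) if v5 is not None and cyto.any() else np.nan
        cells.append(
            CellRecord(
                cell_id=int(cid),
                nucleus_centroid=tuple(prop.centroid),
                nucleus_area=int(prop.area),
                cytoplasm_area=int(cyto.sum()),
                mean_v5=mean_v5,
            )
        )
    return cells, {"nucleus": nucleus_labels, "cell": cell_labels}


def classify_transfection(
    cells: list[CellRecord],
    v5_channel: np.ndarray,
    params: SegmentationParams,
    *,
    labels: dict[str, np.ndarray] | None = None,
    control_stats: tuple[float, float] | None = None,
) -> tuple[list[CellRecord], dict]:
    """Set ``is_transfected`` on each cell from mean cytoplasmic V5.

    ``otsu_global`` splits the per-cell mean distribution; the k-sigma
    method calls a cell positive when its mean exceeds
    ``mean + k * sd`` of an untransfected reference (``control_stats``,
    e.g. from a control well; by default estimated from the non-cell
    background pixels of the same image).  Returns the updated records and
    a log of the method and threshold used.
    """
    means = np.array([c.mean_v5 for c in cells], dtype=float)
    if params.v5_positive_method == "otsu_global":
        if len(means) == 0:
            return cells, {"method": "otsu_global", "threshold": np.nan}
        if np.ptp(means) == 0:
            raise ValueError(
                "all cells have identical mean V5; Otsu split is undefined - "
                "use v5_positive_method='k_sigma_over_untransfected'"
            )
        thr = float(threshold_otsu(means, nbins=max(len(means), 64)))
    else:
        if control_stats is not None:
            mu, sd = control_stats
        else:
            if labels is None:
                raise ValueError("k-sigma method needs labels or control_stats")
            bg = v5_channel[labels["cell"] == 0]
            mu, sd = float(np.mean(bg)), float(np.std(bg))
        thr = mu + max(params.v5_k * sd, params.v5_min_contrast * abs(mu))
    for c in cells:
        c.is_transfected = bool(c.mean_v5 > thr)
    return cells, {"method": params.v5_positive_method, "threshold": thr}


def detect_granules(
    scene: ImageScene,
    cells: list[CellRecord],
    params: SegmentationParams,
    labels: dict[str, np.ndarray],
) -> list[GranuleRecord]:
    """Detect cytoplasmic TIAL1 spots per cell.

    Candidate pixels pass the difference-of-Gaussians band-pass (response
    > 0) and exceed ``spot_threshold_k`` times the cell's median
    cytoplasmic TIAL1; connected components outside the configured area
    band are discarded, and each granule is assigned to the cell
    containing its centroid.
    """
    if "tial1" not in scene.channels:
        raise KeyError("scene has no 'tial1' channel")
    tial1 = scene.channels["tial1"].astype(float)
    if not cells:
        return []
    dog = difference_of_gaussians(tial1, params.spot_detection_sigma_px)
    cell_lab = labels["cell"]
    nuc_lab = labels["nucleus"]
    cyto_all = (cell_lab > 0) & (nuc_lab == 0)

    candidate = np.zeros(tial1.shape, dtype=bool)
    for c in cells:
        cyto = (cell_lab == c.cell_id) & (nuc_lab == 0)
        if not cyto.any():
            continue
        bg = float(np.median(tial1[cyto]))
        candidate |= cyto & (dog > 0) & (tial1 > params.spot_threshold_k * bg)

    comp, n_comp = ndimage.label(candidate)
    granules: list[GranuleRecord] = []
    gid = 0
    for prop in regionprops(comp, intensity_image=tial1):
        if not (params.spot_min_area_px <= prop.area <= params.spot_max_area_px):
            continue
        r, c = (int(round(x)) for x in prop.centroid)
        owner = int(cell_lab[r, c]) if cyto_all[r, c] else 0
        if owner == 0:
            # centroid off-cytoplasm (concave component): majority vote
            rr, cc = np.nonzero(comp == prop.label)
            owners = cell_lab[rr, cc]
            owners = owners[owners > 0]
            if owners.size == 0:
                continue
            owner = int(np.bincount(owners).argmax())
            rr_cc = (rr, cc)
        else:
            rr_cc = np.nonzero(comp == prop.label)
        gid += 1
        granules.append(
            GranuleRecord(
                granule_id=gid,
                cell_id=owner,
                pixel_count=int(prop.area),
                median_tial1=float(np.median(tial1[rr_cc])),
                pixels=rr_cc,
            )
        )
    return granules


def score_v5_enrichment(
    granule: GranuleRecord,
    v5_channel: np.ndarray,
    labels: dict[str, np.ndarray],
    params: SegmentationParams,
    all_spots_mask: np.ndarray,
) -> GranuleRecord:
    """Compute the donut-ratio V5 enrichment of one granule.

    The donut is the dilation of the spot by ``donut_gap_px +
    donut_width_px`` minus the (gap-dilated) spot, minus every granule's
    pixels, intersected with the owning cell's cytoplasm.  The ratio is
    ``median(spot V5) / median(donut V5)``; the enriched flag uses the
    strict inequality ``ratio > enrichment_ratio_threshold``.  An empty
    donut leaves the ratio undefined (the granule still counts in SG
    totals); a zero donut median yields +inf with a warning.
    """
    rr, cc = granule.pixels
    if len(rr) == 0:
        raise ValueError("granule has an empty pixel set")
    h, w = v5_channel.shape
    pad = params.donut_gap_px + params.donut_width_px + 1
    r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad + 1, h)
    c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad + 1, w)

    spot = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    spot[rr - r0, cc - c0] = True
    inner = (
        dilation(spot, disk(params.donut_gap_px)) if params.donut_gap_px else spot
    )
    outer = dilation(inner, disk(params.donut_width_px))
    donut = outer & ~inner
    donut &= ~all_spots_mask[r0:r1, c0:c1]
    cyto_owner = (labels["cell"][r0:r1, c0:c1] == granule.cell_id) & (
        labels["nucleus"][r0:r1, c0:c1] == 0
    )
    donut &= cyto_owner

    v5 = v5_channel[r0:r1, c0:c1]
    granule.median_v5_spot = float(np.median(v5[spot]))
    if not donut.any():
        granule.donut_empty = True
        granule.median_v5_donut = np.nan
        granule.enrichment_ratio = np.nan
        granule.is_v5_enriched = None
        return granule
    granule.median_v5_donut = float(np.median(v5[donut]))
    if granule.median_v5_donut == 0:
        warnings.warn(
            f"granule {granule.granule_id}: donut median V5 is zero; "
            "enrichment ratio reported as +inf",
            stacklevel=2,
        )
        granule.enrichment_ratio = np.inf
    else:
        granule.enrichment_ratio = granule.median_v5_spot / granule.median_v5_donut
    granule.is_v5_enriched = bool(
        granule.enrichment_ratio > params.enrichment_ratio_threshold
    )
    return granule


@dataclass
class ImageSummary:
    """Per-image quantification: cell table, granule table, and the
    condition-level readouts split by transfection status."""

    scene_id: object
    cells: pd.DataFrame       # cell_id, is_transfected, n_sg, n_enriched, n_nonenriched, n_unscored
    granules: list[GranuleRecord]
    log: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict, repr=False)

    @property
    def n_cells_analyzed(self) -> int:
        return len(self.cells)

    @property
    def n_transfected(self) -> int:
        return int(self.cells["is_transfected"].sum()) if len(self.cells) else 0

    def _subset(self, transfected: bool | None) -> pd.DataFrame:
        if transfected is None or not len(self.cells):
            return self.cells
        return self.cells[self.cells["is_transfected"] == transfected]

    def fraction_cells_with_sg(self, transfected: bool | None = None) -> float:
        sub = self._subset(transfected)
        return float((sub["n_sg"] > 0).mean()) if len(sub) else np.nan

    def mean_sg_per_cell(self, transfected: bool | None = None) -> float:
        sub = self._subset(transfected)
        return float(sub["n_sg"].mean()) if len(sub) else np.nan

    def to_row(self, population: bool | None = True) -> dict:
        """Flatten to the well-level response columns; ``population``
        selects transfected (True, default), untransfected (False) or all
        cells (None)."""
        sub = self._subset(population)
        n = len(sub)
        return dict(
            scene_id=self.scene_id,
            n_cells_analyzed=n,
            n_transfected=self.n_transfected,
            prop_sg_cells=float((sub["n_sg"] > 0).mean()) if n else np.nan,
            mean_sg_per_cell=float(sub["n_sg"].mean()) if n else np.nan,
            mean_enriched_sg_per_cell=float(sub["n_enriched"].mean()) if n else np.nan,
            mean_nonenriched_sg_per_cell=float(sub["n_nonenriched"].mean()) if n else np.nan,
        )


def quantify_image(
    scene: ImageScene,
    params: SegmentationParams | None = None,
    *,
    control_stats: tuple[float, float] | None = None,
) -> ImageSummary:
    """Full per-image pipeline: segment, classify transfection, detect
    granules, score enrichment, tabulate per-cell counts."""
    params = params or SegmentationParams()
    cells, labels = segment_cells(scene, params)
    log: dict = {}
    if cells:
        cells, log = classify_transfection(
            cells, scene.channels["v5"], params, labels=labels,
            control_stats=control_stats,
        )
    granules = detect_granules(scene, cells, params, labels) if cells else []

    all_spots = np.zeros(scene.shape, dtype=bool)
    for g in granules:
        all_spots[g.pixels] = True
    for g in granules:
        score_v5_enrichment(g, scene.channels["v5"], labels, params, all_spots)

    rows = []
    for c in cells:
        mine = [g for g in granules if g.cell_id == c.cell_id]
        rows.append(
            dict(
                cell_id=c.cell_id,
                is_transfected=bool(c.is_transfected),
                mean_v5=c.mean_v5,
                n_sg=len(mine),
                n_enriched=sum(1 for g in mine if g.is_v5_enriched is True),
                n_nonenriched=sum(1 for g in mine if g.is_v5_enriched is False),
                n_unscored=sum(1 for g in mine if g.is_v5_enriched is None),
            )
        )
    cell_df = pd.DataFrame(
        rows, columns=["cell_id", "is_transfected", "mean_v5", "n_sg",
                       "n_enriched", "n_nonenriched", "n_unscored"],
    )
    return ImageSummary(
        scene_id=scene.meta.get("scene_id"), cells=cell_df, granules=granules,
        log=log, labels=labels,
    )


def quantify_experiment(
    collection, params: SegmentationParams | None = None, population: bool | None = True
) -> pd.DataFrame:
    """Quantify every scene of an experiment collection into the per-image
    summary table consumed by ``sgstats.aggregate_wells``."""
    rows = []
    for meta, scene in collection:
        summary = quantify_image(scene, params)
        row = summary.to_row(population)
        row.update({k: meta[k] for k in ("construct", "treatment", "replicate")})
        row["scene_id"] = meta["scene_id"]
        rows.append(row)
    return pd.DataFrame(rows)


def match_cells_to_truth(labels: dict[str, np.ndarray], truth) -> dict[int, int]:
    """Map each segmented cell id to the ground-truth cell whose nucleus it
    overlaps most (segmentation label order differs from placement order)."""
    mapping: dict[int, int] = {}
    seg = labels["nucleus"]
    for cid in np.unique(seg[seg > 0]):
        overlap = truth.nucleus_labels[seg == cid]
        overlap = overlap[overlap > 0]
        mapping[int(cid)] = int(np.bincount(overlap).argmax()) if overlap.size else 0
    return mapping


def match_detections_to_truth(granules: list[GranuleRecord], truth) -> pd.DataFrame:
    """One row per detected granule with the overlapping ground-truth spot
    (0 if none); used to score precision/recall on synthetic scenes."""
    rows = []
    for g in granules:
        overlap = truth.spot_labels[g.pixels]
        overlap = overlap[overlap > 0]
        spot_id = int(np.bincount(overlap).argmax()) if overlap.size else 0
        rows.append(dict(granule_id=g.granule_id, cell_id=g.cell_id,
                         truth_spot_id=spot_id))
    return pd.DataFrame(rows, columns=["granule_id", "cell_id", "truth_spot_id"])
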