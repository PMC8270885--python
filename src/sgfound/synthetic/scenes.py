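"""Synthetic stress-granule microscopy scenes with ground truth.

Emulates three-channel widefield acquisitions of transfected HeLa cells
(nuclei/Hoechst, V5 epitope tag, TIAL1 stress-granule marker): nuclei are
non-overlapping ellipses, cytoplasm an irregular lobed region around each
nucleus (overlaps resolved by nearest nucleus), stress granules are 2-D
Gaussian bumps planted in the TIAL1 channel, and V5 enrichment of a
granule is a co-located V5 bump calibrated so the median V5 over the spot
is about ``enrichment_factor`` times the local cytoplasmic V5.  Noise is
additive Gaussian, clipped at zero.  All intensities are unitless floats.

Everything is deterministic given the config seed, and every scene carries
its ground truth (cell and spot label images, transfection and enrichment
flags) so the quantification stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

__all__ = ["SceneConfig", "SceneTruth", "ImageScene", "simulate_sg_scene",
           "simulate_experiment", "ExperimentCollection"]

CHANNELS = ("nuclei", "v5", "tial1")


@dataclass(frozen=True)
class SceneConfig:
    """Generative parameters of one synthetic scene (one field of view).

    Defaults emulate a 20x acquisition of a moderately confluent well:
    ~25 analyzable cells per field, half transfected, stress-level granule
    load of ~2 SGs per cell, and a V5 enrichment factor of 1.5 against the
    classification threshold of 1.2.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 25
    transfected_fraction: float = 0.5
    sg_rate: float = 2.0
    sg_rate_untransfected: float = 2.0
    enriched_fraction: float = 0.5
    enrichment_factor: float = 1.5
    spot_radius_px: tuple[float, float] = (3.0, 5.0)
    noise_sd: float = 4.0
    background_level: float = 100.0
    nucleus_axes_px: tuple[float, float] = (7.0, 11.0)
    cytoplasm_radius_px: float = 14.0
    nucleus_level: float = 300.0
    v5_transfected_level: float = 150.0
    tial1_cell_level: float = 60.0
    sg_amplitude: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.transfected_fraction <= 1:
            raise ValueError("transfected_fraction must be in [0, 1]")
        if not 0 <= self.enriched_fraction <= 1:
            raise ValueError("enriched_fraction must be in [0, 1]")
        if self.sg_rate < 0 or self.sg_rate_untransfected < 0:
            raise ValueError("SG rates must be nonnegative")
        if self.enrichment_factor <= 1:
            raise ValueError("enrichment_factor must exceed 1")
        if self.spot_radius_px[0] < 2:
            raise ValueError("spot radii must be at least 2 px")
        if self.spot_radius_px[0] > self.spot_radius_px[1]:
            raise ValueError("spot_radius_px range must be (lo, hi)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")


@dataclass
class SceneTruth:
    """Ground-truth labels of a synthetic scene."""

    cell_labels: np.ndarray          # 0 background, 1..n cell id (incl. nucleus)
    nucleus_labels: np.ndarray
    spot_labels: np.ndarray          # 0 background, 1..K spot id
    transfected: np.ndarray          # bool, index cell_id - 1
    spots: pd.DataFrame              # spot_id, cell_id, row, col, radius, enriched

    @property
    def n_cells(self) -> int:
        return len(self.transfected)

    @property
    def n_spots(self) -> int:
        return len(self.spots)


@dataclass
class ImageScene:
    """Three-channel scene; ``truth`` is populated for synthetic scenes."""

    channels: dict[str, np.ndarray]
    truth: SceneTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator):
    """Sample non-overlapping nucleus ellipses fully inside the usable area.

    Placement keeps a margin so that cytoplasm (and any planted spot) never
    touches the image border; fails explicitly if the field is too crowded.
    """
    h, w = cfg.image_size
    margin = cfg.nucleus_axes_px[1] + cfg.cytoplasm_radius_px * 1.2 + cfg.spot_radius_px[1] + 2
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        if cfg.n_cells > 0:
            raise ValueError(
                f"image_size {cfg.image_size} too small for the cell geometry "
                f"(needs margin {margin:.0f} px per side)"
            )
        return []
    cells = []
    max_tries = 300 * max(cfg.n_cells, 1)
    tries = 0
    while len(cells) < cfg.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping nuclei in a "
                f"{h}x{w} image after {max_tries} tries; reduce n_cells or "
                "enlarge image_size"
            )
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        a = rng.uniform(*cfg.nucleus_axes_px)
        b = rng.uniform(*cfg.nucleus_axes_px)
        theta = rng.uniform(0, np.pi)
        # conservative circle test: nuclei must not overlap
        r_eff = max(a, b)
        ok = all(
            np.hypot(r - rc, c - cc) > r_eff + max(ac, bc) + 2
            for rc, cc, ac, bc, _ in cells
        )
        if ok:
            cells.append((r, c, a, b, theta))
    return cells


def _cell_regions(cfg: SceneConfig, nuclei, rng: np.random.Generator):
    """Rasterize nuclei and grow irregular cytoplasm; overlapping claims go
    to the nearest nucleus centroid."""
    h, w = cfg.image_size
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    claim_dist = np.full((h, w), np.inf)

    for i, (r, c, a, b, theta) in enumerate(nuclei, start=1):
        rr, cc = draw_ellipse(r, c, a, b, shape=(h, w), rotation=theta)
        nucleus_labels[rr, cc] = i
        # irregular cytoplasm boundary: radius modulated by 2-4 angular lobes
        n_lobes = rng.integers(2, 5)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.05, 0.2)
        scale = rng.uniform(0.9, 1.1)

        reach = int(np.ceil(cfg.cytoplasm_radius_px * 1.3 * scale))
        r0 = max(int(r) - int(np.ceil(max(a, b))) - reach, 0)
        r1 = min(int(r) + int(np.ceil(max(a, b))) + reach + 1, h)
        c0 = max(int(c) - int(np.ceil(max(a, b))) - reach, 0)
        c1 = min(int(c) + int(np.ceil(max(a, b))) + reach + 1, w)
        crop_nuc = nucleus_labels[r0:r1, c0:c1] == i
        dist = ndimage.distance_transform_edt(~crop_nuc)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        ang = np.arctan2(yy - r, xx - c)
        radius_at = cfg.cytoplasm_radius_px * scale * (1 + amp * np.sin(n_lobes * ang + phase))
        cand = dist <= radius_at
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        take = cand & (d2 < claim_dist[r0:r1, c0:c1])
        cell_labels[r0:r1, c0:c1][take] = i
        claim_dist[r0:r1, c0:c1][take] = d2[take]

    # nuclei always belong to their own cell
    cell_labels[nucleus_labels > 0] = nucleus_labels[nucleus_labels > 0]
    return nucleus_labels, cell_labels


def _gaussian_bump(shape, center, sigma, amplitude):
    """Additive 2-D Gaussian on a crop (evaluated out to 4 sigma)."""
    h, w = shape
    r, c = center
    ext = int(np.ceil(4 * sigma))
    r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, h)
    c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    bump = amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    return (slice(r0, r1), slice(c0, c1)), bump


def simulate_sg_scene(config: SceneConfig) -> ImageScene:
    """Generate one synthetic scene with full ground truth.

    Per-cell granule counts are Poisson with the transfection-dependent
    rate; each granule is placed entirely within its cell's cytoplasm.
    Runs are bit-identical for identical configs (single seeded RNG).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size

    nuclei = _place_nuclei(config, rng)
    if nuclei:
        nucleus_labels, cell_labels = _cell_regions(config, nuclei, rng)
    else:
        nucleus_labels = np.zeros((h, w), dtype=np.int32)
        cell_labels = np.zeros((h, w), dtype=np.int32)

    n_cells = len(nuclei)
    n_transfected = int(round(config.transfected_fraction * n_cells))
    transfected = np.zeros(n_cells, dtype=bool)
    if n_cells:
        transfected[rng.permutation(n_cells)[:n_transfected]] = True

    nuclei_ch = np.full((h, w), config.background_level)
    v5_ch = np.full((h, w), config.background_level)
    tial1_ch = np.full((h, w), config.background_level)

    nuclei_ch[nucleus_labels > 0] += config.nucleus_level
    for i in range(1, n_cells + 1):
        mask = cell_labels == i
        tial1_ch[mask] += config.tial1_cell_level
        if transfected[i - 1]:
            v5_ch[mask] += config.v5_transfected_level

    # plant granules
    spot_labels = np.zeros((h, w), dtype=np.int32)
    spot_rows = []
    spot_id = 0
    for i in range(1, n_cells + 1):
        rate = config.sg_rate if transfected[i - 1] else config.sg_rate_untransfected
        count = rng.poisson(rate)
        if count == 0:
            continue
        cyto = (cell_labels == i) & (nucleus_labels == 0)
        edt = ndimage.distance_transform_edt(cyto)
        yy, xx = np.mgrid[0:h, 0:w]
        placed: list[tuple[int, int, float]] = []
        for _ in range(count):
            radius = rng.uniform(*config.spot_radius_px)
            ok = edt >= radius + 1
            # keep spots in the same cell separated so they stay resolvable
            for pr, pc, prad in placed:
                ok &= (yy - pr) ** 2 + (xx - pc) ** 2 > (radius + prad + 3) ** 2
            valid = np.flatnonzero(ok.ravel())
            if valid.size == 0:
                # crowded cell: fall back to the deepest cytoplasmic pixel
                # farthest from the spots already placed
                score = edt.copy()
                for pr, pc, prad in placed:
                    score = np.minimum(score, np.hypot(yy - pr, xx - pc))
                flat = int(np.argmax(score))
                radius = max(2.0, min(radius, float(edt.ravel()[flat]) - 1.0))
                valid = np.array([flat])
            pick = int(valid[rng.integers(valid.size)])
            r, c = divmod(pick, w)
            placed.append((r, c, radius))
            spot_id += 1
            sigma = radius / 2.0
            sl, bump = _gaussian_bump((h, w), (r, c), sigma, config.sg_amplitude)
            tial1_ch[sl] += bump
            rr, cc = draw_ellipse(r, c, radius, radius, shape=(h, w))
            spot_labels[rr, cc] = spot_id
            # V5 enrichment only exists where there is V5, i.e. in
            # transfected cells; untransfected spots are never enriched
            enriched = bool(rng.random() < config.enriched_fraction) and bool(
                transfected[i - 1]
            )
            if enriched:
                local_v5 = config.background_level + config.v5_transfected_level
                # median of a Gaussian over the spot disk is amplitude*e^-1
                amp = (config.enrichment_factor - 1.0) * local_v5 * np.e
                sl2, bump2 = _gaussian_bump((h, w), (r, c), sigma, amp)
                v5_ch[sl2] += bump2
            spot_rows.append(dict(spot_id=spot_id, cell_id=i, row=r, col=c,
                                  radius=radius, enriched=enriched))

    if config.noise_sd > 0:
        for ch in (nuclei_ch, v5_ch, tial1_ch):
            ch += rng.normal(0.0, config.noise_sd, size=(h, w))
    nuclei_ch = np.clip(nuclei_ch, 0, None)
    v5_ch = np.clip(v5_ch, 0, None)
    tial1_ch = np.clip(tial1_ch, 0, None)

    spots = pd.DataFrame(
        spot_rows, columns=["spot_id", "cell_id", "row", "col", "radius", "enriched"]
    )
    truth = SceneTruth(cell_labels=cell_labels, nucleus_labels=nucleus_labels,
                       spot_labels=spot_labels, transfected=transfected, spots=spots)
    return ImageScene(
        channels={"nuclei": nuclei_ch, "v5": v5_ch, "tial1": tial1_ch},
        truth=truth,
    )


@dataclass
class ExperimentCollection:
    """Scenes of a full design plus their condition metadata."""

    scenes: list[ImageScene]
    metadata: pd.DataFrame  # scene_id, construct, treatment, replicate

    def __len__(self) -> int:
        return len(self.scenes)

    def __iter__(self):
        return iter(zip(self.metadata.to_dict("records"), self.scenes))


def simulate_experiment(design) -> ExperimentCollection:
    """Simulate one scene per design row.

    ``design`` is an iterable of ``(construct, treatment, replicate,
    SceneConfig)`` rows; rows must be unique on (construct, treatment,
    replicate, seed) and share the image geometry.
    """
    rows = list(design)
    keys = [(c, t, r, cfg.seed) for c, t, r, cfg in rows]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate design rows (same condition and seed)")
    geoms = {cfg.image_size for _, _, _, cfg in rows}
    if len(geoms) > 1:
        raise ValueError(f"designs must share image geometry, got {geoms}")

    scenes, meta = [], []
    for i, (construct, treatment, replicate, cfg) in enumerate(rows):
        scene = simulate_sg_scene(cfg)
        scene.meta = dict(scene_id=i, construct=construct,
                          treatment=treatment, replicate=replicate)
        scenes.append(scene)
        meta.append(scene.meta)
    return ExperimentCollection(
        scenes=scenes,
        metadata=pd.DataFrame(meta, columns=["scene_id", "construct",
                                             "treatment", "replicate"]),
    )
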