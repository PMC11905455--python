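"""Synthetic data generators with known ground truth.

Three generators mirror the three data modalities the pipeline consumes:

* :func:`simulate_proteomics` — a label-free protein intensity matrix with
  AT8-pulldown and antibody-omission control columns per disease case,
  spiked-in associated proteins, and logistic missing-not-at-random dropout.
* :func:`simulate_histology` — a two-channel (AT8 + candidate) lesion image
  where each lesion's candidate overlap fraction is painted to pixel
  resolution, with blob-, thread- and corona-shaped lesions.
* :func:`simulate_brightfield_dab` — an H-DAB brightfield composite built by
  Beer-Lambert forward synthesis with a known percent tau burden.

Every generator is deterministic under a fixed seed and returns the matching
ground truth so downstream stages can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.color import rgb_from_hed
from skimage.draw import disk as draw_disk
from skimage.measure import regionprops
from skimage.morphology import dilation, disk as disk_footprint

from .datatypes import ConfigurationError, IntensityMatrix, LesionROI, MultichannelImage

DISEASES = ("AD", "CBD", "PiD", "PSP")


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

@dataclass
class ProteomicsSimConfig:
    """Study-design parameters for the proteomics generator.

    Intensities are generated on the log2 scale: a per-protein baseline
    ``Normal(base_log_mean, base_log_sd)`` plus replicate noise
    ``Normal(0, noise_log_sd)``. Associated proteins gain
    ``enrichment_log2fc`` in the pulldown condition (shared proteins in every
    disease, disease-specific ones only in theirs). Dropout follows a
    logistic missing-not-at-random model: the probability that an entry is
    missing decreases with its log2 intensity, crossing 50% at
    ``dropout_midpoint`` with steepness ``dropout_slope``.
    """

    n_proteins: int = 1000
    diseases: tuple = DISEASES
    n_cases_per_disease: int = 6
    frac_shared_associated: float = 0.05
    frac_disease_specific: float = 0.02
    enrichment_log2fc: float = 3.0
    base_log_mean: float = 20.0
    base_log_sd: float = 2.0
    noise_log_sd: float = 0.5
    dropout_midpoint: float = 16.5
    dropout_slope: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_shared_associated + \
            self.frac_disease_specific * len(self.diseases)
        if not (0 <= self.frac_shared_associated <= 1
                and 0 <= self.frac_disease_specific <= 1 and total <= 1):
            raise ConfigurationError("associated fractions must lie in [0,1] "
                                     "and sum to at most 1")
        if self.n_cases_per_disease < 2:
            raise ConfigurationError("need at least 2 cases per disease")
        if self.base_log_sd <= 0 or self.noise_log_sd <= 0:
            raise ConfigurationError("standard deviations must be positive")
        if self.n_proteins < 1 or not self.diseases:
            raise ConfigurationError("need proteins and at least one disease")


def simulate_proteomics(config: ProteomicsSimConfig
                        ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Generate an intensity matrix plus a per-protein truth table.

    Returns
    -------
    matrix
        :class:`IntensityMatrix` with one column per
        (disease, case, condition); missing entries are NaN.
    truth
        DataFrame indexed by protein id with a ``label`` column taking
        values ``null``, ``shared_associated`` or ``specific:<disease>``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    proteins = np.array([f"P{i:05d}" for i in range(cfg.n_proteins)])

    # partition proteins into truth classes
    n_shared = int(round(cfg.frac_shared_associated * cfg.n_proteins))
    n_spec = int(round(cfg.frac_disease_specific * cfg.n_proteins))
    order = rng.permutation(cfg.n_proteins)
    labels = np.full(cfg.n_proteins, "null", dtype=object)
    pos = 0
    labels[order[pos:pos + n_shared]] = "shared_associated"
    pos += n_shared
    for d in cfg.diseases:
        labels[order[pos:pos + n_spec]] = f"specific:{d}"
        pos += n_spec

    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, cfg.n_proteins)

    columns, col_meta = [], []
    data = {}
    for d in cfg.diseases:
        enriched = (labels == "shared_associated") | (labels == f"specific:{d}")
        for c in range(1, cfg.n_cases_per_disease + 1):
            for cond in ("pulldown", "control"):
                sid = f"{d}_case{c}_{cond}"
                log2_int = base + rng.normal(0, cfg.noise_log_sd,
                                             cfg.n_proteins)
                if cond == "pulldown":
                    log2_int = log2_int + enriched * cfg.enrichment_log2fc
                p_miss = expit(-cfg.dropout_slope
                               * (log2_int - cfg.dropout_midpoint))
                vals = np.exp2(log2_int)
                vals[rng.random(cfg.n_proteins) < p_miss] = np.nan
                data[sid] = vals
                columns.append(sid)
                col_meta.append((sid, d, f"{d}_case{c}", cond))

    values = pd.DataFrame(data, index=proteins)[columns]
    meta = pd.DataFrame(col_meta, columns=["sample_id", "disease", "case",
                                           "condition"]).set_index("sample_id")
    truth = pd.DataFrame({"label": labels}, index=proteins)
    return IntensityMatrix(values=values, meta=meta), truth


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------

@dataclass
class LesionSpec:
    """One lesion to paint: shape, placement, and true overlap fraction."""

    shape: str                      # blob | thread | corona
    center: tuple[int, int]
    size: float                     # blob/corona radius or thread step count
    true_overlap_fraction: float
    width: int = 2                  # thread dilation half-width (px)

    def __post_init__(self) -> None:
        if self.shape not in ("blob", "thread", "corona"):
            raise ConfigurationError(f"unknown lesion shape {self.shape!r}")
        if not 0.0 <= self.true_overlap_fraction <= 1.0:
            raise ConfigurationError("overlap fraction must lie in [0,1]")


@dataclass
class HistologySimConfig:
    """Canvas and lesion layout for the two-channel generator."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.325
    lesions: list = field(default_factory=list)
    candidate_background_level: float = 0.0
    noise_sd: float = 0.0
    foreground_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.noise_sd < 0 or self.candidate_background_level < 0:
            raise ConfigurationError("noise/background must be >= 0")


def _blob_mask(shape, center, radius) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=None)
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ConfigurationError(f"lesion at {center} exceeds canvas {shape}")
    m[rr, cc] = True
    return m


def _aspect_ratio(mask: np.ndarray) -> float:
    """Fitted-ellipse major/minor axis ratio from second-order moments."""
    props = regionprops(mask.astype(np.uint8))
    if not props:
        return 1.0
    p = props[0]
    if p.axis_minor_length == 0:
        return np.inf
    return p.axis_major_length / p.axis_minor_length


def _thread_mask(shape, center, n_steps, width, rng,
                 min_aspect=3.0, max_tries=50) -> np.ndarray:
    """Random-walk polyline dilated to ``width``; regenerated until the
    fitted-ellipse aspect ratio exceeds ``min_aspect``."""
    n_steps = int(n_steps)
    for _ in range(max_tries):
        # direction drifts slowly -> elongated, thread-like track
        ang = rng.uniform(0, 2 * np.pi)
        r, c = float(center[0]), float(center[1])
        pts = [(r, c)]
        for _ in range(n_steps):
            ang += rng.normal(0, 0.25)
            r += np.sin(ang)
            c += np.cos(ang)
            pts.append((r, c))
        rows = np.clip(np.round([p[0] for p in pts]).astype(int),
                       0, shape[0] - 1)
        cols = np.clip(np.round([p[1] for p in pts]).astype(int),
                       0, shape[1] - 1)
        m = np.zeros(shape, dtype=bool)
        m[rows, cols] = True
        m = dilation(m, disk_footprint(max(1, width // 2)))
        if _aspect_ratio(m) > min_aspect:
            return m
    raise ConfigurationError("could not generate a thread with the required "
                             "aspect ratio")


def _corona_masks(shape, center, radius, rng) -> tuple[np.ndarray, np.ndarray]:
    """Annulus of Gaussian puncta (AT8 mask) + filled-annulus ROI,
    emulating an astrocytic-plaque corona."""
    roi = _blob_mask(shape, center, radius + 3)
    puncta = np.zeros(shape, dtype=bool)
    n_puncta = max(8, int(2 * np.pi * radius / 4))
    for ang in rng.uniform(0, 2 * np.pi, n_puncta):
        pr = int(round(center[0] + radius * np.sin(ang)))
        pc = int(round(center[1] + radius * np.cos(ang)))
        puncta |= _blob_mask(shape, (pr, pc), 2.5)
    return puncta, roi


def simulate_histology(config: HistologySimConfig
                       ) -> tuple[MultichannelImage, dict]:
    """Paint the AT8 and candidate channels plus per-lesion ground truth.

    For each lesion a random subset of exactly ``round(f * N)`` of its N
    AT8-positive pixels is painted in the candidate channel, so the true
    overlap fraction is controlled to pixel resolution before noise.

    Returns the image and a truth dict with ``rois`` (list of
    :class:`LesionROI`), ``table`` (per-lesion DataFrame with the realized
    overlap fraction) and ``at8_mask`` / ``candidate_mask`` (noiseless).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.image_shape)
    at8 = np.zeros(shape, dtype=bool)
    cand = np.zeros(shape, dtype=bool)
    rois, records = [], []

    shape2type = {"blob": "NFT", "thread": "NT", "corona": "AP"}
    for i, les in enumerate(cfg.lesions, start=1):
        if les.shape == "blob":
            m = _blob_mask(shape, les.center, les.size)
            roi_mask = dilation(m, disk_footprint(2))
        elif les.shape == "thread":
            m = _thread_mask(shape, les.center, les.size, les.width, rng)
            roi_mask = dilation(m, disk_footprint(2))
        else:
            m, roi_mask = _corona_masks(shape, les.center, les.size, rng)
        at8 |= m
        idx = np.flatnonzero(m)
        n_paint = int(round(les.true_overlap_fraction * idx.size))
        chosen = rng.choice(idx, size=n_paint, replace=False)
        painted = np.zeros(shape, dtype=bool)
        painted.flat[chosen] = True
        cand |= painted
        ltype = shape2type[les.shape]
        rois.append(LesionROI(mask=roi_mask, type=ltype,
                              provenance="manual", label=i))
        records.append({"label": i, "type": ltype, "shape": les.shape,
                        "n_at8_px": int(idx.size),
                        "true_fraction": n_paint / idx.size if idx.size else 0.0})

    px = np.zeros(shape + (2,), dtype=float)
    px[:, :, 0] = np.where(at8, cfg.foreground_level, 0.0)
    px[:, :, 1] = np.where(cand, cfg.foreground_level,
                           cfg.candidate_background_level)
    if cfg.noise_sd > 0:
        px = np.clip(px + rng.normal(0, cfg.noise_sd, px.shape), 0, None)

    img = MultichannelImage(pixels=px, channel_names=["AT8", "candidate"],
                            pixel_size_um=cfg.pixel_size_um)
    truth = {"rois": rois, "table": pd.DataFrame(records),
             "at8_mask": at8, "candidate_mask": cand}
    return img, truth


# ---------------------------------------------------------------------------
# brightfield H-DAB
# ---------------------------------------------------------------------------

@dataclass
class BrightfieldSimConfig:
    """H-DAB composite with a target DAB burden fraction over tissue."""

    image_shape: tuple[int, int] = (512, 512)
    burden_fraction: float = 0.10
    hematoxylin_od: float = 0.5
    dab_od: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burden_fraction <= 1.0:
            raise ConfigurationError("burden_fraction must lie in [0,1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _burden_mask(shape, fraction, rng) -> np.ndarray:
    """Random disks until the painted fraction reaches the target
    (the last disk is trimmed pixel-wise to land exactly on it)."""
    target = int(round(fraction * shape[0] * shape[1]))
    m = np.zeros(shape, dtype=bool)
    while m.sum() < target:
        r = rng.integers(3, max(4, shape[0] // 20))
        center = (int(rng.integers(r, shape[0] - r)),
                  int(rng.integers(r, shape[1] - r)))
        m |= _blob_mask(shape, center, r)
    excess = int(m.sum()) - target
    if excess > 0:
        on = np.flatnonzero(m)
        m.flat[rng.choice(on, size=excess, replace=False)] = False
    return m


def simulate_brightfield_dab(config: BrightfieldSimConfig
                             ) -> tuple[np.ndarray, dict]:
    """Compose an RGB brightfield image by Beer-Lambert forward synthesis.

    Hematoxylin optical density is laid down everywhere (the tissue), DAB
    optical density only on the burden mask; transmitted intensity is
    ``I = 256 * 10^(-OD) - 1`` per channel, the exact inverse of the
    measurement-side transform. Returns the uint8 RGB image and a truth dict
    with the burden mask and true burden percentage.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.image_shape)
    mask = _burden_mask(shape, cfg.burden_fraction, rng) \
        if cfg.burden_fraction > 0 else np.zeros(shape, dtype=bool)

    conc = np.zeros(shape + (3,), dtype=float)        # H, E, DAB
    conc[:, :, 0] = cfg.hematoxylin_od
    conc[:, :, 2] = np.where(mask, cfg.dab_od, 0.0)
    od = conc @ rgb_from_hed                          # per-RGB-channel OD
    if cfg.noise_sd > 0:
        od = np.clip(od + rng.normal(0, cfg.noise_sd, od.shape), 0, None)
    rgb = np.clip(256.0 * np.power(10.0, -od) - 1.0, 0, 255)
    rgb = rgb.astype(np.uint8)

    truth = {"burden_mask": mask,
             "true_burden_pct": 100.0 * mask.sum() / mask.size}
    return rgb, truth
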