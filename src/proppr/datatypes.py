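"""Core in-memory containers shared across the pipeline.

The proteomics side of the pipeline operates on an :class:`IntensityMatrix`
(proteins x samples, with per-sample annotations distinguishing AT8 pulldowns
from antibody-omission controls), the imaging side on a
:class:`MultichannelImage` with micrometre calibration plus lesion ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Conditions a sample can be in: AT8 pulldown, or antibody-omission control.
CONDITIONS = ("pulldown", "control")

#: Lesion type vocabulary used throughout the co-localization pipeline.
LESION_TYPES = (
    "NFT", "PT", "TANC", "GLO-NFT", "BN", "NT", "NP",
    "AP", "TA", "CB", "PB", "GT", "SPL",
)

#: Per-lesion co-localization categories, strongest first.
CATEGORIES = ("strong", "moderate", "weak", "negative")


class ConfigurationError(ValueError):
    """Raised for invalid configuration or malformed inputs."""


@dataclass
class IntensityMatrix:
    """Protein-level label-free quantities with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein accession, one column per sample.
        Missing quantities are NaN; present quantities are >= 0.
    meta
        DataFrame indexed by sample id with columns ``disease``, ``case``
        and ``condition`` (``pulldown`` or ``control``).
    gene_symbols
        Optional accession -> gene symbol mapping (Series indexed like
        ``values``).
    log_scale
        False for raw non-negative quantities; True once log-transformed
        (signed values are then legal).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    gene_symbols: pd.Series | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v, meta = self.values, self.meta
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate protein ids: {dups[:5]}")
        missing_meta = [s for s in v.columns if s not in meta.index]
        if missing_meta:
            raise ConfigurationError(
                f"samples absent from metadata: {missing_meta}")
        for col in ("disease", "case", "condition"):
            if col not in meta.columns:
                raise ConfigurationError(f"metadata lacks column {col!r}")
        bad = set(meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ConfigurationError(f"unknown conditions: {sorted(bad)}")
        arr = v.to_numpy(dtype=float)
        if not self.log_scale and np.nanmin(arr, initial=0.0) < 0:
            raise ConfigurationError("negative intensities present")

    # -- convenience selectors -------------------------------------------

    @property
    def diseases(self) -> list[str]:
        return list(pd.unique(self.meta.loc[self.values.columns, "disease"]))

    def samples(self, disease: str | None = None,
                condition: str | None = None) -> list[str]:
        """Sample ids filtered by disease and/or condition."""
        m = self.meta.loc[self.values.columns]
        keep = pd.Series(True, index=m.index)
        if disease is not None:
            keep &= m["disease"] == disease
        if condition is not None:
            keep &= m["condition"] == condition
        return list(m.index[keep])

    def subset(self, samples: list[str]) -> "IntensityMatrix":
        return replace(self, values=self.values[samples],
                       meta=self.meta.loc[samples])


@dataclass
class MultichannelImage:
    """Calibrated multichannel fluorescence image (rows x cols x channels)."""

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ConfigurationError("pixels must be rows x cols x channels")
        if self.pixels.shape[2] != len(self.channel_names):
            raise ConfigurationError("channel_names/pixels mismatch")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.pixels.min() < 0:
            raise ConfigurationError("negative intensities")

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"no channel {name!r}; have {self.channel_names}") from None
        return self.pixels[:, :, i]


@dataclass
class BinaryMask:
    """Boolean mask with provenance of how it was thresholded."""

    mask: np.ndarray
    channel: str = ""
    method: str = ""
    threshold: float = float("nan")
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class LesionROI:
    """One lesion region of interest.

    ``provenance`` is ``manual`` for hand-drawn ROIs and ``auto`` only for
    neuropil threads found by the particle filter.
    """

    mask: np.ndarray
    type: str
    provenance: str = "manual"
    label: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ConfigurationError("empty lesion ROI")
        if self.type not in LESION_TYPES:
            raise ConfigurationError(f"unknown lesion type {self.type!r}")
        if self.provenance == "auto" and self.type != "NT":
            raise ConfigurationError("auto provenance is reserved for NT")


@dataclass
class LesionScore:
    """Per-lesion co-localization measurements and category."""

    label: int
    type: str
    provenance: str
    area_at8_pct: float
    area_overlap_pct: float
    proportion: float
    overlap_area_um2: float
    category: str

    def as_dict(self) -> dict:
        return {
            "label": self.label, "type": self.type,
            "provenance": self.provenance,
            "area_at8_pct": self.area_at8_pct,
            "area_overlap_pct": self.area_overlap_pct,
            "proportion": self.proportion,
            "overlap_area_um2": self.overlap_area_um2,
            "category": self.category,
        }


@dataclass
class GeneSet:
    """Named set of gene/protein identifiers."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)
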