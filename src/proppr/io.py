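"""Readers and writers for every on-disk format the pipeline touches.

Tabular data travels as TSV/CSV (intensity matrix + sample metadata, MiST
results, per-lesion scores), gene sets as one-ID-per-line text or GMT,
images as (OME-)TIFF with micrometre calibration, and run configuration as
strict-schema YAML. Writers and readers round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import ConfigurationError, GeneSet, IntensityMatrix, MultichannelImage

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


# ---------------------------------------------------------------------------
# proteomics tables
# ---------------------------------------------------------------------------

def write_intensity_table(m: IntensityMatrix, matrix_path, meta_path) -> None:
    out = m.values.copy()
    out.index.name = "protein"
    out.to_csv(matrix_path, sep="\t", na_rep="NA")
    meta = m.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)


def read_intensity_table(matrix_path, meta_path,
                         zero_as_missing: bool = False) -> IntensityMatrix:
    """Load and validate a protein x sample TSV plus its metadata CSV.

    Empty cells and ``NA`` both parse to the missing marker (NaN);
    ``zero_as_missing`` additionally treats exact zeros as missing.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         na_values=list(MISSING_TOKENS), keep_default_na=False)
    meta = pd.read_csv(meta_path, index_col=0)
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ConfigurationError(f"duplicated protein ids: {dups[:5]}")
    orphans = [s for s in values.columns if s not in meta.index]
    if orphans:
        raise ConfigurationError(
            f"samples in matrix but not metadata: {orphans}")
    values = values.astype(float)
    if zero_as_missing:
        values = values.where(values != 0.0)
    return IntensityMatrix(values=values, meta=meta)


def write_gene_set(gs: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gs.members)) + "\n")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return GeneSet(name=name or Path(path).stem,
                   members=frozenset(ln for ln in lines if ln))


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file into ``{term: member set}`` (members deduplicated).

    Each line is ``term<TAB>description<TAB>member...``; fewer than three
    fields is an error reported with its line number.
    """
    annotation: dict[str, set] = {}
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    for i, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ConfigurationError(
                f"{path}:{i}: GMT line has fewer than 3 fields")
        term, _desc, *members = fields
        annotation[term] = {g for g in members if g}
    if not annotation:
        import warnings
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
    return annotation


def write_gmt(annotation: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for term, members in annotation.items():
            fh.write("\t".join([term, term] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_ome_tiff(img: MultichannelImage, path) -> None:
    """Write channels-first OME-TIFF with named channels and um pixel size."""
    data = np.moveaxis(img.pixels, -1, 0).astype(np.float32)
    tifffile.imwrite(
        path, data, ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(img.channel_names)},
            "PhysicalSizeX": img.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": img.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        })


def read_ome_tiff(path, pixel_size_um: float | None = None,
                  channel_names: list[str] | None = None
                  ) -> MultichannelImage:
    """Read a multichannel TIFF; calibration/channel names come from OME
    metadata when present, else from the explicit arguments."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET
            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pixels = root.find(".//ome:Pixels", ns)
            if pixels is not None:
                if pixel_size_um is None and "PhysicalSizeX" in pixels.attrib:
                    pixel_size_um = float(pixels.attrib["PhysicalSizeX"])
                names = [c.attrib.get("Name", f"ch{i}") for i, c in
                         enumerate(pixels.findall("ome:Channel", ns))]
                if channel_names is None and names:
                    channel_names = names
    if data.ndim == 2:
        data = data[None, :, :]
    if pixel_size_um is None:
        raise ConfigurationError("pixel size not in metadata; pass "
                                 "pixel_size_um")
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    return MultichannelImage(pixels=np.moveaxis(data, 0, -1).astype(float),
                             channel_names=list(channel_names),
                             pixel_size_um=pixel_size_um)


def write_label_mask(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(int)


def rois_from_label_mask(labels: np.ndarray, types: pd.DataFrame):
    """Build LesionROIs from an integer label mask plus a label->type CSV
    table (columns ``label``, ``type``; optional ``provenance``)."""
    from .datatypes import LesionROI
    rois = []
    for _, row in types.iterrows():
        lab = int(row["label"])
        mask = labels == lab
        if not mask.any():
            raise ConfigurationError(f"label {lab} absent from mask")
        rois.append(LesionROI(mask=mask, type=str(row["type"]),
                              provenance=str(row.get("provenance", "manual")),
                              label=lab))
    return rois


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: Every tunable stage parameter with its default; unknown keys are
#: rejected so silently misspelled settings cannot slip through.
CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "mist": {"cutoff": 0.75, "mode": "fixed",
             "weights": [0.30, 0.08, 0.62]},
    "differential": {"alpha": 0.05, "min_frac": 1.0,
                     "impute_shift": 1.8, "impute_width": 0.3},
    "enrichment": {"universe": 20607, "min_size": 10, "max_size": 500},
    "coloc": {"threshold": "otsu", "bg_radius_um": None,
              "nt_min_area_um2": 0.01, "nt_min_aspect": 3.0},
    "burden": {"od_threshold": 0.15, "tissue_od_min": 0.10},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    for key, dval in defaults.items():
        uval = user.get(key, dval)
        if isinstance(dval, dict) and isinstance(uval, dict):
            out[key] = _merge(dval, uval, f"{path}{key}.")
        else:
            out[key] = uval
    return out


def load_config(path=None) -> dict:
    """Load a YAML run configuration merged over the defaults."""
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config must be a YAML mapping")
    return _merge(CONFIG_DEFAULTS, user)


def write_resolved_config(config: dict, out_dir) -> Path:
    """Persist the fully-resolved configuration next to a run's outputs."""
    out = Path(out_dir) / "resolved_config.yaml"
    out.write_text(yaml.safe_dump(config, sort_keys=False))
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
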