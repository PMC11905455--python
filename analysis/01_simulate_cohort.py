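#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the study design: four tauopathies (AD, CBD, PiD, PSP), six cases
each, one pooled AT8-pulldown and one antibody-omission control sample per
case, with 5% shared and 2%-per-disease specific associated proteins spiked
at log2 fold 3; plus one mixed-lesion two-channel image and one H-DAB
brightfield slide. Writes everything under results/simulated/.
"""

import sys
from pathlib import Path

import numpy as np

from proppr import io as pio
from proppr.simulate import (
    BrightfieldSimConfig,
    HistologySimConfig,
    LesionSpec,
    ProteomicsSimConfig,
    simulate_brightfield_dab,
    simulate_histology,
    simulate_proteomics,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    m, truth = simulate_proteomics(ProteomicsSimConfig(seed=SEED))
    pio.write_intensity_table(m, OUT / "intensities.tsv",
                              OUT / "sample_meta.csv")
    truth.to_csv(OUT / "protein_truth.csv")
    print(f"proteomics: {m.values.shape[0]} proteins x "
          f"{m.values.shape[1]} samples, "
          f"{truth['label'].ne('null').sum()} associated, "
          f"{m.values.isna().mean().mean():.1%} missing")

    rng = np.random.default_rng(SEED)
    layout = [("blob", (90, 90), 15.0), ("blob", (420, 420), 20.0),
              ("thread", (250, 120), 40), ("thread", (120, 380), 40),
              ("corona", (400, 150), 25.0), ("blob", (260, 300), 12.0)]
    lesions = [LesionSpec(s, c, z, float(f)) for (s, c, z), f in
               zip(layout, rng.uniform(0, 1, len(layout)))]
    img, htruth = simulate_histology(HistologySimConfig(
        lesions=lesions, noise_sd=0.05 * 255, seed=SEED))
    pio.write_ome_tiff(img, OUT / "image.ome.tif")
    labels = np.zeros(img.pixels.shape[:2], dtype=np.uint16)
    for roi in htruth["rois"]:
        labels[roi.mask] = roi.label
    pio.write_label_mask(labels, OUT / "rois.tif")
    htruth["table"].to_csv(OUT / "lesion_truth.csv", index=False)
    print(f"histology: {len(lesions)} lesions on "
          f"{img.pixels.shape[0]}x{img.pixels.shape[1]} canvas")

    rgb, btruth = simulate_brightfield_dab(
        BrightfieldSimConfig(burden_fraction=0.10, seed=SEED))
    import tifffile
    tifffile.imwrite(OUT / "brightfield.tif", rgb)
    pio.write_json({"true_burden_pct": btruth["true_burden_pct"]},
                   OUT / "brightfield_truth.json")
    print(f"brightfield: true burden {btruth['true_burden_pct']:.2f}%")


if __name__ == "__main__":
    main()
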