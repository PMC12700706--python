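"""Generate the synthetic 12-channel neuropil scene used by later steps.

Channel abundances follow the observed per-image means of the 12-mRNA panel,
scaled to a 52 x 52 µm field (the ROI size of the composition analysis);
puncta areas are drawn from the four empirical size-class distributions.
Writes the puncta table and its ground truth under results/.
"""

from pathlib import Path

from puncta.core import RoiSpec
from puncta.io import write_puncta_csv, write_truth_csv
from puncta.synth import ChannelSpec, generate_scene, HIPLEX_PANEL

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 20250925

# (52/211)^2 of the full-image counts keeps the per-µm² densities
SCALE = (52.0 / 211.0) ** 2


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    roi = RoiSpec(52.0, 52.0)
    specs = [
        ChannelSpec(name, count * SCALE, size_class)
        for name, (count, size_class) in HIPLEX_PANEL.items()
    ]
    scene = generate_scene(specs, [], roi, nuclei_count=3, seed=SEED)
    write_puncta_csv(list(scene.channels.values()), SCRATCH / "hiplex_scene.csv")
    write_truth_csv(scene.truth, SCRATCH / "hiplex_scene_truth.csv")
    counts = {name: len(s) for name, s in scene.channels.items()}
    print(f"wrote {SCRATCH / 'hiplex_scene.csv'}")
    print("realized counts per 52 µm ROI:", counts)
    print(
        "abundance spans "
        f"{min(counts.values())}-{max(counts.values())} puncta per image, "
        "matching the ~11x spread of the panel"
    )

    # full-field scene at the per-image panel abundances; the distribution
    # analysis needs thousands of puncta per channel for stable histograms
    roi_full = RoiSpec(211.0, 211.0)
    specs_full = [
        ChannelSpec(name, count, size_class)
        for name, (count, size_class) in HIPLEX_PANEL.items()
    ]
    scene_full = generate_scene(specs_full, [], roi_full, nuclei_count=40, seed=SEED + 1)
    write_puncta_csv(list(scene_full.channels.values()), SCRATCH / "hiplex_scene_211.csv")
    write_truth_csv(scene_full.truth, SCRATCH / "hiplex_scene_211_truth.csv")
    n_full = sum(len(s) for s in scene_full.channels.values())
    print(f"wrote {SCRATCH / 'hiplex_scene_211.csv'} ({n_full} puncta over 12 channels)")


if __name__ == "__main__":
    main()
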