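"""Serial probe-dilution simulation over copy-number populations.

Dilutes the labeled probe 1x, 1:2, 1:4, 1:8 over three populations: pure
single-copy, pure eight-copy, and a 60/40 mixture.  Single-copy puncta drop
out of detection linearly with the labeled fraction at constant intensity;
high-copy puncta stay countable but dim linearly — the two signatures used
to infer that real puncta hold both low and multiple transcript copies.
"""

from pathlib import Path

import pandas as pd

from puncta.synth import dilution_series

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20250925


def main() -> None:
    OUT.mkdir(exist_ok=True)
    tables = []
    for label, population in [
        ("single_copy", 1),
        ("eight_copy", 8),
        ("mixture_60_40", {1: 0.6, 8: 0.4}),
    ]:
        df = dilution_series(population, (1.0, 0.5, 0.25, 0.125), seed=SEED)
        df.insert(0, "population", label)
        tables.append(df)
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(OUT / "dilution_series.csv", index=False)
    print(f"wrote {OUT / 'dilution_series.csv'}")
    single = out[out.population == "single_copy"]
    octo = out[out.population == "eight_copy"]
    print(
        "single-copy detected fraction over the ladder:",
        [round(v, 3) for v in single.detected_fraction],
        "(tracks the labeled fraction; intensity flat)",
    )
    print(
        "eight-copy intensity ratio over the ladder:",
        [round(v / octo.mean_intensity.iloc[0], 3) for v in octo.mean_intensity],
        "(tracks the labeled fraction down to 1:4; at 1:8 detection truncation "
        "sets in as some puncta carry no labeled copy)",
    )
    print(
        "eight-copy detected fraction:",
        [round(v, 3) for v in octo.detected_fraction],
    )


if __name__ == "__main__":
    main()
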