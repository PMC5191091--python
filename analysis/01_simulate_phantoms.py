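#!/usr/bin/env python
"""Generate the four phantom experiments and archive them under scratch/.

Writes each preset as a multi-page TIFF + JSON sidecar with its ground
truth, so later steps (and external viewers) can work from files instead
of re-simulating.
"""

from pathlib import Path

from svoct import oct_io, phantom

OUT = Path(__file__).resolve().parents[1] / "scratch" / "phantoms"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for preset in phantom.PRESETS:
        fx = phantom.make_fixture(preset, seed=SEED)
        pairs = fx if preset == "four_energies" else [fx]
        for i, (series, truth) in enumerate(pairs):
            stem = OUT / (preset if len(pairs) == 1 else f"{preset}_{i}")
            oct_io.write_series(series, stem)
            phantom.save_ground_truth(truth, stem.with_name(stem.name + "_truth"))
            print(
                f"{stem.name}: {len(series)} frames {series.shape}, "
                f"{len(truth.maz_list)} MAZ(s), seed {SEED}"
            )


if __name__ == "__main__":
    main()
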