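"""Simulate one nuclear-envelope movie per movement condition.

Writes calibrated TIFF stacks plus ground-truth tables for the three motion
regimes (wild-type-like patches with motor-driven runs, mutant-like slow
foci, near-pure-diffusion foci) under ``results/movies/``.  These are the
same generator settings the tracking analyses use; this script exists so the
raw inputs can be inspected with standard imaging tools.
"""

import argparse
from pathlib import Path

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from netrack import get_preset  # noqa: E402
from netrack import io as nio  # noqa: E402
from netrack.pipeline import condition_seed  # noqa: E402
from netrack.simulate import simulate_ne_movie  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/movies"))
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(("wt-like", "spd3-like", "jf18-like")):
        preset = get_preset(name, seed=condition_seed(args.seed, i), n_nuclei=1)
        movie, gt = simulate_ne_movie(preset.config, preset.motion)
        stem = name.replace("-like", "")
        nio.write_movie(args.out / f"{stem}.tif", movie)
        nio.write_ground_truth(args.out, gt, stem=f"{stem}_gt")
        n_fusions = sum(1 for e in gt.events if e.kind == "fusion")
        print(
            f"{name}: movie {movie.data.shape} ({movie.pixel_size_um} µm/px, "
            f"{movie.frame_interval_s} s/frame), {len(gt.tracks)} true tracks, "
            f"{n_fusions} fusion events -> {args.out / (stem + '.tif')}"
        )


if __name__ == "__main__":
    main()
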