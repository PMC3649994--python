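"""Render the per-condition movement report from a pipeline manifest.

Three panels per condition -- displacement-track map, arc fan (one wedge per
track, angle proportional to distance traveled on the nucleus circumference),
and the projected-speed distribution -- plus a pooled statistics table.
Requires ``02_track_and_summarize.py`` to have been run first.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from netrack.pipeline import render_report  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", type=Path, default=Path("results/run/manifest.json"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    if not args.manifest.exists():
        raise SystemExit(
            f"{args.manifest} not found; run analysis/02_track_and_summarize.py first"
        )
    for path in render_report(args.manifest, args.out):
        print(path)


if __name__ == "__main__":
    main()
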