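"""Regenerate the packaged reference histogram from the default phantom.

The pipeline's histogram-matching stage needs a reference intensity
distribution.  Since no clinical reference volume ships with the package,
the default phantom (seed 0) serves as the reference; users can replace it
with a histogram built from their own data via
``ReferenceHistogram.from_volume(...).to_file(...)``.

Run from the repository root:

    python scripts/build_reference_histogram.py
"""

from pathlib import Path

from pelviseg.phantom import PhantomSpec, generate_phantom
from pelviseg.preprocessing import ReferenceHistogram

OUT = Path(__file__).resolve().parent.parent / "src" / "pelviseg" / "data" / \
    "reference_histogram.csv"


def main() -> None:
    vol, _ = generate_phantom(PhantomSpec(seed=0))
    ref = ReferenceHistogram.from_volume(vol, source_id="default-phantom-seed0")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    ref.to_file(OUT)
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes, {len(ref.bin_edges)} points)")


if __name__ == "__main__":
    main()
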