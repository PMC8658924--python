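#!/usr/bin/env python
"""Build the GSE6432 sample-annotation sidecar from the series-matrix file.

The condition/time assignment is derived from the file's own sample metadata
lines (``!Sample_title`` / ``!Sample_characteristics``): hours via regex,
"control" keyword versus the rest.  Because that is heuristic, the result is
cross-checked against the known replicate layout (treated 3/2/3/4/3/2/2 and
control 1/2/3/2/3/1/1 at 1, 2, 4, 8, 12, 24, 48 h) and the script refuses to
write an annotation that does not match.

Usage:
    python scripts/build_gse6432_annotation.py GSE6432_series_matrix.txt.gz \
        -o data/gse6432_annotation.tsv
"""

from __future__ import annotations

import argparse
import sys
from collections import Counter

from pcafe.io_geo import build_annotation_from_headers, write_annotation

EXPECTED_LAYOUT = {
    "treated": {1.0: 3, 2.0: 2, 4.0: 3, 8.0: 4, 12.0: 3, 24.0: 2, 48.0: 2},
    "control": {1.0: 1, 2.0: 2, 4.0: 3, 8.0: 2, 12.0: 3, 24.0: 1, 48.0: 1},
}


def layout_of(annotation) -> dict[str, dict[float, int]]:
    counts: dict[str, Counter] = {"treated": Counter(), "control": Counter()}
    for sid in annotation.sample_ids:
        counts[annotation.condition[sid]][annotation.time_h[sid]] += 1
    return {cond: dict(c) for cond, c in counts.items()}


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("series_matrix", help="GSE6432_series_matrix.txt[.gz]")
    parser.add_argument("-o", "--out", required=True, help="annotation TSV path")
    args = parser.parse_args(argv)

    annotation = build_annotation_from_headers(args.series_matrix)
    layout = layout_of(annotation)
    if layout != EXPECTED_LAYOUT:
        print(
            "ERROR: derived annotation does not match the expected replicate "
            f"layout.\n  derived:  {layout}\n  expected: {EXPECTED_LAYOUT}\n"
            "Inspect the sample metadata and supply a hand-built annotation "
            "instead.",
            file=sys.stderr,
        )
        return 1
    write_annotation(annotation, args.out)
    print(f"wrote {len(annotation.sample_ids)} samples to {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
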