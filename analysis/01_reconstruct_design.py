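"""Rebuild the five-factor CCD from factor specifications and compare it
against the bundled experimental table.

The design is a 2^(5-1) resolution-V half fraction (16 runs) plus 10
star points at coded ±2 (negative star levels floored at 0.0005) and 10
center replicates.  Writes the regenerated design and a cell-level
comparison against the bundled table to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from codmedia import doe

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    fixture = doe.load_paper_fixture()
    generated = doe.generate_ccd(fixture.factors, n_center=10, fraction="half")
    generated.to_csv(OUT / "design_generated.csv")

    diffs = np.argwhere(np.abs(generated.uncoded - fixture.uncoded) > 1e-12)
    rows = [
        {
            "run": int(r) + 1,
            "factor": fixture.factor_names[c],
            "generated": generated.uncoded[r, c],
            "bundled": fixture.uncoded[r, c],
        }
        for r, c in diffs
    ]
    pd.DataFrame(rows, columns=["run", "factor", "generated", "bundled"]).to_csv(
        OUT / "design_discrepancies.csv", index=False
    )

    counts = generated.df["point_type"].value_counts().to_dict()
    print(f"Regenerated {len(generated)} runs: {counts}")
    if rows:
        print("Cells differing from the bundled table (suspected transcription error):")
        for row in rows:
            print(
                f"  run {row['run']}, {row['factor']}: generated {row['generated']}"
                f" vs bundled {row['bundled']}"
            )
    else:
        print("Regenerated design matches the bundled table cell for cell.")


if __name__ == "__main__":
    main()
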