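"""Apply the symptom algorithms to the simulated cohort.

Runs the non-hierarchical (multi-cause) and hierarchical (single-cause)
classifiers over results/cohort.csv and writes per-record assignments.
"""

import argparse
import csv
import pathlib

from vacod.rule_engine import classify_multi, classify_single
from vacod.va_data import read_records


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = parser.parse_args()

    records = read_records(args.outdir / "cohort.csv")
    out = args.outdir / "assignments.csv"
    multi_sizes = []
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "nha_causes", "ha_cause"])
        for r in records:
            multi = classify_multi(r)
            multi_sizes.append(len(multi))
            writer.writerow(
                [
                    r.record_id,
                    ";".join(sorted(c.value for c in multi)),
                    classify_single(r).value,
                ]
            )
    n_multi = sum(1 for s in multi_sizes if s > 1)
    n_none = sum(1 for s in multi_sizes if s == 0)
    print(f"classified {len(records)} records -> {out}")
    print(
        f"  non-hierarchical: {n_multi} records satisfy >1 criterion, "
        f"{n_none} satisfy none (counted as OTHER)"
    )


if __name__ == "__main__":
    main()
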