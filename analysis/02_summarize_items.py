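#!/usr/bin/env python
"""Per-item availability and score summaries for each synthetic participant.

The analogue of a study's descriptive item table: mean (SD) of the observed
scores, percent of the 105 scheduled points observed, and days covered —
the quantities the node-selection rule feeds on. Reads results/data/, writes
results/tables/item_summaries_<participant>.csv.
"""

from pathlib import Path

from idionet.data import Schedule, completeness_summary, load_ema_table, load_manifest_csv
from idionet.selection import item_summaries, summaries_frame

DATA = Path("results/data")
OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for data_path in sorted(DATA.glob("synthetic-patient-*.csv")):
        if data_path.stem.endswith("_manifest"):
            continue
        manifest = load_manifest_csv(DATA / f"{data_path.stem}_manifest.csv")
        dataset = load_ema_table(data_path, manifest, Schedule())
        table = summaries_frame(item_summaries(dataset)).merge(
            completeness_summary(dataset), on="item_id"
        )
        out = OUT / f"item_summaries_{data_path.stem}.csv"
        table.sort_values("mean", ascending=False).to_csv(out, index=False)
        top = table.sort_values("mean", ascending=False).iloc[0]
        print(
            f"{data_path.stem}: highest-mean item {top.item_id} "
            f"(mean {top['mean']:.2f}, available {top.available_percent}%) -> {out}"
        )


if __name__ == "__main__":
    main()
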