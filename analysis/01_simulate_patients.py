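#!/usr/bin/env python
"""Generate the three synthetic study-like participants.

The raw clinical EMA series are request-only, so the analysis runs on
synthetic participants with known graphical-VAR ground truth, matched to the
protocol (21 days x 5 beeps, 0-100 sliders) and to the reported range of
data availability: exactly 96, 75 and 45 completed beeps of 105.

Writes wide-format EMA tables and the item manifest to results/data/.
"""

from pathlib import Path

from idionet.data import write_manifest_csv, write_wide_csv
from idionet.simulate import study_like_trio

OUT = Path("results/data")
SEED = 20260927


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for dataset in study_like_trio(seed=SEED):
        path = OUT / f"{dataset.participant_id}.csv"
        write_wide_csv(dataset, path)
        write_manifest_csv(dataset.manifest, OUT / f"{dataset.participant_id}_manifest.csv")
        print(
            f"{dataset.participant_id}: {dataset.n_completed_beeps}/{dataset.schedule.size} "
            f"completed beeps -> {path}"
        )


if __name__ == "__main__":
    main()
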