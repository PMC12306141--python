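import numpy as np
import pytest

from idionet.data import Community, EMADataset, EMARecord, Schedule, SymptomItem

ED_ITEMS = ["feel_fat", "fear_weight", "worth_weight", "skip_meals_urge"]
SUI_ITEMS = ["desire_live", "fear_death", "reasons_die", "passive_ideation_1"]


def make_manifest(ed=ED_ITEMS, sui=SUI_ITEMS):
    return [SymptomItem(n, n, n, Community.ED) for n in ed] + [
        SymptomItem(n, n, n, Community.SUI) for n in sui
    ]


def make_dataset(values, schedule=None, manifest=None, participant_id="p1"):
    """Dataset from a (schedule.size, p) array; NaN rows/cells become missing."""
    manifest = manifest or make_manifest()
    item_ids = [it.item_id for it in manifest]
    schedule = schedule or Schedule(
        n_days=len(values) // 5 if len(values) % 5 == 0 else len(values), beeps_per_day=5
    )
    assert len(values) == schedule.size
    records = []
    pos = 0
    for day in range(1, schedule.n_days + 1):
        for beep in range(1, schedule.beeps_per_day + 1):
            row = values[pos]
            pos += 1
            scores = {
                item_ids[j]: float(row[j]) for j in range(len(item_ids)) if not np.isnan(row[j])
            }
            if scores:
                records.append(EMARecord(day, beep, scores))
    return EMADataset(participant_id, manifest, schedule, records)


def white_noise_dataset(seed, n_days=21, p=8, mean=50.0, sd=15.0):
    """Independent-node dataset: the null case for network selection."""
    rng = np.random.default_rng(seed)
    schedule = Schedule(n_days=n_days, beeps_per_day=5)
    values = np.clip(mean + sd * rng.standard_normal((schedule.size, p)), 0, 100)
    return make_dataset(values, schedule=schedule)


@pytest.fixture
def manifest():
    return make_manifest()


@pytest.fixture
def complete_dataset():
    """2 days x 5 beeps, 8 items, fully observed, deterministic values."""
    rng = np.random.default_rng(7)
    values = np.round(np.clip(50 + 15 * rng.standard_normal((10, 8)), 0, 100), 1)
    return make_dataset(values, schedule=Schedule(n_days=2, beeps_per_day=5))
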