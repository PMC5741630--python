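"""Shared fixtures: hand-built fins and datasets for rule-level tests."""

import pytest

from finray.records import Dataset, FinSeries, RayRecord


def make_fin(layout, fish="f1", fin="caudal", outcome_field="regen_7dpi"):
    """Build a FinSeries from a compact per-ray layout list.

    Each element is either an injury class string ("none",
    "epidermal_wound", ...), "escaper", or a (injury, regen) tuple where
    regen sets the outcome field. "escaper" implies injury none and
    regen True.
    """
    rays = []
    for i, item in enumerate(layout, start=1):
        regen = False
        if isinstance(item, tuple):
            injury, regen = item
            escaper = False
        elif item == "escaper":
            injury, escaper, regen = "none", True, True
        else:
            injury, escaper = item, False
        rays.append(
            RayRecord(
                fish_id=fish,
                fin_id=fin,
                ray_index=i,
                injury=injury,
                escaper=escaper,
                **{outcome_field: regen},
            )
        )
    return FinSeries(fish, fin, rays)


def make_dataset(*fins, label="test"):
    return Dataset(fins=list(fins), label=label)


@pytest.fixture
def single_fin_dataset():
    """One fin of six non-injured rays, two of them regenerating adjacently."""
    fin = make_fin(
        [("none", False), ("none", True), ("none", True),
         ("none", False), ("none", False), ("none", True)]
    )
    return make_dataset(fin)
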