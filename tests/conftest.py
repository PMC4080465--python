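import numpy as np
import pandas as pd
import pytest

from dlopanel import DLOParams, ObservationSchedule, PanelSeries, simulate_panel


@pytest.fixture(scope="session")
def sine_panel():
    """Fully observed noisy sine panel (5 persons, 97 weeks, seeded)."""
    rng = np.random.default_rng(42)
    blocks = []
    for p in range(5):
        t = np.arange(1, 98, dtype=float)
        y = 0.5 + 0.1 * np.sin(2 * np.pi * t / 40 + p) + rng.normal(0, 0.02, len(t))
        blocks.append(
            pd.DataFrame({"person": f"S{p}", "week": t.astype(int), "value": y})
        )
    return PanelSeries(pd.concat(blocks, ignore_index=True))


@pytest.fixture(scope="session")
def gappy_sine_panel(sine_panel):
    """The sine panel with ~half the weeks masked out (seeded)."""
    rng = np.random.default_rng(7)
    frame = sine_panel.frame.copy()
    for person, grp in frame.groupby("person", sort=False):
        idx = grp.index.to_numpy()
        interior = idx[1:-1]
        drop = rng.choice(interior, size=len(interior) // 2, replace=False)
        frame.loc[drop, "value"] = np.nan
    return PanelSeries(frame)


@pytest.fixture(scope="session")
def study_panel():
    """Default study-design simulation: 112 persons, 40 obs in 77-97 weeks."""
    panel, truth = simulate_panel(DLOParams(), ObservationSchedule(), seed=2024)
    return panel, truth
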