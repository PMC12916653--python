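"""Shared fixtures: compact synthetic panels sized for fast, seeded tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hdpimmune.synthetic import PlantedEffect, SyntheticConfig

# A reduced 8-type x 6-marker panel: 8 frequency + 4 x 48 signaling = 200
# candidate features when no stratum is trimmed.
SMALL_CELL_TYPES = ("cMC", "intMC", "ncMC", "NK_CD56dim", "Bcells",
                    "CD4T_naive", "CD8T_naive", "Neutrophils")
SMALL_MARKERS = ("pCREB", "pSTAT3", "pNFkB", "CXCR4", "GLUT1", "pS6")
SMALL_GRANULOCYTES = ("Neutrophils",)

#: ten well-spread signaling features used for planted-effect scenarios
PLANTED_TEN = [
    ("unstim", "cMC", "pCREB"), ("unstim", "cMC", "pSTAT3"),
    ("unstim", "intMC", "pNFkB"), ("unstim", "ncMC", "CXCR4"),
    ("unstim", "NK_CD56dim", "GLUT1"), ("unstim", "Bcells", "pS6"),
    ("unstim", "CD4T_naive", "pCREB"), ("unstim", "CD8T_naive", "pSTAT3"),
    ("unstim", "cMC", "pNFkB"), ("unstim", "intMC", "pCREB"),
]


def small_config(seed: int = 0, n_cases: int = 30, n_controls: int = 30,
                 effects: tuple[PlantedEffect, ...] = (),
                 cohort: str = "AP", **kwargs) -> SyntheticConfig:
    """Sample-level generator config on the reduced 200-feature panel."""
    return SyntheticConfig(
        n_cases=n_cases, n_controls=n_controls, cohort_label=cohort,
        cell_types=SMALL_CELL_TYPES, markers=SMALL_MARKERS,
        granulocyte_types=SMALL_GRANULOCYTES,
        canonical_response_map={}, planted_effects=tuple(effects),
        seed=seed, **kwargs)


def planted_effects(effect: float, n: int = 10) -> tuple[PlantedEffect, ...]:
    return tuple(PlantedEffect(s, ct, m, effect) for s, ct, m in PLANTED_TEN[:n])


def event_config(seed: int = 0, n_cases: int = 6, n_controls: int = 6,
                 effects: tuple[PlantedEffect, ...] = (), **kwargs) -> SyntheticConfig:
    """Event-level generator config: common populations only, enough cells
    for stable medians (equal mononuclear composition avoids thin subsets)."""
    mono = tuple(t for t in SMALL_CELL_TYPES if t not in SMALL_GRANULOCYTES)
    defaults = dict(cells_per_sample=2000,
                    baseline_frequency_concentration={t: 30.0 for t in mono})
    defaults.update(kwargs)
    return SyntheticConfig(
        n_cases=n_cases, n_controls=n_controls,
        cell_types=SMALL_CELL_TYPES, markers=SMALL_MARKERS,
        granulocyte_types=SMALL_GRANULOCYTES,
        planted_effects=tuple(effects), seed=seed, **defaults)


@pytest.fixture(autouse=True)
def _quiet_constant_column_warnings():
    """Model-fitting emits advisory warnings (constant columns, extra
    columns); tests assert on results, not on the advisories."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*constant feature column.*")
        warnings.filterwarnings("ignore", message=".*extra feature columns.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
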