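"""Seeded synthetic data with the statistical structure the pipeline assumes.

Two entry points:

* :func:`generate_events` draws gated cell-level event tables (one block per
  sample and stimulation condition) with Dirichlet-multinomial cell-type
  composition and log-normal marker intensities.  Stimulation acts
  multiplicatively on the raw scale, so canonical responses appear as
  approximately additive shifts of the arcsinh-transformed medians — the
  scale on which response features are defined.
* :func:`generate_feature_table` is the sample-level shortcut: it draws the
  derived feature table directly from a block-correlated Gaussian model (plus
  a Dirichlet layer for frequencies), skipping cell simulation.

Case/control differences are *planted effects*: standardized mean shifts on
the derived-feature scale for a chosen (stratum, cell type, marker).  The
planting is calibrated against the generator's own feature-level standard
deviation (including median-sampling noise for the event generator), so the
configured effect size is what a two-sample comparison of derived features
recovers in expectation.

Confounders (BMI, age, parity, gestational diabetes, blood pressure, visit
timing) are drawn per arm from cohort-specific means/SDs, defaulting to the
three study cohorts' printed demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohortstats import REFERENCE_COHORT_COUNTS, REFERENCE_COHORT_SUMMARIES
from .features import (
    CONDITIONS,
    DEFAULT_CELL_TYPES,
    DEFAULT_GRANULOCYTES,
    DEFAULT_MARKERS,
    DEFAULT_MONONUCLEAR,
    STIM_CONDITIONS,
    PenalizationMatrix,
    build_default_mask,
    feature_id,
)

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "default_planted_effects",
    "default_canonical_response_map",
    "generate_events",
    "generate_feature_table",
    "generate_confounders",
]

#: Default cohort sizes (cases, controls) for the three study groups.
DEFAULT_COHORT_SIZES = {"AP": (28, 38), "PP": (42, 37), "ML": (70, 74)}

# Plausible baseline mononuclear composition (% of mononuclear cells);
# normalized to a simplex at config construction.
_BASE_MONO_PROPS = {
    "cMC": 12.0, "intMC": 1.5, "ncMC": 2.0, "mDC": 1.0, "pDC": 0.5,
    "NK_CD56bright": 1.0, "NK_CD56dim": 8.0, "NK_CD16hi": 2.0,
    "NK_CD57pos": 2.0, "NKT_like": 2.0, "Bcells": 10.0, "Plasmablasts": 0.5,
    "CD4T_naive": 12.0, "CD4T_cm": 8.0, "CD4T_em": 6.0, "CD4T_emra": 1.5,
    "Th1": 3.0, "Th2": 2.0, "Th17": 1.5, "Tfh": 1.0,
    "Treg_naive": 1.0, "Treg_memory": 1.5,
    "CD8T_naive": 6.0, "CD8T_cm": 3.0, "CD8T_em": 4.0, "CD8T_emra": 2.0,
    "gdT": 2.0, "MAIT": 1.5, "DNT": 1.0, "Ki67_CD4T": 0.5, "Ki67_CD8T": 0.5,
    "Basophils": 1.0, "ILC": 0.5,
}
# Top-level composition of singlet leukocytes: mononuclear vs granulocytes.
_TOP_LEVEL_PROPS = {"mononuclear": 0.42, "Neutrophils": 0.55, "Eosinophils": 0.03}


def default_canonical_response_map(
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
) -> dict[str, list[tuple[str, str]]]:
    """Canonical stimulation responses: which (cell type, marker) pairs shift.

    LPS drives MyD88/NFkB signaling (pCREB, pNFkB, pERK1/2, pp38) in monocyte
    and DC subsets; IL-18 drives pCREB/pNFkB in NK and NKT-like cells; the
    IL-2/IL-4/IL-6 cocktail drives STAT phosphorylation (pSTAT3, pSTAT5,
    pSTAT6, pSTAT1) in monocytes and T cells.
    """
    cs = set(cell_types)
    monocytes = [t for t in ("cMC", "intMC", "ncMC") if t in cs]
    dcs = [t for t in ("mDC", "pDC") if t in cs]
    nk = [t for t in ("NK_CD56bright", "NK_CD56dim", "NK_CD16hi",
                      "NK_CD57pos", "NKT_like") if t in cs]
    tcells = [t for t in ("CD4T_naive", "CD4T_cm", "CD4T_em", "CD4T_emra",
                          "Th1", "Th2", "Th17", "Tfh", "Treg_naive",
                          "Treg_memory", "CD8T_naive", "CD8T_cm", "CD8T_em",
                          "CD8T_emra") if t in cs]
    return {
        "LPS": [(t, m) for t in monocytes + dcs
                for m in ("pCREB", "pNFkB", "pERK12", "pp38")],
        "IL18": [(t, m) for t in nk for m in ("pCREB", "pNFkB")],
        "IL246": [(t, m) for t in monocytes + tcells
                  for m in ("pSTAT3", "pSTAT5", "pSTAT6", "pSTAT1")],
    }


@dataclass(frozen=True)
class PlantedEffect:
    """Case-minus-control standardized mean shift on one derived feature."""

    stratum: str
    cell_type: str
    marker: str
    effect: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("planted effect size must be finite")

    @property
    def feature(self) -> str:
        return feature_id(self.stratum, self.cell_type,
                          self.marker if self.stratum != "freq" else "frequency")


def default_planted_effects() -> list[PlantedEffect]:
    """Default case/control differences: elevated B-cell frequency and a
    depressed pSTAT3 response to IL-2/IL-4/IL-6 in classical monocytes."""
    return [
        PlantedEffect("freq", "Bcells", "frequency", 0.8),
        PlantedEffect("IL246", "cMC", "pSTAT3", -0.8),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    n_cases: int = 28
    n_controls: int = 38
    cohort_label: str = "AP"
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    granulocyte_types: tuple[str, ...] = DEFAULT_GRANULOCYTES
    markers: tuple[str, ...] = DEFAULT_MARKERS
    conditions: tuple[str, ...] = CONDITIONS
    cells_per_sample: int = 1000
    #: Dirichlet concentration total for the mononuclear simplex.
    frequency_concentration: float = 200.0
    #: Optional override of per-cell-type Dirichlet parameters (positive).
    baseline_frequency_concentration: dict[str, float] | None = None
    #: Location/scale of cell-level log-intensities.
    baseline_log_intensity: float = float(np.log(20.0))
    cell_log_sd: float = 0.8
    #: Between-sample SDs of endogenous activity and stimulation response
    #: (arcsinh/log scale).
    endogenous_sd: float = 0.25
    response_sd: float = 0.25
    #: Multiplicative stimulation shift, on the log scale (ln k).
    response_magnitude: float = 0.7
    canonical_response_map: dict[str, list[tuple[str, str]]] | None = None
    planted_effects: tuple[PlantedEffect, ...] = ()
    #: Within-cell-type feature correlation for the sample-level generator.
    block_correlation: float = 0.2
    confounder_model: dict | None = None
    stratum_sizes: dict[str, int] | None = None
    mask: PenalizationMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if self.cells_per_sample <= 0:
            raise ValueError("cells_per_sample must be positive")
        if self.frequency_concentration <= 0:
            raise ValueError("frequency concentration must be positive")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block correlation must be in [0, 1)")
        if self.baseline_frequency_concentration is not None:
            bad = {k: v for k, v in self.baseline_frequency_concentration.items()
                   if v <= 0}
            if bad:
                raise ValueError(f"Dirichlet parameters must be positive: {bad}")
        space = set(self.feature_ids())
        for eff in self.planted_effects:
            if eff.feature not in space:
                raise ValueError(
                    f"planted effect references unknown or masked-out feature "
                    f"{eff.feature!r}")

    # -- derived structure ------------------------------------------------
    @property
    def mononuclear_types(self) -> tuple[str, ...]:
        return tuple(t for t in self.cell_types if t not in self.granulocyte_types)

    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def penalization(self) -> PenalizationMatrix:
        if self.mask is not None:
            return self.mask
        if self.stratum_sizes is not None:
            return build_default_mask(self.cell_types, self.markers,
                                      self.stratum_sizes)
        n_pairs = len(self.cell_types) * len(self.markers)
        sizes = {"freq": len(self.cell_types), "unstim": n_pairs,
                 "LPS": n_pairs, "IL246": n_pairs, "IL18": n_pairs}
        if (self.cell_types, self.markers) == (DEFAULT_CELL_TYPES, DEFAULT_MARKERS):
            return build_default_mask()
        return build_default_mask(self.cell_types, self.markers, sizes)

    def feature_ids(self) -> list[str]:
        return self.penalization().feature_ids(self.cell_types, self.markers)

    def mono_alpha(self) -> np.ndarray:
        """Dirichlet parameters over the mononuclear simplex."""
        mono = self.mononuclear_types
        if self.baseline_frequency_concentration is not None:
            return np.array([self.baseline_frequency_concentration[t] for t in mono])
        props = np.array([_BASE_MONO_PROPS.get(t, 1.0) for t in mono], float)
        props /= props.sum()
        return props * self.frequency_concentration

    def response_map(self) -> dict[str, list[tuple[str, str]]]:
        if self.canonical_response_map is not None:
            return self.canonical_response_map
        return default_canonical_response_map(self.cell_types)

    def outcome_labels(self) -> np.ndarray:
        return np.array([1] * self.n_cases + [0] * self.n_controls)

    def sample_ids(self) -> list[str]:
        return [f"{self.cohort_label}_{'case' if y else 'ctrl'}_{i:03d}"
                for i, y in enumerate(self.outcome_labels())]


# ---------------------------------------------------------------------------
# frequency-effect calibration

def _shifted_alpha(alpha: np.ndarray, idx: int, delta: float) -> np.ndarray:
    """Shift the mean of simplex component ``idx`` by ``delta`` (proportion
    scale) keeping the concentration total fixed; other components scale
    proportionally so the simplex stays valid."""
    a0 = alpha.sum()
    p = alpha / a0
    p_new = p[idx] + delta
    if not 0 < p_new < 1:
        raise ValueError(
            "planted frequency effect pushes the mean proportion outside (0,1)")
    out = p * (1 - p_new) / (1 - p[idx])
    out[idx] = p_new
    return out * a0


def _freq_sd_prop(alpha: np.ndarray, idx: int, n_cells: float) -> float:
    """Approximate SD (proportion scale) of an observed cell-type frequency:
    Dirichlet between-sample variance plus multinomial counting noise."""
    a0 = alpha.sum()
    p = alpha[idx] / a0
    var = p * (1 - p) / (a0 + 1) + p * (1 - p) / max(n_cells, 1.0)
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# confounders

def _default_confounder_model(cohort: str) -> dict:
    summaries = REFERENCE_COHORT_SUMMARIES[cohort]
    model: dict = {var: {arm: {"mean": m, "sd": s}
                         for arm, (m, s, _n) in arms.items()}
                   for var, arms in summaries.items()}
    for var, (a, n1, c, n0) in REFERENCE_COHORT_COUNTS[cohort].items():
        model[var] = {"case": {"rate": a / n1}, "control": {"rate": c / n0}}
    return model


# Subtype composition of cases per cohort (proportions): probability of early
# onset (<=34 wks), of gestational hypertension (vs preeclampsia), and of
# severe features or HELLP among preeclampsia cases.
_SUBTYPE_PROPS = {
    "AP": {"early_onset": 0.821, "gest_htn": 0.143, "severe": 0.708, "hellp": 0.042},
    "PP": {"early_onset": 0.381, "gest_htn": 0.190, "severe": 0.676, "hellp": 0.029},
    "ML": {"early_onset": 0.143, "gest_htn": 0.129, "severe": 0.475, "hellp": 0.082},
}


def generate_confounders(config: SyntheticConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample confounder and HDP-subtype records.

    Continuous confounders are Gaussian with arm-specific mean/SD; binary
    confounders Bernoulli with arm-specific rate.  Subtype fields are drawn
    for cases only.  Defaults reproduce the study cohorts' demographics.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    model = config.confounder_model or _default_confounder_model(config.cohort_label)
    labels = config.outcome_labels()
    n = len(labels)
    out = pd.DataFrame({"sample_id": config.sample_ids(),
                        "cohort": config.cohort_label, "outcome": labels})
    for var, arms in model.items():
        vals = np.empty(n)
        for arm, y in (("case", 1), ("control", 0)):
            idx = labels == y
            params = arms[arm]
            if "rate" in params:
                vals[idx] = rng.binomial(1, params["rate"], idx.sum())
            else:
                sd = params["sd"]
                if sd < 0:
                    raise ValueError(f"negative SD for confounder {var!r}")
                vals[idx] = (params["mean"] if sd == 0
                             else rng.normal(params["mean"], sd, idx.sum()))
        out[var] = vals
    props = _SUBTYPE_PROPS.get(config.cohort_label,
                               {"early_onset": 0.3, "gest_htn": 0.15,
                                "severe": 0.6, "hellp": 0.05})
    case_idx = labels == 1
    n_case = int(case_idx.sum())
    early = rng.binomial(1, props["early_onset"], n_case).astype(float)
    gh = rng.binomial(1, props["gest_htn"], n_case).astype(float)
    u = rng.random(n_case)
    severity = np.where(gh == 1, "none",
                        np.where(u < props["hellp"], "HELLP",
                                 np.where(u < props["hellp"] + props["severe"],
                                          "severe", "mild")))
    for col in ("early_onset", "preterm_onset", "gest_htn"):
        out[col] = np.nan
    out["severity"] = pd.Series([None] * n, dtype=object)
    out.loc[case_idx, "early_onset"] = early
    out.loc[case_idx, "preterm_onset"] = np.maximum(
        early, rng.binomial(1, 0.3, n_case))
    out.loc[case_idx, "gest_htn"] = gh
    out.loc[case_idx, "severity"] = severity
    return out


# ---------------------------------------------------------------------------
# event-level generator

def generate_events(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gated cell-level event table plus cohort metadata.

    One event block per (sample, condition).  Cell-type counts follow a
    Dirichlet-multinomial; marker intensities are log-normal with
    condition-specific multiplicative shifts for canonical responses and
    additional shifts encoding planted case effects.  Identical config and
    seed give bitwise-identical tables.
    """
    ss = np.random.SeedSequence([config.seed, 11])
    sample_seeds = ss.spawn(config.n_samples())
    labels = config.outcome_labels()
    sample_ids = config.sample_ids()
    mono = config.mononuclear_types
    gran = tuple(t for t in config.cell_types if t in config.granulocyte_types)
    markers = list(config.markers)
    resp_map = {c: set(v) for c, v in config.response_map().items()}

    alpha = config.mono_alpha()
    top_props = np.array([_TOP_LEVEL_PROPS["mononuclear"]] +
                         [_TOP_LEVEL_PROPS.get(t, 0.02) for t in gran], float)
    top_props /= top_props.sum()
    top_alpha = top_props * 150.0

    n_mono_cells = _TOP_LEVEL_PROPS["mononuclear"] * config.cells_per_sample
    case_alpha, case_top_alpha = alpha, top_alpha
    sig_shift: dict[tuple[str, str, str], float] = {}  # (stratum, ct, m) -> log shift
    for eff in config.planted_effects:
        if eff.stratum == "freq":
            if eff.cell_type in mono:
                idx = mono.index(eff.cell_type)
                sd = _freq_sd_prop(alpha, idx, n_mono_cells)
                case_alpha = _shifted_alpha(
                    case_alpha if case_alpha is not alpha else alpha.copy(),
                    idx, eff.effect * sd)
            else:
                idx = 1 + gran.index(eff.cell_type)
                sd = _freq_sd_prop(top_alpha, idx, config.cells_per_sample)
                case_top_alpha = _shifted_alpha(
                    case_top_alpha if case_top_alpha is not top_alpha
                    else top_alpha.copy(), idx, eff.effect * sd)
        else:
            sig_shift[(eff.stratum, eff.cell_type, eff.marker)] = eff.effect

    med_factor = np.sqrt(np.pi / 2.0)  # asymptotic sd inflation of a median

    def _expected_count(ct: str) -> float:
        if ct in mono:
            p = alpha[mono.index(ct)] / alpha.sum()
            return max(p * n_mono_cells, 1.0)
        p = top_alpha[1 + gran.index(ct)] / top_alpha.sum()
        return max(p * config.cells_per_sample, 1.0)

    def _sig_sd(stratum: str, ct: str) -> float:
        mednoise = med_factor * config.cell_log_sd / np.sqrt(_expected_count(ct))
        if stratum == "unstim":
            return float(np.sqrt(config.endogenous_sd**2 + mednoise**2))
        return float(np.sqrt(config.response_sd**2 + 2 * mednoise**2))

    blocks = []
    for sid, y, seed in zip(sample_ids, labels, sample_seeds):
        rng = np.random.default_rng(seed)
        a = case_alpha if y else alpha
        ta = case_top_alpha if y else top_alpha
        top = rng.dirichlet(ta)
        n_mono = rng.binomial(config.cells_per_sample, top[0])
        n_gran = rng.multinomial(config.cells_per_sample - n_mono,
                                 top[1:] / top[1:].sum()) if gran else []
        mono_p = rng.dirichlet(a)
        mono_counts = rng.multinomial(n_mono, mono_p)
        counts = dict(zip(mono, mono_counts))
        counts.update(dict(zip(gran, n_gran)))
        # sample-level endogenous activity per (cell type, marker)
        endo = {(ct, m): rng.normal(0.0, config.endogenous_sd)
                for ct in counts for m in markers}
        for cond in config.conditions:
            for ct, n_ct in counts.items():
                if n_ct == 0:
                    continue
                loc = np.empty(len(markers))
                for j, m in enumerate(markers):
                    mu = config.baseline_log_intensity + endo[(ct, m)]
                    if y and (eshift := sig_shift.get(("unstim", ct, m))):
                        mu += eshift * _sig_sd("unstim", ct)
                    if cond != "Unstim":
                        resp = rng.normal(0.0, config.response_sd)
                        if (ct, m) in resp_map.get(cond, set()):
                            resp += config.response_magnitude
                        if y and (pshift := sig_shift.get((cond, ct, m))):
                            resp += pshift * _sig_sd(cond, ct)
                        mu += resp
                    loc[j] = mu
                x = np.exp(loc + config.cell_log_sd *
                           rng.standard_normal((n_ct, len(markers))))
                block = pd.DataFrame(x, columns=markers)
                block.insert(0, "cell_type", ct)
                block.insert(0, "condition", cond)
                block.insert(0, "sample_id", sid)
                blocks.append(block)
    events = pd.concat(blocks, ignore_index=True)
    metadata = generate_confounders(config)
    return events, metadata


# ---------------------------------------------------------------------------
# sample-level generator

def generate_feature_table(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-sample feature table directly (no cell simulation).

    Signaling features are block-correlated Gaussians on the arcsinh scale
    (blocks = cell types, correlation ``block_correlation``); canonical
    response pairs are mean-shifted by ``response_magnitude``.  Frequencies
    come from the same Dirichlet layer as the event generator.  Planted
    effects are standardized mean shifts for case samples.
    """
    feature_ids = config.feature_ids()
    ss = np.random.SeedSequence([config.seed, 23])
    rng = np.random.default_rng(ss)
    labels = config.outcome_labels()
    n = config.n_samples()
    mono = config.mononuclear_types
    gran = tuple(t for t in config.cell_types if t in config.granulocyte_types)
    resp_map = {c: set(v) for c, v in config.response_map().items()}

    endo_mean = float(np.arcsinh(np.exp(config.baseline_log_intensity) / 5.0))
    endo_sd = config.endogenous_sd
    resp_sd = config.response_sd
    rho = config.block_correlation

    alpha = config.mono_alpha()
    top_props = np.array([_TOP_LEVEL_PROPS["mononuclear"]] +
                         [_TOP_LEVEL_PROPS.get(t, 0.02) for t in gran], float)
    top_props /= top_props.sum()
    top_alpha = top_props * 150.0
    case_alpha, case_top_alpha = alpha.copy(), top_alpha.copy()
    planted = {}
    for eff in config.planted_effects:
        if eff.stratum == "freq":
            if eff.cell_type in mono:
                idx = mono.index(eff.cell_type)
                sd = _freq_sd_prop(alpha, idx, np.inf)
                case_alpha = _shifted_alpha(case_alpha, idx, eff.effect * sd)
            else:
                idx = 1 + gran.index(eff.cell_type)
                sd = _freq_sd_prop(top_alpha, idx, np.inf)
                case_top_alpha = _shifted_alpha(case_top_alpha, idx, eff.effect * sd)
        else:
            planted[eff.feature] = eff.effect

    cols = {}
    # frequency stratum
    mono_fracs = np.vstack([rng.dirichlet(case_alpha if y else alpha)
                            for y in labels])
    top_fracs = np.vstack([rng.dirichlet(case_top_alpha if y else top_alpha)
                           for y in labels])
    for fid in feature_ids:
        stratum, ct, _ = fid.split("|")
        if stratum != "freq":
            continue
        if ct in mono:
            cols[fid] = 100.0 * mono_fracs[:, mono.index(ct)]
        else:
            cols[fid] = 100.0 * top_fracs[:, 1 + gran.index(ct)]
    # signaling strata: shared per-(sample, cell type, stratum) block factor
    block_factor: dict[tuple[str, str], np.ndarray] = {}
    for fid in feature_ids:
        stratum, ct, marker = fid.split("|")
        if stratum == "freq":
            continue
        key = (stratum, ct)
        if key not in block_factor:
            block_factor[key] = rng.standard_normal(n)
        z = (np.sqrt(rho) * block_factor[key]
             + np.sqrt(1.0 - rho) * rng.standard_normal(n))
        if stratum == "unstim":
            x = endo_mean + endo_sd * z
        else:
            mean = (config.response_magnitude
                    if (ct, marker) in resp_map.get(stratum, set()) else 0.0)
            x = mean + resp_sd * z
        if fid in planted:
            sd = endo_sd if stratum == "unstim" else resp_sd
            x = x + planted[fid] * sd * labels
        cols[fid] = x
    table = pd.DataFrame(cols, index=pd.Index(config.sample_ids(), name="sample_id"))
    table = table[feature_ids]
    metadata = generate_confounders(config)
    return table, metadata
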