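"""Per-sample immune feature derivation from gated mass-cytometry events.

Events arrive pre-gated: each row is one cell with a sample id, a stimulation
condition (``Unstim``, ``LPS``, ``IL246``, ``IL18``), a cell-type label and
one intensity column per functional marker.  Four families of features are
derived per sample:

* **freq** — cell-type frequencies, computed on the unstimulated aliquot:
  mononuclear subsets as a percentage of mononuclear cells, granulocyte
  subsets as a percentage of all singlet leukocytes;
* **unstim** — endogenous signaling/functional activity: the arcsinh(x/5)
  transform of the median marker intensity in the unstimulated aliquot, per
  (cell type, marker);
* **LPS / IL246 / IL18** — stimulation responses: the difference in
  arcsinh-transformed median intensity between the stimulated and the
  unstimulated aliquot.

A binary penalization mask encoding prior knowledge of receptor-specific
canonical signaling (e.g. LPS engages TLR4/MyD88 in myeloid cells, not in
T cells; interleukin cocktails engage JAK/STAT) restricts the feature space
to biologically plausible (cell type, marker, condition) combinations;
pairs for which prior knowledge is unclear are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "STIM_CONDITIONS",
    "STRATA",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_GRANULOCYTES",
    "DEFAULT_MARKERS",
    "FeatureDerivationConfig",
    "PenalizationMatrix",
    "arcsinh_transform",
    "cell_frequencies",
    "signaling_features",
    "apply_penalization",
    "derive_features",
    "build_default_mask",
    "feature_id",
]

CONDITIONS = ("Unstim", "LPS", "IL246", "IL18")
STIM_CONDITIONS = ("LPS", "IL246", "IL18")
#: Stratum order: frequencies, endogenous activity, then stimulation responses.
STRATA = ("freq", "unstim", "LPS", "IL246", "IL18")

# 33 mononuclear subsets + 2 granulocyte subsets = 35 gated populations.
DEFAULT_MONONUCLEAR = (
    "cMC", "intMC", "ncMC", "mDC", "pDC",
    "NK_CD56bright", "NK_CD56dim", "NK_CD16hi", "NK_CD57pos", "NKT_like",
    "Bcells", "Plasmablasts",
    "CD4T_naive", "CD4T_cm", "CD4T_em", "CD4T_emra",
    "Th1", "Th2", "Th17", "Tfh", "Treg_naive", "Treg_memory",
    "CD8T_naive", "CD8T_cm", "CD8T_em", "CD8T_emra",
    "gdT", "MAIT", "DNT", "Ki67_CD4T", "Ki67_CD8T", "Basophils", "ILC",
)
DEFAULT_GRANULOCYTES = ("Neutrophils", "Eosinophils")
DEFAULT_CELL_TYPES = DEFAULT_MONONUCLEAR + DEFAULT_GRANULOCYTES

# 20 functional read-outs: phospho-signaling proteins, metabolic enzymes and
# transporters, chemotactic receptors, proliferation/apoptosis and chromatin
# marks.  Together with 35 cell types this closes the 700-feature endogenous
# grid.
DEFAULT_MARKERS = (
    "pCREB", "pSTAT1", "pSTAT3", "pSTAT5", "pSTAT6", "pNFkB", "pERK12",
    "pp38", "pS6", "pPLCg1", "GLUT1", "HK2", "CPT1a", "VDAC1",
    "CXCR4", "CD62L", "CD63", "Ki67", "cPARP", "H3K27me3",
)

MYELOID = ("cMC", "intMC", "ncMC", "mDC", "pDC", "Basophils",
           "Neutrophils", "Eosinophils")
NK_LIKE = ("NK_CD56bright", "NK_CD56dim", "NK_CD16hi", "NK_CD57pos", "NKT_like")
T_CELLS = ("CD4T_naive", "CD4T_cm", "CD4T_em", "CD4T_emra", "Th1", "Th2",
           "Th17", "Tfh", "Treg_naive", "Treg_memory", "CD8T_naive",
           "CD8T_cm", "CD8T_em", "CD8T_emra", "gdT", "MAIT", "DNT",
           "Ki67_CD4T", "Ki67_CD8T")
B_CELLS = ("Bcells", "Plasmablasts")

MYD88_MARKERS = ("pNFkB", "pERK12", "pp38", "pCREB", "pS6")
JAK_STAT_MARKERS = ("pSTAT1", "pSTAT3", "pSTAT5", "pSTAT6")
METABOLIC_MARKERS = ("GLUT1", "HK2", "CPT1a", "VDAC1")
CHEMOTACTIC_MARKERS = ("CXCR4", "CD62L", "CD63")


def feature_id(stratum: str, cell_type: str, marker: str = "frequency") -> str:
    """Canonical feature id ``stratum|cell_type|marker``."""
    return f"{stratum}|{cell_type}|{marker}"


@dataclass(frozen=True)
class FeatureDerivationConfig:
    arcsinh_cofactor: float = 5.0
    mononuclear_types: tuple[str, ...] = DEFAULT_MONONUCLEAR
    granulocyte_types: tuple[str, ...] = DEFAULT_GRANULOCYTES
    min_cells: int = 3

    def __post_init__(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh cofactor must be positive")
        overlap = set(self.mononuclear_types) & set(self.granulocyte_types)
        if overlap:
            raise ValueError(f"mononuclear and granulocyte sets overlap: {sorted(overlap)}")


def arcsinh_transform(x, cofactor: float = 5.0):
    """arcsinh(x / cofactor); strictly increasing, odd, ~ln(2x/cofactor) for large x."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


class PenalizationMatrix:
    """Binary include/exclude mask over (cell type, marker, condition) plus
    per-cell-type frequency include flags.

    ``signaling`` maps (cell_type, marker, condition) -> {0, 1} where the
    condition is one of ``unstim``/``LPS``/``IL246``/``IL18`` strata; a value
    of 1 means the feature enters the analysis.
    """

    def __init__(self, signaling: dict[tuple[str, str, str], int],
                 freq_include: dict[str, int]):
        for key, v in signaling.items():
            if v not in (0, 1):
                raise ValueError(f"mask value for {key} must be 0 or 1, got {v}")
        for ct, v in freq_include.items():
            if v not in (0, 1):
                raise ValueError(f"frequency mask value for {ct} must be 0 or 1, got {v}")
        self.signaling = dict(signaling)
        self.freq_include = dict(freq_include)

    def include(self, stratum: str, cell_type: str, marker: str) -> int:
        if stratum == "freq":
            return self.freq_include[cell_type]
        return self.signaling[(cell_type, marker, stratum)]

    def stratum_sizes(self) -> dict[str, int]:
        sizes = {"freq": sum(self.freq_include.values())}
        for stratum in ("unstim",) + STIM_CONDITIONS:
            sizes[stratum] = sum(v for (ct, m, c), v in self.signaling.items()
                                 if c == stratum)
        return sizes

    def feature_ids(self, cell_types: tuple[str, ...],
                    markers: tuple[str, ...]) -> list[str]:
        """Retained feature ids in canonical order (stratum, cell type, marker)."""
        ids = [feature_id("freq", ct) for ct in cell_types
               if self.freq_include.get(ct, 0)]
        for stratum in ("unstim",) + STIM_CONDITIONS:
            for ct in cell_types:
                for m in sorted(markers):
                    if self.signaling.get((ct, m, stratum), 0):
                        ids.append(feature_id(stratum, ct, m))
        return ids

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cell_type": ct, "marker": "frequency", "condition": "freq",
                 "include": v} for ct, v in self.freq_include.items()]
        rows += [{"cell_type": ct, "marker": m, "condition": c, "include": v}
                 for (ct, m, c), v in self.signaling.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PenalizationMatrix":
        required = {"cell_type", "marker", "condition", "include"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"mask table missing columns: {sorted(missing)}")
        bad = set(df["include"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"mask values outside {{0,1}}: {sorted(bad)}")
        freq = df[df["condition"] == "freq"]
        sig = df[df["condition"] != "freq"]
        return cls(
            {(r.cell_type, r.marker, r.condition): int(r.include)
             for r in sig.itertuples()},
            {r.cell_type: int(r.include) for r in freq.itertuples()},
        )

    @classmethod
    def from_csv(cls, path) -> "PenalizationMatrix":
        return cls.from_frame(pd.read_csv(path))


def _pathway_score(cell_type: str, marker: str, condition: str) -> int:
    """Prior-knowledge tier: 2 = canonical direct response, 1 = unclear
    (retained), 0 = excluded (pathway known not to engage)."""
    if condition == "LPS":
        # TLR4/MyD88 signaling is myeloid-restricted; lymphocytes generally
        # lack TLR4, so their direct LPS signaling responses are excluded.
        # Metabolic and chemotactic read-outs are treated as unclear in all
        # cell types (indirect effects within 15 min are not ruled out).
        if cell_type in MYELOID and marker in MYD88_MARKERS:
            return 2
        if marker in METABOLIC_MARKERS + CHEMOTACTIC_MARKERS:
            return 1
        return 1 if cell_type in MYELOID else 0
    if condition == "IL246":
        # IL-2/IL-4/IL-6 engage JAK/STAT broadly across lymphoid and myeloid
        # cells, with downstream MAPK/mTOR and metabolic/chemotactic shifts.
        if marker in JAK_STAT_MARKERS:
            return 2
        if marker in ("pS6", "pERK12", "pCREB") + METABOLIC_MARKERS + CHEMOTACTIC_MARKERS:
            return 1
        return 1 if cell_type in T_CELLS + NK_LIKE + B_CELLS else 0
    if condition == "IL18":
        # IL-18R signals through MyD88/NFkB, principally in NK, NKT-like and
        # T subsets plus monocytes; metabolic re-wiring is plausible broadly.
        if cell_type in NK_LIKE + T_CELLS + ("cMC", "intMC", "ncMC"):
            if marker in MYD88_MARKERS:
                return 2
            if marker in METABOLIC_MARKERS + CHEMOTACTIC_MARKERS:
                return 1
            return 1
        return 1 if cell_type in MYELOID and marker in MYD88_MARKERS else 0
    raise ValueError(f"unknown stimulation condition {condition!r}")


DEFAULT_STRATUM_SIZES = {"freq": 35, "unstim": 700, "LPS": 248,
                         "IL246": 635, "IL18": 554}


def build_default_mask(
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    stratum_sizes: dict[str, int] | None = None,
) -> PenalizationMatrix:
    """Canonical-pathway penalization mask with configurable per-stratum totals.

    All frequency and endogenous features are retained.  For each stimulation
    stratum, (cell type, marker) pairs are ranked by prior-knowledge tier
    (canonical direct response > unclear > excluded) with a deterministic
    tie-break on cell-type then marker order, and the top ``stratum_sizes``
    pairs are included.  With the default 35x20 grid the default totals are
    35 + 700 + 248 + 635 + 554 = 2172 features.
    """
    sizes = dict(DEFAULT_STRATUM_SIZES if stratum_sizes is None else stratum_sizes)
    n_pairs = len(cell_types) * len(markers)
    for stratum in ("unstim",) + STIM_CONDITIONS:
        if sizes.get(stratum, 0) > n_pairs:
            raise ValueError(
                f"stratum {stratum!r} requests {sizes[stratum]} features but the "
                f"grid has only {n_pairs} (cell type, marker) pairs")
    freq_include = {ct: 1 if i < sizes.get("freq", len(cell_types)) else 0
                    for i, ct in enumerate(cell_types)}
    signaling: dict[tuple[str, str, str], int] = {}
    for ct in cell_types:
        for m in markers:
            signaling[(ct, m, "unstim")] = 0
    order = [(ct, m) for ct in cell_types for m in markers]
    # endogenous stratum: retained up to the configured total, in grid order
    for ct, m in order[: sizes.get("unstim", n_pairs)]:
        signaling[(ct, m, "unstim")] = 1
    for stratum in STIM_CONDITIONS:
        ranked = sorted(
            order,
            key=lambda p: (-_pathway_score(p[0], p[1], stratum),
                           cell_types.index(p[0]), markers.index(p[1])),
        )
        keep = set(ranked[: sizes.get(stratum, n_pairs)])
        for ct, m in order:
            signaling[(ct, m, stratum)] = 1 if (ct, m) in keep else 0
    return PenalizationMatrix(signaling, freq_include)


def _check_events(events: pd.DataFrame, markers: list[str]) -> None:
    required = {"sample_id", "condition", "cell_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    absent = [m for m in markers if m not in events.columns]
    if absent:
        raise ValueError(f"event table missing marker columns: {absent}")


def cell_frequencies(events: pd.DataFrame,
                     config: FeatureDerivationConfig | None = None) -> pd.DataFrame:
    """Cell-type frequency features from the unstimulated aliquot.

    Mononuclear subsets are expressed as a percentage of mononuclear events;
    granulocyte subsets as a percentage of all singlet leukocyte events.
    Returns samples x ``freq|cell_type|frequency`` columns, values in [0, 100].
    """
    config = config or FeatureDerivationConfig()
    _check_events(events, [])
    unstim = events[events["condition"] == "Unstim"]
    if unstim.empty:
        raise ValueError("no unstimulated events; frequencies are computed from the Unstim aliquot")
    counts = unstim.groupby(["sample_id", "cell_type"], observed=True).size().unstack(fill_value=0)
    for ct in config.mononuclear_types + config.granulocyte_types:
        if ct not in counts.columns:
            counts[ct] = 0
    mono = [ct for ct in config.mononuclear_types]
    gran = [ct for ct in config.granulocyte_types]
    mono_total = counts[mono].sum(axis=1)
    zero = mono_total[mono_total == 0]
    if not zero.empty:
        raise ValueError(f"zero mononuclear events for samples: {list(zero.index)}")
    leuk_total = counts.sum(axis=1)
    out = pd.DataFrame(index=counts.index)
    for ct in mono:
        out[feature_id("freq", ct)] = 100.0 * counts[ct] / mono_total
    for ct in gran:
        out[feature_id("freq", ct)] = 100.0 * counts[ct] / leuk_total
    out.index.name = "sample_id"
    return out


def _median_intensities(events: pd.DataFrame, markers: list[str],
                        min_cells: int) -> pd.DataFrame:
    """Median raw intensity per (sample, condition, cell type, marker).

    Cell populations observed with fewer than ``min_cells`` events in a
    condition are rejected: medians of so few cells are unstable and no
    imputation is performed downstream.
    """
    grouped = events.groupby(["sample_id", "condition", "cell_type"], observed=True)
    sizes = grouped.size()
    thin = sizes[sizes < min_cells]
    if not thin.empty:
        raise ValueError(
            "insufficient cells (< {0}) for a valid median in: {1}".format(
                min_cells, [tuple(k) for k in thin.index[:20]]))
    return grouped[markers].median()


def signaling_features(events: pd.DataFrame,
                       config: FeatureDerivationConfig | None = None,
                       markers: list[str] | None = None) -> pd.DataFrame:
    """Endogenous and stimulation-response signaling features.

    Endogenous (``unstim`` stratum): arcsinh-transformed median intensity in
    the unstimulated aliquot per (cell type, marker).  Response strata: the
    difference in arcsinh-transformed medians between the stimulated and the
    unstimulated aliquot — the arcsinh ratio of the raw medians.
    """
    config = config or FeatureDerivationConfig()
    if markers is None:
        skip = {"sample_id", "condition", "cell_type"}
        markers = [c for c in events.columns if c not in skip]
    _check_events(events, markers)
    med = _median_intensities(events, markers, config.min_cells)
    asinh = arcsinh_transform(med, config.arcsinh_cofactor)
    asinh = pd.DataFrame(asinh, index=med.index, columns=med.columns)
    present_conditions = events["condition"].unique()
    cell_types = [ct for ct in (config.mononuclear_types + config.granulocyte_types)
                  if ct in set(events["cell_type"].unique())]
    wide = asinh.unstack(["condition", "cell_type"])  # columns (marker, condition, cell_type)
    cols: dict[str, pd.Series] = {}
    for ct in cell_types:
        for m in sorted(markers):
            base = wide[(m, "Unstim", ct)]
            cols[feature_id("unstim", ct, m)] = base
            for stim in STIM_CONDITIONS:
                if stim in present_conditions:
                    cols[feature_id(stim, ct, m)] = wide[(m, stim, ct)] - base
    out = pd.DataFrame(cols, index=wide.index)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing medians (cell type absent in a condition) for: {bad[:20]}")
    # canonical column order: stratum, then cell type, then marker
    ordered = [feature_id(s, ct, m)
               for s in ("unstim",) + STIM_CONDITIONS
               for ct in cell_types for m in sorted(markers)
               if feature_id(s, ct, m) in out.columns]
    out = out[ordered]
    out.index.name = "sample_id"
    return out


def apply_penalization(table: pd.DataFrame, mask: PenalizationMatrix) -> pd.DataFrame:
    """Drop masked-out feature columns, preserving column order.

    Every column of ``table`` must be covered by the mask; a missing entry is
    an error rather than a silent exclusion.
    """
    keep = []
    for col in table.columns:
        stratum, ct, marker = col.split("|")
        try:
            inc = mask.include(stratum, ct, marker)
        except KeyError as exc:
            raise ValueError(f"penalization mask does not cover feature {col!r}") from exc
        if inc:
            keep.append(col)
    return table[keep]


def derive_features(events: pd.DataFrame,
                    config: FeatureDerivationConfig | None = None,
                    mask: PenalizationMatrix | None = None) -> pd.DataFrame:
    """Full per-sample feature table: frequencies + signaling, optionally masked."""
    config = config or FeatureDerivationConfig()
    freq = cell_frequencies(events, config)
    sig = signaling_features(events, config)
    table = freq.join(sig, how="inner")
    if len(table) != len(freq):
        missing = sorted(set(freq.index) ^ set(sig.index))
        raise ValueError(f"samples missing from one feature family: {missing}")
    if mask is not None:
        table = apply_penalization(table, mask)
    return table


def split_by_stratum(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a feature table into the five strata by feature-id prefix."""
    out = {}
    for stratum in STRATA:
        cols = [c for c in table.columns if c.startswith(stratum + "|")]
        if cols:
            out[stratum] = table[cols]
    return out


def stratum_of(col: str) -> str:
    return col.split("|", 1)[0]


def write_events_csv(events: pd.DataFrame, path) -> None:
    """Long-format event CSV: sample_id, condition, cell_type, marker, value."""
    skip = {"sample_id", "condition", "cell_type"}
    markers = [c for c in events.columns if c not in skip]
    long = events.melt(id_vars=["sample_id", "condition", "cell_type"],
                       value_vars=markers, var_name="marker", value_name="value")
    long.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    required = {"sample_id", "condition", "cell_type", "marker", "value"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    long["_cell"] = long.groupby(
        ["sample_id", "condition", "cell_type", "marker"]).cumcount()
    wide = long.pivot_table(index=["sample_id", "condition", "cell_type", "_cell"],
                            columns="marker", values="value").reset_index()
    wide.columns.name = None
    return wide.drop(columns="_cell")
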