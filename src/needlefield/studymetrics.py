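"""Small stroke-study formulas and filters, with toy-table fixtures.

The quantitative recipes from the in-vivo side of an HD-tDCS stroke study
that are pure arithmetic on small tables:

* edema-corrected infarct volume from serial brain sections,
* qPCR relative expression (2^-ddCt),
* novel-object-recognition index and turn/freezing percentages,
* differential-expression filtering with fold-change / expression-level /
  p-value cutoffs (strict inequalities),
* laser-Doppler cerebral-blood-flow inclusion rules for the arterial
  occlusion model.

Tables are plain :class:`pandas.DataFrame` objects; CSV round-trips use the
column names documented in each function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InfarctSections",
    "DegThresholds",
    "corrected_infarct_volume",
    "ddct_fold_change",
    "recognition_index",
    "proportion_percent",
    "deg_filter",
    "mcao_inclusion",
    "make_toy_study_tables",
]


@dataclass
class InfarctSections:
    """Per-section hemisphere and infarct areas (mm^2) with slice thickness (mm).

    CSV columns: ``contralateral_mm2, ipsilateral_mm2, infarct_mm2``.
    """

    contralateral: np.ndarray
    ipsilateral: np.ndarray
    infarct: np.ndarray
    thickness: float

    def __post_init__(self) -> None:
        self.contralateral = np.atleast_1d(np.asarray(self.contralateral, float))
        self.ipsilateral = np.atleast_1d(np.asarray(self.ipsilateral, float))
        self.infarct = np.atleast_1d(np.asarray(self.infarct, float))
        if not (
            len(self.contralateral) == len(self.ipsilateral) == len(self.infarct)
        ):
            raise ValueError("section arrays must have equal length")
        if self.thickness <= 0:
            raise ValueError("section thickness must be positive")
        for name, arr in (
            ("contralateral", self.contralateral),
            ("ipsilateral", self.ipsilateral),
            ("infarct", self.infarct),
        ):
            if (arr < 0).any():
                raise ValueError(f"negative {name} area")
        if (self.infarct > self.ipsilateral).any():
            raise ValueError("infarct area exceeds ipsilateral hemisphere area")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, thickness: float) -> "InfarctSections":
        return cls(
            df["contralateral_mm2"].to_numpy(),
            df["ipsilateral_mm2"].to_numpy(),
            df["infarct_mm2"].to_numpy(),
            thickness,
        )


@dataclass
class DegThresholds:
    """Differential-expression cutoffs (all strict inequalities)."""

    fold_change_min: float = 1.5
    log2_norm_min: float = 2.0
    p_max: float = 0.05
    #: 'linear' applies the cutoff to the signed linear fold change;
    #: 'log2' interprets the fold-change column as log2 values.
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.fold_change_min <= 1 and self.scale == "linear":
            raise ValueError("fold_change_min must exceed 1")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if self.scale not in ("linear", "log2"):
            raise ValueError("scale must be 'linear' or 'log2'")


def corrected_infarct_volume(sections: InfarctSections) -> float:
    """Edema-corrected infarct volume (mm^3).

    Per section: [contralateral area - (ipsilateral area - infarct area)]
    x thickness, summed over sections; subtracting the non-infarcted
    ipsilateral tissue from the contralateral hemisphere corrects for
    edema-driven swelling of the injured hemisphere.
    """
    per = (
        sections.contralateral - (sections.ipsilateral - sections.infarct)
    ) * sections.thickness
    return float(per.sum())


def ddct_fold_change(delta_delta_ct: float) -> float:
    """Relative qPCR expression 2^(-ddCt)."""
    ddct = np.asarray(delta_delta_ct, dtype=np.float64)
    if not np.isfinite(ddct).all():
        raise ValueError("ddCt must be finite")
    return float(2.0 ** (-ddct)) if ddct.ndim == 0 else 2.0 ** (-ddct)


def recognition_index(time_novel: float, time_familiar: float) -> float:
    """Novel-object recognition index (%): 100 B / (B + A)."""
    if time_novel < 0 or time_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = time_novel + time_familiar
    if total == 0:
        raise ValueError("at least one exploration time must be positive")
    return 100.0 * time_novel / total


def proportion_percent(count: float, total: float) -> float:
    """Percentage of events (e.g. ipsilateral turns, freezing time)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    return 100.0 * count / total


def deg_filter(
    table: pd.DataFrame, thresholds: DegThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a gene table into (upregulated, downregulated) by strict cutoffs.

    Columns: ``gene, fold_change, log2_norm, p`` — signed linear fold change
    (or log2 fold change with ``thresholds.scale='log2'``), normalised log2
    expression, and p-value.  Row order is preserved; rows on a threshold
    boundary are excluded.
    """
    th = thresholds or DegThresholds()
    required = {"gene", "fold_change", "log2_norm", "p"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(table):
        for col in ("fold_change", "log2_norm", "p"):
            if not np.isfinite(table[col]).all():
                raise ValueError(f"non-finite values in {col!r}")
        if ((table["p"] < 0) | (table["p"] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
    fc = table["fold_change"] if len(table) else pd.Series(dtype=float)
    cut = th.fold_change_min if th.scale == "linear" else np.log2(th.fold_change_min)
    base = (table["log2_norm"] > th.log2_norm_min) & (table["p"] < th.p_max)
    up = table[(fc > cut) & base] if len(table) else table
    down = table[(fc < -cut) & base] if len(table) else table
    return up, down


def mcao_inclusion(
    cbf_drop_at_occlusion_percent: float,
    cbf_drop_pre_reperfusion_percent: float,
) -> tuple[bool, str]:
    """Cerebral-blood-flow inclusion rules for the occlusion model.

    Include when the CBF drop at occlusion is at least 80% of baseline and
    the drop measured just before the intended reperfusion still exceeds
    30% (a drop that has recovered to 30% or less indicates premature
    reperfusion and excludes the animal).
    """
    for v in (cbf_drop_at_occlusion_percent, cbf_drop_pre_reperfusion_percent):
        if not 0 <= v <= 100:
            raise ValueError("CBF drop percentages must lie in [0, 100]")
    if cbf_drop_at_occlusion_percent < 80.0:
        return False, "occlusion drop < 80%"
    if cbf_drop_pre_reperfusion_percent <= 30.0:
        return False, "pre-reperfusion drop <= 30%"
    return True, "included"


def make_toy_study_tables(seed: int) -> dict:
    """Deterministic synthetic fixture bundle for the study formulas.

    Returns a dict with ``sections`` (InfarctSections), ``ct`` (qPCR ddCt
    table), ``exploration`` (novel/familiar times), and ``deg`` (gene table
    guaranteed to contain rows passing and failing every cutoff).
    """
    rng = np.random.default_rng(seed)
    n_sec = 10
    contra = rng.uniform(8.0, 12.0, n_sec)
    infarct = rng.uniform(0.5, 3.0, n_sec)
    # edema: the injured hemisphere swells around the infarct
    ipsi = contra - infarct * rng.uniform(0.3, 0.9, n_sec) + infarct
    sections = InfarctSections(contra, ipsi, infarct, thickness=0.075)

    genes = [f"g{i}" for i in range(1, 9)]
    ct = pd.DataFrame(
        {
            "gene": genes,
            "ddct": np.round(rng.normal(0.0, 1.5, len(genes)), 3),
        }
    )
    ct["fold_change"] = 2.0 ** (-ct["ddct"])

    exploration = pd.DataFrame(
        {
            "animal": [f"m{i}" for i in range(1, 7)],
            "time_novel_s": np.round(rng.uniform(5.0, 40.0, 6), 1),
            "time_familiar_s": np.round(rng.uniform(5.0, 40.0, 6), 1),
        }
    )

    # DEG table: guaranteed pass/fail rows for each cutoff plus random rows
    fixed = pd.DataFrame(
        {
            "gene": ["up_hit", "down_hit", "weak_fc", "low_expr", "high_p"],
            "fold_change": [2.0, -2.0, 1.2, 2.0, 2.0],
            "log2_norm": [3.0, 3.0, 3.0, 1.0, 3.0],
            "p": [0.01, 0.01, 0.01, 0.01, 0.2],
        }
    )
    rand = pd.DataFrame(
        {
            "gene": [f"r{i}" for i in range(10)],
            "fold_change": np.round(rng.normal(0, 2.0, 10), 2),
            "log2_norm": np.round(rng.uniform(0.0, 6.0, 10), 2),
            "p": np.round(rng.uniform(0.0, 1.0, 10), 3),
        }
    )
    deg = pd.concat([fixed, rand], ignore_index=True)
    return {"sections": sections, "ct": ct, "exploration": exploration, "deg": deg}
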