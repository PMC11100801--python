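"""Molecular-assay normalizations and the animal-level statistics contract.

Closed-form normalizations:

* qPCR relative quantification by the 2^-ddCt method against a reference
  gene (18S) and a control group:
  dCt = Ct_target - Ct_reference; ddCt = dCt - mean control dCt;
  fold change = 2^-ddCt.
* ELISA target protein per total protein:
  pg per 100 mg protein = (conc_pg_per_ml * 100) / (total_protein_mg_per_ml * 1000).

Statistics contract: group comparisons run on animal-level summaries
(the unweighted mean of each animal's cells or images), never on raw
cell rows, so the animal is the unit of analysis.  Models are fit first
with sex as a factor; when sex shows no main effect (p >= 0.05) the
model is refit pooled across sexes, and the pooling decision is
reported.  Pairwise comparisons use a Sidak correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .io_core import logger

__all__ = [
    "average_triplicates",
    "ddct_fold_change",
    "ddct_table",
    "elisa_normalize",
    "aggregate_to_animal",
    "group_compare",
    "GroupComparison",
]


def average_triplicates(ct_values, max_dev: float = 0.5) -> float:
    """Mean Ct of technical replicates after discarding outliers.

    Replicates more than ``max_dev`` cycles from the replicate median are
    discarded (and logged) before averaging.
    """
    cts = np.asarray([c for c in ct_values if np.isfinite(c)], dtype=float)
    if cts.size == 0:
        raise ValueError("no finite Ct replicates")
    med = np.median(cts)
    keep = np.abs(cts - med) <= max_dev
    if not keep.all():
        logger.info(
            "average_triplicates: discarded %d replicate(s) > %.2f cycles from median",
            int((~keep).sum()), max_dev,
        )
    return float(cts[keep].mean())


def ddct_fold_change(
    ct_target: float, ct_reference: float, control_mean_dct: float
) -> float:
    """Fold change by 2^-ddCt relative to the control group's mean dCt."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("missing Ct value")
    dct = ct_target - ct_reference
    ddct = dct - control_mean_dct
    return float(2.0 ** (-ddct))


def ddct_table(
    samples: pd.DataFrame,
    control_group: str,
    group_col: str = "group",
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
) -> pd.DataFrame:
    """Per-sample fold changes against a named control group.

    Samples with a missing Ct are excluded with a log entry, never
    silently.  The control group's mean dCt is computed from the included
    control samples; control fold changes therefore centre on 1.
    """
    df = samples.copy()
    ok = np.isfinite(df[target_col]) & np.isfinite(df[reference_col])
    if not ok.all():
        for _, row in df[~ok].iterrows():
            logger.info("ddct_table: excluded sample %r (missing Ct)", row.get("sample_id"))
    df = df[ok].copy()
    ctrl = df[df[group_col] == control_group]
    if ctrl.empty:
        raise ValueError(f"no usable samples in control group {control_group!r}")
    df["dct"] = df[target_col] - df[reference_col]
    control_mean_dct = float(ctrl[target_col].mean() - ctrl[reference_col].mean())
    df["ddct"] = df["dct"] - control_mean_dct
    df["fold_change"] = 2.0 ** (-df["ddct"])
    return df


def elisa_normalize(
    concentration_pg_per_ml: float, total_protein_mg_per_ml: float
) -> float:
    """Target protein per 100 mg total protein:
    ``(conc_pg_per_ml * 100) / (total_protein_mg_per_ml * 1000)``."""
    if total_protein_mg_per_ml <= 0:
        raise ValueError("total protein must be positive")
    if concentration_pg_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return (concentration_pg_per_ml * 100.0) / (total_protein_mg_per_ml * 1000.0)


def aggregate_to_animal(
    cell_table: pd.DataFrame,
    measure: str,
    group_cols: tuple[str, ...] = (),
    animal_col: str = "animal_id",
) -> pd.DataFrame:
    """Unweighted per-animal mean of a measure over that animal's units.

    Carries any group labels along (they must be constant within animal)
    and records the contributing n.
    """
    if animal_col not in cell_table.columns:
        raise ValueError(f"column {animal_col!r} required on every row")
    keys = [animal_col, *group_cols]
    grouped = cell_table.groupby(keys, sort=True, dropna=False)
    out = grouped.agg(**{measure: (measure, "mean"), "n_units": (measure, "size")})
    return out.reset_index()


@dataclass
class GroupComparison:
    """Result of a factorial group comparison on animal summaries."""

    effects: pd.DataFrame  # ANOVA table (factor, F, p)
    pairwise: pd.DataFrame  # group pairs with raw and Sidak-adjusted p
    sex_pooled: bool | None  # None when no sex column was modeled
    sex_p: float | None
    formula: str
    notes: list[str] = field(default_factory=list)

    def effect_p(self, factor: str) -> float:
        row = self.effects.loc[self.effects.factor.str.contains(factor, regex=False)]
        if row.empty:
            raise KeyError(f"factor {factor!r} not in {list(self.effects.factor)}")
        return float(row.iloc[0]["p"])


def _anova(df: pd.DataFrame, measure: str, factors: list[str]) -> tuple[pd.DataFrame, str]:
    terms = " * ".join(f"C({f})" for f in factors)
    formula = f"{measure} ~ {terms}"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    eff = (
        table.reset_index()
        .rename(columns={"index": "factor", "PR(>F)": "p", "F": "F"})
        [["factor", "F", "p"]]
    )
    eff = eff[eff.factor != "Residual"]
    return eff, formula


def _sidak(p: float, m: int) -> float:
    return float(1.0 - (1.0 - p) ** m) if m > 1 else float(p)


def group_compare(
    summaries: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    sex_col: str | None = None,
    extra_factors: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> GroupComparison:
    """Factorial comparison of animal summaries with the sex-first contract.

    Fit the model including sex; if sex has no main effect at ``alpha``,
    refit pooled across sexes.  Pairwise group comparisons (Welch t
    tests on the final model's data) are Sidak-adjusted over the number
    of pairs.  Raises on singular designs (a group with < 2 animals or a
    single group).
    """
    groups = summaries[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    sizes = summaries.groupby(group_col, observed=True)[measure].size()
    if (sizes < 2).any():
        raise ValueError(f"singular design: group sizes {dict(sizes)}")

    notes: list[str] = []
    factors = [group_col, *extra_factors]
    sex_pooled: bool | None = None
    sex_p: float | None = None
    if sex_col is not None:
        eff_sex, formula = _anova(summaries, measure, [sex_col, *factors])
        sex_p = float(eff_sex.loc[eff_sex.factor == f"C({sex_col})", "p"].iloc[0])
        if sex_p >= alpha:
            sex_pooled = True
            notes.append(
                f"no main effect of {sex_col} (p={sex_p:.3f} >= {alpha}); "
                "sexes pooled and model refit"
            )
            effects, formula = _anova(summaries, measure, factors)
        else:
            sex_pooled = False
            notes.append(f"main effect of {sex_col} (p={sex_p:.3f}); sex retained")
            effects = eff_sex
    else:
        effects, formula = _anova(summaries, measure, factors)

    pairs = []
    m = len(list(combinations(sorted(groups), 2)))
    for a, b in combinations(sorted(groups), 2):
        xa = summaries.loc[summaries[group_col] == a, measure]
        xb = summaries.loc[summaries[group_col] == b, measure]
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        pairs.append(
            {"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p),
             "p_sidak": _sidak(float(p), m)}
        )
    for note in notes:
        logger.info("group_compare: %s", note)
    return GroupComparison(
        effects=effects,
        pairwise=pd.DataFrame(pairs),
        sex_pooled=sex_pooled,
        sex_p=sex_p,
        formula=formula,
        notes=notes,
    )
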