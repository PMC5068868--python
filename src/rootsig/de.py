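"""Differential-expression selection: t-test + fold-change thresholding.

The selection rule is the conjunction of two configurable cutoffs applied
per gene: a two-sided t-test p-value (Welch or Student, paired or unpaired)
below ``p_cutoff`` (default 0.05, **unadjusted** — no multiple-testing
correction, deliberately, so list sizes stay comparable across biosets at the
cost of a known per-gene false-positive rate), and a signed linear fold
change of magnitude at least ``fc_cutoff`` (default 1.2, inclusive).

Fold change is the ratio of case to control group means on the linear
intensity scale, reported as the negative reciprocal when below 1, so its
magnitude is always >= 1 and sign encodes direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Bioset, normalize_symbols
from .simulate import ExpressionBioset

logger = logging.getLogger(__name__)

DEFAULT_P_CUTOFF = 0.05
DEFAULT_FC_CUTOFF = 1.2


def t_test(
    case_values,
    control_values,
    variant: str = "welch",
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test; returns (statistic, p_value).

    Conventions for degenerate inputs: zero variance in both groups with
    equal means gives p=1 (statistic 0); zero variance with unequal means
    gives p=0. A paired test reduces to the one-sample test on differences,
    with all-zero differences giving p=1.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        if case.size != control.size:
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(case, control)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # zero-variance differences
            d = case - control
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = float(np.sign(d.mean()) * np.inf), 0.0
        return stat, p
    res = stats.ttest_ind(case, control, equal_var=(variant == "student"))
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # both groups zero-variance
        if case.mean() == control.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = float(np.sign(case.mean() - control.mean()) * np.inf), 0.0
    return stat, p


def fold_change(case_values, control_values, gene: str | None = None) -> float:
    """Signed linear fold change of group means.

    r = mean(case)/mean(control); returns r if r >= 1 else -1/r, so the
    magnitude is always >= 1. Raises on nonpositive group means (log-scale
    intensities must be exponentiated before calling).
    """
    mc = float(np.mean(case_values))
    mk = float(np.mean(control_values))
    if mc <= 0 or mk <= 0:
        label = f" for gene {gene}" if gene else ""
        raise ValueError(f"nonpositive group mean{label}: case={mc}, control={mk}")
    r = mc / mk
    return r if r >= 1.0 else -1.0 / r


@dataclass(frozen=True)
class DESelection:
    """Result of DE selection on one expression bioset."""

    bioset: Bioset  # the selected gene list with metadata
    table: pd.DataFrame  # gene, fold_change, p_value, selected


def _vectorized_p(case: np.ndarray, control: np.ndarray, variant: str,
                  paired: bool) -> np.ndarray:
    if paired:
        res = stats.ttest_rel(case, control, axis=1)
    else:
        res = stats.ttest_ind(case, control, axis=1,
                              equal_var=(variant == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    nan = np.isnan(p)
    if nan.any():
        equal = np.isclose(case.mean(axis=1), control.mean(axis=1))
        p[nan & equal] = 1.0
        p[nan & ~equal] = 0.0
    return p


def select_de_genes(
    bioset: ExpressionBioset,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    variant: str = "welch",
    paired: bool | None = None,
) -> DESelection:
    """Apply the two-cutoff DE rule to every gene of an expression bioset.

    ``paired`` defaults to the bioset's own flag. Symbols of selected genes
    are normalized (uppercased, deduplicated). An empty result is legal and
    logged, not an error.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    use_paired = bioset.paired if paired is None else paired
    case = bioset.case_matrix()
    control = bioset.control_matrix()
    genes = bioset.values.index.to_numpy()

    mc = case.mean(axis=1)
    mk = control.mean(axis=1)
    bad = (mc <= 0) | (mk <= 0)
    if bad.any():
        raise ValueError(
            f"nonpositive group mean for gene {genes[bad][0]} "
            f"in bioset {bioset.bioset_id}"
        )
    r = mc / mk
    fc = np.where(r >= 1.0, r, -1.0 / r)
    p = _vectorized_p(case, control, variant, use_paired)
    selected = (p < p_cutoff) & (np.abs(fc) >= fc_cutoff)

    table = pd.DataFrame(
        {"gene": genes, "fold_change": fc, "p_value": p, "selected": selected}
    )
    symbols, _ = normalize_symbols(genes[selected].tolist())
    if not symbols:
        logger.info("bioset %s: no genes passed DE selection", bioset.bioset_id)
    out = Bioset(
        bioset_id=bioset.bioset_id,
        experiment_id=bioset.experiment_id,
        tissue=bioset.tissue,
        genes=symbols,
    )
    return DESelection(bioset=out, table=table)
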