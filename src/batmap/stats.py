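"""Paired cohort statistics and the lipid-vs-perfusion attribution rule.

All within-subject comparisons use the Wilcoxon matched-pairs
signed-rank test at alpha = 0.05, two-sided.  Zero differences are
dropped and tied |differences| receive midranks; the null distribution
is computed exactly (by dynamic programming over the 2^n sign
assignments) for effective n <= 25 and by the tie-corrected normal
approximation above that.  P values in [0.05, 0.10) are reported as a
"trend" label; the label plays no role in attribution.

The attribution rule formalises the protocol's reasoning: perfusion is
rapidly regulated, so a perfusion-driven FF change reverses after short
reheating, while lipid consumption is slowly regulated and persists.  A
significant FF decrease in the cold scan that is still present versus
baseline after reheating (and with no cold-to-reheated rebound) is
attributed to lipid consumption; a decrease that reverses is attributed
to perfusion.  This rule table is an interpretation of the verbal
argument, not a printed algorithm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon matched-pairs result for one VOI/quantity transition."""

    mean_change: float
    sd_change: float
    statistic: float  # min(W+, W-) over nonzero differences
    p_value: float
    significant: bool
    trend: bool
    n: int  # pairs entering the test (nonzero differences)
    degenerate: bool = False
    voi: str = ""
    quantity: str = ""
    transition: str = ""


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by DP over all sign assignments.

    Ranks may be midranks (half-integers); doubling makes them integers.
    The null distribution of W+ is symmetric about S/2 (S = sum of
    ranks), so the two-sided p is P(|W - S/2| >= |w - S/2|).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    s = int(r2.sum())
    counts = np.zeros(s + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[: s + 1 - r]
    w2 = int(round(2.0 * w_plus))
    dev = abs(2 * w2 - s)  # doubled distance from centre
    k = np.arange(s + 1)
    extreme = np.abs(2 * k - s) >= dev
    return float(counts[extreme].sum() / counts.sum())


def _normal_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    mu = ranks.sum() / 2.0
    sigma = np.sqrt((ranks**2).sum() / 4.0)
    if sigma == 0:
        return 1.0
    z = (w_plus - mu) / sigma
    return float(2.0 * norm.sf(abs(z)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
    exact_max_n: int = 25,
    voi: str = "",
    quantity: str = "",
    transition: str = "",
) -> PairedTestResult:
    """Wilcoxon matched-pairs signed-rank test on differences x - y.

    ``mean_change``/``sd_change`` summarise the raw differences (sample
    SD).  All-zero differences give the degenerate result p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equally long 1D paired samples")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_change = float(d.mean())
    sd_change = float(d.std(ddof=1))
    nz = d[d != 0]
    if nz.size == 0:
        return PairedTestResult(
            mean_change=mean_change,
            sd_change=sd_change,
            statistic=0.0,
            p_value=1.0,
            significant=False,
            trend=False,
            n=0,
            degenerate=True,
            voi=voi,
            quantity=quantity,
            transition=transition,
        )
    ranks = rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    if nz.size <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        p = _normal_two_sided_p(ranks, w_plus)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return PairedTestResult(
        mean_change=mean_change,
        sd_change=sd_change,
        statistic=min(w_plus, w_minus),
        p_value=p,
        significant=p < alpha,
        trend=alpha <= p < 0.10,
        n=int(nz.size),
        voi=voi,
        quantity=quantity,
        transition=transition,
    )


# ---------------------------------------------------------------------------
# cohort containers and protocol summaries

COOLING_TRANSITIONS = (
    ("Cold", "Baseline"),
    ("Reheated", "Baseline"),
    ("Reheated", "Cold"),
)
PROCEDURE_TRANSITIONS = (("Scan2", "Scan1"),)


@dataclass
class CohortMeasurements:
    """Per-subject, per-state VOI means (FF in percent, R2* in s^-1)."""

    data: pd.DataFrame  # columns: subject, state, voi, mean_ff_pct, mean_r2s
    protocol_mode: str = "cooling_reheating"

    def __post_init__(self) -> None:
        required = {"subject", "state", "voi", "mean_ff_pct", "mean_r2s"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"measurement table missing columns {sorted(missing)}")
        if self.data["subject"].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        if self.protocol_mode not in ("cooling_reheating", "procedure_study"):
            raise ValueError(f"unknown protocol mode {self.protocol_mode!r}")

    @property
    def states(self) -> Tuple[str, ...]:
        return (
            ("Baseline", "Cold", "Reheated")
            if self.protocol_mode == "cooling_reheating"
            else ("Scan1", "Scan2")
        )

    @property
    def transitions(self) -> Tuple[Tuple[str, str], ...]:
        return (
            COOLING_TRANSITIONS
            if self.protocol_mode == "cooling_reheating"
            else PROCEDURE_TRANSITIONS
        )

    def paired(self, voi: str, quantity: str, after: str, before: str):
        """Aligned per-subject values for one transition; subjects missing
        either state are dropped pairwise with a warning."""
        col = "mean_ff_pct" if quantity == "ff" else "mean_r2s"
        sub = self.data[self.data["voi"] == voi]
        a = sub[sub["state"] == after].set_index("subject")[col]
        b = sub[sub["state"] == before].set_index("subject")[col]
        common = a.index.intersection(b.index)
        dropped = set(a.index).symmetric_difference(b.index)
        if dropped:
            warnings.warn(
                f"subjects {sorted(dropped)} missing a state for {voi}/{quantity} "
                f"{after}-{before}; excluded pairwise"
            )
        common = sorted(common)
        return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def summarize_protocol(
    m: CohortMeasurements, alpha: float = ALPHA_DEFAULT
) -> Dict[str, pd.DataFrame]:
    """Group summary tables for the protocol.

    Returns ``states`` (per-state group mean +- SD and range of the
    individual VOI means), ``changes`` (per-transition mean/SD change
    with the Wilcoxon test), and ``contrasts`` (first-state sBAT-vs-SAT
    differences, same test machinery).
    """
    state_rows = []
    for voi in ("sbat", "sat"):
        sub = m.data[m.data["voi"] == voi]
        for quantity, col in (("ff", "mean_ff_pct"), ("r2s", "mean_r2s")):
            for state in m.states:
                vals = sub[sub["state"] == state][col].to_numpy()
                if vals.size == 0:
                    continue
                state_rows.append(
                    {
                        "voi": voi,
                        "quantity": quantity,
                        "state": state,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                        "n": int(vals.size),
                    }
                )

    change_rows = []
    for voi in ("sbat", "sat"):
        for quantity in ("ff", "r2s"):
            for after, before in m.transitions:
                a, b = m.paired(voi, quantity, after, before)
                if a.size < 2:
                    continue
                t = wilcoxon_signed_rank(
                    a, b, alpha=alpha, voi=voi, quantity=quantity,
                    transition=f"{after}-{before}",
                )
                change_rows.append(
                    {
                        "voi": voi,
                        "quantity": quantity,
                        "transition": f"{after}-{before}",
                        "mean_change": t.mean_change,
                        "sd_change": t.sd_change,
                        "statistic": t.statistic,
                        "p_value": t.p_value,
                        "significant": t.significant,
                        "trend": t.trend,
                        "n": t.n,
                    }
                )

    contrast_rows = []
    first = m.states[0]
    for quantity, col in (("ff", "mean_ff_pct"), ("r2s", "mean_r2s")):
        sub = m.data[m.data["state"] == first]
        a = sub[sub["voi"] == "sbat"].set_index("subject")[col]
        b = sub[sub["voi"] == "sat"].set_index("subject")[col]
        common = sorted(a.index.intersection(b.index))
        if len(common) >= 2:
            t = wilcoxon_signed_rank(
                a.loc[common].to_numpy(), b.loc[common].to_numpy(), alpha=alpha,
                voi="sbat-sat", quantity=quantity, transition=first,
            )
            contrast_rows.append(
                {
                    "quantity": quantity,
                    "state": first,
                    "mean_difference": t.mean_change,
                    "sd_difference": t.sd_change,
                    "p_value": t.p_value,
                    "significant": t.significant,
                    "trend": t.trend,
                    "n": t.n,
                }
            )

    return {
        "states": pd.DataFrame(state_rows),
        "changes": pd.DataFrame(change_rows),
        "contrasts": pd.DataFrame(contrast_rows),
    }


# ---------------------------------------------------------------------------
# mechanism attribution


@dataclass(frozen=True)
class AttributionResult:
    mechanism: str  # lipid | perfusion | mixed | none | indeterminate
    tests: Tuple[PairedTestResult, PairedTestResult, PairedTestResult]


def attribute_mechanism(
    t_cold_vs_base: PairedTestResult,
    t_reheat_vs_base: PairedTestResult,
    t_reheat_vs_cold: PairedTestResult,
    alpha: float = ALPHA_DEFAULT,
) -> AttributionResult:
    """Attribute a cold-induced FF decrease to lipid consumption and/or
    perfusion from the three pairwise tests of one VOI/quantity.

    Rule table (FF decrease = significant with negative mean change):
    persistent decrease (cold significant, reheated-vs-baseline
    significant, no cold-to-reheated rebound) -> lipid; reversing
    decrease (cold significant, reheated back at baseline, significant
    rebound) -> perfusion; decrease with both reheated comparisons
    significant -> mixed; no significant cold change -> none; anything
    else -> indeterminate.
    """
    tests = (t_cold_vs_base, t_reheat_vs_base, t_reheat_vs_cold)
    vois = {t.voi for t in tests if t.voi}
    quantities = {t.quantity for t in tests if t.quantity}
    if len(vois) > 1 or len(quantities) > 1:
        raise ValueError(
            f"tests come from different VOIs/quantities: {sorted(vois)} {sorted(quantities)}"
        )

    cold_sig = t_cold_vs_base.significant
    cold_down = t_cold_vs_base.mean_change < 0
    rb_sig = t_reheat_vs_base.significant
    rb_down = t_reheat_vs_base.mean_change < 0
    rc_sig = t_reheat_vs_cold.significant
    rc_up = t_reheat_vs_cold.mean_change > 0

    if not cold_sig:
        mechanism = "none"
    elif cold_down and rb_sig and rb_down and rc_sig:
        mechanism = "mixed"
    elif cold_down and rb_sig and rb_down and not rc_sig:
        mechanism = "lipid"
    elif cold_down and not rb_sig and rc_sig and rc_up:
        mechanism = "perfusion"
    else:
        mechanism = "indeterminate"
    return AttributionResult(mechanism=mechanism, tests=tests)


def attribute_from_measurements(
    m: CohortMeasurements, voi: str = "sbat", quantity: str = "ff",
    alpha: float = ALPHA_DEFAULT,
) -> AttributionResult:
    """Run the three protocol tests for one VOI/quantity and attribute."""
    if m.protocol_mode != "cooling_reheating":
        raise ValueError("attribution requires the three-state cooling-reheating mode")
    tests = []
    for after, before in COOLING_TRANSITIONS:
        a, b = m.paired(voi, quantity, after, before)
        tests.append(
            wilcoxon_signed_rank(
                a, b, alpha=alpha, voi=voi, quantity=quantity,
                transition=f"{after}-{before}",
            )
        )
    return attribute_mechanism(*tests, alpha=alpha)
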