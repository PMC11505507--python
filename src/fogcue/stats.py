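"""Stimulation-effect statistics: two-proportion z-test on FoG sample rates.

For each patient there are two recordings: one without vibratory stimulation
(the training session) and one with on-demand stimulation.  Treating each
40 Hz sample as a Bernoulli trial (FoG / not FoG), the FoG probability under a
condition is the fraction of FoG samples, and the effect of stimulation is
tested with the unpooled two-proportion z statistic

    SE = sqrt( r1 (1 - r1) / n1  +  r2 (1 - r2) / n2 ),
    z  = (r2 - r1) / SE,

where r1, n1 refer to the no-stimulation condition and r2, n2 to the
stimulation condition.  A negative z therefore means stimulation reduced the
FoG rate.  The two-sided p-value comes from the standard normal CDF.  Percent
reduction is (r1 - r2) / r1 * 100.

A Monte-Carlo binomial check under the pooled null cross-validates the normal
approximation.

Samples within an episode are strongly autocorrelated, so the Bernoulli
independence assumption is optimistic; the test quantifies the rate change,
not a causal effect (no crossover design, no multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionCounts",
    "TwoProportionResult",
    "fog_probability",
    "two_proportion_test",
    "exact_binomial_check",
    "load_packaged_counts",
    "stimulation_report",
]


@dataclass(frozen=True)
class ConditionCounts:
    """Sample counts for one recording condition."""

    n_total: int
    n_fog: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_fog <= self.n_total:
            raise ValueError("need 0 <= n_fog <= n_total")


@dataclass(frozen=True)
class TwoProportionResult:
    r1: float  # FoG probability without stimulation
    r2: float  # FoG probability with stimulation
    se: float
    z: float
    p: float
    reduction_pct: float


def fog_probability(c: ConditionCounts) -> float:
    """Fraction of samples labeled FoG under one condition."""
    return c.n_fog / c.n_total


def two_proportion_test(
    without: ConditionCounts, with_: ConditionCounts
) -> TwoProportionResult:
    """Unpooled two-proportion z-test of the stimulation effect.

    Sign convention: z < 0 when stimulation lowers the FoG rate.  The p-value
    is two-sided, 2 * Phi(-|z|).
    """
    r1 = fog_probability(without)
    r2 = fog_probability(with_)
    if r1 == 0.0:
        raise ValueError("FoG rate without stimulation is zero; reduction undefined")
    se = float(
        np.sqrt(r1 * (1 - r1) / without.n_total + r2 * (1 - r2) / with_.n_total)
    )
    if se == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = (r2 - r1) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(p, 1.0)
        if p == 0.0:  # keep p in (0, 1] even when the normal tail underflows
            p = float(np.nextafter(0, 1))
    reduction_pct = (r1 - r2) / r1 * 100.0
    return TwoProportionResult(r1=r1, r2=r2, se=se, z=z, p=p, reduction_pct=reduction_pct)


def exact_binomial_check(
    without: ConditionCounts,
    with_: ConditionCounts,
    n_sims: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo two-sided p for the difference of proportions, pooled null.

    Simulates both conditions as binomials with the pooled FoG rate and counts
    how often the absolute rate difference reaches the observed one.  The
    add-one correction keeps the estimate away from an impossible exact zero.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    rng = np.random.default_rng(seed)
    n1, n2 = without.n_total, with_.n_total
    pooled = (without.n_fog + with_.n_fog) / (n1 + n2)
    observed = abs(fog_probability(without) - fog_probability(with_))
    x1 = rng.binomial(n1, pooled, size=n_sims)
    x2 = rng.binomial(n2, pooled, size=n_sims)
    diffs = np.abs(x1 / n1 - x2 / n2)
    return (1 + int(np.sum(diffs >= observed))) / (n_sims + 1)


def load_packaged_counts() -> pd.DataFrame:
    """Per-patient with/without-stimulation sample counts shipped with the package."""
    with resources.files("fogcue.data").joinpath("stimulation_counts.csv").open() as fh:
        return pd.read_csv(fh)


def stimulation_report(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full per-patient stimulation-effect table.

    ``counts`` must have columns patient, condition ({with, without}), total,
    fog; defaults to the packaged study counts.
    """
    if counts is None:
        counts = load_packaged_counts()
    required = {"patient", "condition", "total", "fog"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    rows = []
    for patient, grp in counts.groupby("patient", sort=True):
        by_cond = {r["condition"]: ConditionCounts(int(r["total"]), int(r["fog"]))
                   for _, r in grp.iterrows()}
        if set(by_cond) != {"with", "without"}:
            raise ValueError(
                f"patient {patient}: need exactly one 'with' and one 'without' row"
            )
        res = two_proportion_test(by_cond["without"], by_cond["with"])
        rows.append(
            {
                "patient": patient,
                "n_without": by_cond["without"].n_total,
                "fog_without": by_cond["without"].n_fog,
                "n_with": by_cond["with"].n_total,
                "fog_with": by_cond["with"].n_fog,
                "fog_prob_without": res.r1,
                "fog_prob_with": res.r2,
                "reduction_pct": res.reduction_pct,
                "z": res.z,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
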