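"""Genetic sex estimation from the chrY / (chrX + chrY) read ratio (Ry).

Ry is the fraction of sex-chromosome-mapped non-redundant reads that map to
the Y chromosome.  Females carry no Y, so their Ry is near zero (residual
misalignment only); males show a markedly higher ratio whose exact value
depends on relative X/Y mappability of the read set.  Confident calls
require the 95% confidence interval to clear published threshold zones;
low counts give wide intervals and an unresolved or indeterminate call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Ry below this (upper CI bound) is a confident female call.
FEMALE_MAX = 0.016
#: Ry above this (lower CI bound) is a confident male call.
MALE_MIN = 0.075


@dataclass
class SexEstimate:
    individual: str
    n_y: int
    n_xy: int
    ry: float | None
    ci95: tuple[float, float] | None
    call: str = "indeterminate"


def compute_ry(n_y: int, n_xy: int, individual: str = "",
               exact: bool = False) -> SexEstimate:
    """Ry = nY / nXY with a 95% confidence interval.

    Default interval is the normal approximation Ry +/- 1.96*sqrt(Ry(1-Ry)/n),
    clipped to [0, 1]; ``exact=True`` uses the Clopper-Pearson binomial
    interval instead.  nXY = 0 yields an indeterminate estimate with no ratio.
    """
    if n_xy == 0:
        return SexEstimate(individual, n_y, 0, None, None, "indeterminate")
    if not 0 <= n_y <= n_xy:
        raise ValueError("need 0 <= nY <= nXY")
    ry = n_y / n_xy
    if exact:
        lo = stats.beta.ppf(0.025, n_y, n_xy - n_y + 1) if n_y > 0 else 0.0
        hi = stats.beta.ppf(0.975, n_y + 1, n_xy - n_y) if n_y < n_xy else 1.0
    else:
        half = 1.96 * np.sqrt(ry * (1.0 - ry) / n_xy)
        lo, hi = ry - half, ry + half
    ci = (max(0.0, float(lo)), min(1.0, float(hi)))
    return SexEstimate(individual, n_y, n_xy, ry, ci)


def assign_sex(est: SexEstimate, female_max: float = FEMALE_MAX,
               male_min: float = MALE_MIN) -> SexEstimate:
    """Attach a sex call to an Ry estimate.

    female  if the whole CI sits below the female threshold;
    male    if the whole CI sits above the male threshold;
    consistent-male-unresolved  if the point estimate is in the male zone
            but the CI still overlaps the female zone (assignment of male
            likely, female not rejected);
    indeterminate otherwise.
    """
    if est.ry is None:
        est.call = "indeterminate"
        return est
    lo, hi = est.ci95
    if hi < female_max:
        est.call = "female"
    elif lo > male_min:
        est.call = "male"
    elif est.ry > male_min and lo < female_max:
        est.call = "consistent-male-unresolved"
    else:
        est.call = "indeterminate"
    return est


def estimate_sexes(counts: pd.DataFrame, female_max: float = FEMALE_MAX,
                   male_min: float = MALE_MIN, exact: bool = False) -> pd.DataFrame:
    """Run Ry estimation + calling over a count table.

    ``counts`` needs columns individual, n_y, n_xy.  Returns a frame with
    ry, ci bounds and the call per individual.
    """
    rows = []
    for row in counts.itertuples():
        est = assign_sex(compute_ry(int(row.n_y), int(row.n_xy), row.individual,
                                    exact=exact),
                         female_max=female_max, male_min=male_min)
        rows.append({
            "individual": est.individual, "n_y": est.n_y, "n_xy": est.n_xy,
            "ry": est.ry,
            "ci_low": est.ci95[0] if est.ci95 else None,
            "ci_high": est.ci95[1] if est.ci95 else None,
            "call": est.call,
        })
    return pd.DataFrame(rows)


def concordance(genetic: pd.DataFrame, osteology: pd.DataFrame
                ) -> tuple[float, pd.DataFrame]:
    """Concordance between confident genetic calls and an osteological table.

    Only individuals with a confident genetic call (female/male) on both
    sides enter the denominator; unresolved and indeterminate genetic calls
    are excluded.  Returns (fraction concordant, discrepancy table).
    """
    merged = genetic.merge(osteology, on="individual", suffixes=("_gen", "_ost"))
    confident = merged[merged["call"].isin(["female", "male"])]
    if confident.empty:
        return float("nan"), confident
    agree = confident["call"] == confident["sex"]
    discrepancies = confident.loc[~agree, ["individual", "call", "sex"]]
    return float(agree.mean()), discrepancies.reset_index(drop=True)
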