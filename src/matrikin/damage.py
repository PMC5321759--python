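"""Post-mortem deamination profiling, overhang masking, PMD scoring, dedup.

Ancient DNA fragments carry single-stranded overhangs in which cytosines
deaminate to uracil, sequenced as C->T at 5' ends (and, after
complementing into reference orientation, G->A at 3' ends).  Overhang
lengths follow a geometric distribution with per-base termination
probability lambda; the terminal misincorporation rate at position i from
the read end therefore decays as d0 * (1 - lambda)^(i-1).

This module estimates that profile from an aligned read stack, fits
(lambda, d0, baseline), derives the mask width covering 95% of overhangs,
hard-masks candidate damage residues, scores reads for post-mortem damage
(PMD) with a likelihood ratio, and removes coordinate duplicates.

Read stacks are pandas DataFrames in the layout produced by
:mod:`matrikin.synthetic_data` (sequences stored in reference orientation,
so both strands present C->T at the left end and G->A at the right end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class DamageFitError(RuntimeError):
    """Damage-curve fit failed or is unidentifiable."""


@dataclass
class DamageProfile:
    """Positional terminal misincorporation rates and the fitted decay.

    c_to_t / g_to_a are rates per position 1..K from the 5' / 3' read end;
    NaN marks positions with no opportunities.  lam, d0 and baseline are
    populated by :func:`fit_lambda`.
    """

    c_to_t: np.ndarray
    g_to_a: np.ndarray
    c_opportunities: np.ndarray = field(default=None)  # type: ignore[assignment]
    g_opportunities: np.ndarray = field(default=None)  # type: ignore[assignment]
    lam: float | None = None
    d0: float | None = None
    baseline: float = 0.0
    flat: bool = False           # set if the profile carries no damage signal
    residual_norm: float | None = None

    def rate(self, i: int) -> float:
        """Fitted damage probability at position i (1-based) from the 5' end."""
        if self.lam is None:
            raise DamageFitError("profile has not been fitted")
        if self.flat or self.d0 is None:
            return self.baseline
        return self.baseline + self.d0 * (1.0 - self.lam) ** (i - 1)

    def to_text(self) -> str:
        lines = [f"lambda\t{self.lam}", f"d0\t{self.d0}",
                 f"baseline\t{self.baseline}", f"flat\t{self.flat}"]
        for i, (ct, ga) in enumerate(zip(self.c_to_t, self.g_to_a), 1):
            lines.append(f"pos\t{i}\t{ct}\t{ga}")
        return "\n".join(lines) + "\n"


def terminal_profile(reads: pd.DataFrame, reference: str, k: int = 25) -> DamageProfile:
    """Raw terminal misincorporation rates from an aligned read stack.

    Position i from the 5' (left) end counts reads whose reference base is C
    and observed base is T; mirrored G->A from the 3' (right) end.  Because
    reads are stored in reference orientation the two strands contribute
    identically (reverse-strand 5' C->T complements to left-end C->T).
    Positions with zero opportunities are NaN and excluded from fitting.
    """
    ct_mm = np.zeros(k)
    ct_opp = np.zeros(k)
    ga_mm = np.zeros(k)
    ga_opp = np.zeros(k)
    ref = reference
    for start, seq in zip(reads["start"].to_numpy(), reads["seq"].to_numpy()):
        n = len(seq)
        kk = min(k, n)
        for i in range(kk):  # 5' side
            r = ref[start - 1 + i]
            if r == "C":
                ct_opp[i] += 1
                if seq[i] == "T":
                    ct_mm[i] += 1
        for i in range(kk):  # 3' side
            r = ref[start - 1 + n - 1 - i]
            if r == "G":
                ga_opp[i] += 1
                if seq[n - 1 - i] == "A":
                    ga_mm[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(ct_opp > 0, ct_mm / np.maximum(ct_opp, 1), np.nan)
        ga = np.where(ga_opp > 0, ga_mm / np.maximum(ga_opp, 1), np.nan)
    return DamageProfile(c_to_t=ct, g_to_a=ga,
                         c_opportunities=ct_opp, g_opportunities=ga_opp)


def fit_lambda(profile: DamageProfile, min_positions: int = 5,
               flat_threshold: float = 0.005) -> DamageProfile:
    """Fit rate(i) = baseline + d0 * (1 - lam)^(i-1) to the 5' C->T rates.

    Nonlinear least squares over informative (non-NaN) positions; the 3'
    G->A profile is left as a consistency check.  A profile whose fitted
    amplitude d0 falls below ``flat_threshold`` carries no damage signal:
    lambda is unidentifiable and the profile is flagged ``flat``.
    Returns the profile with lam / d0 / baseline filled in.
    """
    y = profile.c_to_t
    idx = np.flatnonzero(~np.isnan(y))
    if len(idx) < min_positions:
        raise DamageFitError(
            f"only {len(idx)} informative positions; need >= {min_positions}")
    x = idx + 1.0  # 1-based position
    yy = y[idx]

    def model(i, baseline, d0, lam):
        return baseline + d0 * (1.0 - lam) ** (i - 1.0)

    amp0 = max(float(yy[0] - yy[-1]), 1e-3)
    try:
        popt, _ = curve_fit(
            model, x, yy,
            p0=[max(float(yy[-1]), 1e-4), amp0, 0.3],
            bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, 1.0]),
            ftol=1e-15, xtol=1e-15, gtol=1e-15, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise DamageFitError(f"damage fit did not converge: {exc}") from exc
    baseline, d0, lam = map(float, popt)
    resid = float(np.linalg.norm(model(x, *popt) - yy))
    flat = d0 < flat_threshold
    profile.baseline = baseline
    profile.d0 = d0
    profile.lam = None if flat else lam
    profile.flat = flat
    profile.residual_norm = resid
    return profile


def mask_width_95(lam: float, quantile: float = 0.95) -> int:
    """Minimal k with cumulative Geometric(lam) mass 1-(1-lam)^k >= quantile.

    This is the overhang length encompassing 95% of inferred overhangs;
    terminal residues within it are candidates for hard-masking.
    """
    if not 0 < lam <= 1:
        raise ValueError("lambda must lie in (0, 1]")
    if lam == 1.0:
        return 1
    k = math.ceil(math.log(1.0 - quantile) / math.log(1.0 - lam))
    # guard against floating-point edge: ensure minimality and sufficiency
    while 1.0 - (1.0 - lam) ** k < quantile:
        k += 1
    while k > 1 and 1.0 - (1.0 - lam) ** (k - 1) >= quantile:
        k -= 1
    return k


def mask_terminal(reads: pd.DataFrame, k: int) -> pd.DataFrame:
    """Hard-mask candidate deamination residues at read ends.

    Every T among the first k bases (5' side) and every A among the last k
    bases (3' side) is replaced by N.  Reference-orientation storage makes
    this rule orientation-correct for both strands.  Returns a new frame;
    masking is idempotent.
    """
    if k < 1:
        raise ValueError("mask width must be >= 1")

    def mask_one(seq: str) -> str:
        n = len(seq)
        kk = min(k, n)
        left = seq[:kk].replace("T", "N")
        right = seq[n - kk:].replace("A", "N")
        if 2 * kk >= n:  # overlapping windows on short reads
            merged = []
            for i in range(n):
                c = seq[i]
                if i < kk and c == "T":
                    c = "N"
                if i >= n - kk and c == "A":
                    c = "N"
                merged.append(c)
            return "".join(merged)
        mid = seq[kk:n - kk]
        return left + mid + right

    out = reads.copy()
    out["seq"] = [mask_one(s) for s in out["seq"]]
    return out


def pmd_score(seq: str, start: int, reference: str, profile: DamageProfile,
              baseq: float = 30.0) -> float:
    """Per-read log-likelihood ratio of the damage model against a null.

    Sums over positions whose reference base is C (scored from the 5' end)
    or G (scored from the 3' end).  Under the damage model a reference C at
    position i is observed as T with probability D(i) + (1 - D(i)) * eps,
    where D(i) = d0 * (1 - lam)^(i-1) and eps is the error probability
    implied by the base quality; under the null only eps.  Matching bases
    contribute negatively.  A read with no informative positions scores 0.
    """
    if profile.lam is None and not profile.flat:
        raise DamageFitError("profile has not been fitted")
    eps = 10.0 ** (-baseq / 10.0)
    score = 0.0
    n = len(seq)
    for i in range(n):
        r = reference[start - 1 + i]
        b = seq[i]
        if b == "N":
            continue
        if r == "C":
            d = profile.rate(i + 1) if not profile.flat else profile.baseline
            p_dam_t = d + (1.0 - d) * eps
            if b == "T":
                score += math.log(p_dam_t / eps)
            elif b == "C":
                score += math.log((1.0 - p_dam_t) / (1.0 - eps))
        elif r == "G":
            j = n - i  # position from the 3' end, 1-based
            d = profile.rate(j) if not profile.flat else profile.baseline
            p_dam_a = d + (1.0 - d) * eps
            if b == "A":
                score += math.log(p_dam_a / eps)
            elif b == "G":
                score += math.log((1.0 - p_dam_a) / (1.0 - eps))
    return score


def pmd_filter(reads: pd.DataFrame, reference: str, profile: DamageProfile,
               threshold: float = 3.0) -> pd.DataFrame:
    """Retain reads whose PMD score meets the threshold (default 3),
    isolating fragments with evidence of authentic post-mortem damage."""
    scores = np.array([
        pmd_score(row.seq, row.start, reference, profile, row.baseq)
        for row in reads.itertuples()
    ])
    out = reads.loc[scores >= threshold].reset_index(drop=True)
    return out


def dedup(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate-read clusters to one representative each.

    Clusters are identified by (start, end, orientation); the survivor is
    the read with the highest mean base quality, ties broken by first
    occurrence in input order.  Input order of survivors is preserved.
    """
    if reads.empty:
        return reads.copy()
    df = reads.reset_index(drop=True)
    # stable sort: within cluster, highest quality first, then input order
    order = df.sort_values("baseq", ascending=False, kind="stable")
    keep = order.drop_duplicates(subset=["start", "end", "strand"], keep="first")
    return df.loc[sorted(keep.index)].reset_index(drop=True)
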