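"""Pseudo-haploid pairwise relatedness with block-jackknife errors.

Low-coverage ancient samples rarely yield confident diploid genotypes, so
each individual is reduced to a haploid call set by sampling one random
read per covered site (pseudo-haploid sampling).  For a pair of
individuals, the mean mismatch rate x over sites covered in both carries
the kinship signal: two unrelated individuals mismatch at some rate 2b set
by panel heterozygosity, while two samplings of one genome mismatch at
half that (per-site heterozygote sampling), giving the affine estimator

    r_hat = 2 - x / b,      b = (max unrelated mismatch) / 2 = 0.105

with r_hat(2b) = 0 (unrelated) and r_hat(b) = 1 (identical genomes).
Standard errors come from a weighted block jackknife over contiguous
genomic blocks (default 5 Mb), which respects local LD correlation;
the 95% CI on r propagates as 1.96 * se_x / b and detection uses
Z = (baseline - x) / se_x with Z > 3 flagging related pairs.

CpG-context SNPs are excluded throughout, because post-mortem deamination
rates differ among individuals most strongly at CpG sites and would
inflate mismatch asymmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

DEFAULT_B = 0.105           # half the ~21% maximum unrelated mismatch
DEFAULT_BLOCK_SIZE = 5_000_000
Z_THRESHOLD = 3.0
CANONICAL_R = {"identical": 1.0, "first": 0.5, "second": 0.25, "unrelated": 0.0}


class RelatednessError(ValueError):
    pass


@dataclass
class KinPairEstimate:
    pair: tuple[str, str]
    n_sites: int
    x: float
    se_x: float
    b: float
    r: float
    ci95_r: tuple[float, float]
    z: float
    degree: str


def exclude_cpg(table: pd.DataFrame) -> pd.DataFrame:
    """Keep autosomal (chromosomes 1-22), non-CpG-context observations."""
    chrom = pd.to_numeric(table["chrom"], errors="coerce")
    keep = (~table["cpg"].astype(bool)) & chrom.between(1, 22)
    return table.loc[keep].reset_index(drop=True)


def pseudo_haploidize(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """One uniformly random read per (individual, chrom, pos).

    Returns a call-set frame with columns individual, chrom, pos, base —
    at most one row per covered site, every base drawn from an observed
    read.  Reproducible under ``seed``.
    """
    if table.empty:
        return table.loc[:, ["individual", "chrom", "pos", "base"]].copy()
    rng = np.random.default_rng(seed)
    key = rng.random(len(table))
    shuffled = table.assign(_key=key).sort_values("_key", kind="stable")
    calls = shuffled.drop_duplicates(subset=["individual", "chrom", "pos"])
    return (calls.sort_values(["individual", "chrom", "pos"])
            .loc[:, ["individual", "chrom", "pos", "base"]]
            .reset_index(drop=True))


def pairwise_mismatch(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                      block_size: int = DEFAULT_BLOCK_SIZE
                      ) -> tuple[float, int, pd.DataFrame]:
    """Mean mismatch rate over the site intersection of two call sets.

    Sites covered in only one individual never enter; any base difference
    (including triallelic observations) counts as a mismatch.  Also returns
    per-block mismatch means and site counts on contiguous ``block_size``
    windows per chromosome, for the jackknife.
    """
    merged = calls_a.merge(calls_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    n = len(merged)
    if n == 0:
        raise RelatednessError("no overlapping sites between the two call sets")
    mism = (merged["base_a"] != merged["base_b"]).to_numpy()
    block = merged["chrom"].astype(int) * 10_000 + merged["pos"] // block_size
    blocks = (pd.DataFrame({"block": block, "mismatch": mism})
              .groupby("block")["mismatch"].agg(["mean", "size"])
              .rename(columns={"mean": "x", "size": "n_sites"})
              .reset_index())
    return float(mism.mean()), n, blocks


def block_jackknife_se(block_means: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one-block jackknife standard error of a mean.

    Blocks are contiguous genomic windows, weighted by their site counts.
    Uses the weighted-jackknife variance of Busing et al. (1999): with g
    blocks, total weight n, h_j = n / w_j and delete-one estimates
    theta_{-j},

        theta_J = g*theta - sum_j (1 - w_j/n) * theta_{-j}
        var = (1/g) * sum_j (h_j*theta - (h_j-1)*theta_{-j} - theta_J)^2
                            / (h_j - 1)

    With equal weights this reduces to the ordinary delete-one jackknife.
    """
    m = np.asarray(block_means, dtype=float)
    w = np.asarray(weights, dtype=float)
    g = len(m)
    if g < 2:
        raise RelatednessError("need at least 2 non-empty blocks for the jackknife")
    if (w <= 0).any():
        raise RelatednessError("block weights must be positive")
    n = w.sum()
    theta = float((w * m).sum() / n)
    theta_del = (n * theta - w * m) / (n - w)
    h = n / w
    theta_j = g * theta - float(((1.0 - w / n) * theta_del).sum())
    pseudo = h * theta - (h - 1.0) * theta_del
    var = float(((pseudo - theta_j) ** 2 / (h - 1.0)).sum() / g)
    return np.sqrt(max(var, 0.0))


def expected_b(freqs: np.ndarray) -> float:
    """Expected mismatch between two single-read samplings of one
    individual, from panel allele frequencies: mean of p(1-p).

    Each pseudo-haploid draw of a Hardy-Weinberg individual reports the
    alternate allele with probability p, so two independent samplings of
    the same genome disagree with probability p(1-p) per site (half the
    unrelated-pair rate 2p(1-p)).  Useful when the panel spectrum is known,
    e.g. to calibrate synthetic runs; real analyses use the published
    constant or (max observed pairwise x)/2.
    """
    p = np.asarray(freqs, dtype=float)
    return float((p * (1.0 - p)).mean())


def estimate_r(x: float, se_x: float = 0.0, b: float = DEFAULT_B
               ) -> tuple[float, tuple[float, float]]:
    """r_hat = 2 - x/b with 95% CI propagated as 1.96*se_x/b (b fixed).

    The estimator is the unique affine function of x with r_hat(2b) = 0 and
    r_hat(b) = 1.  r_hat is not clipped: sampling noise can push it outside
    [0, 1] and clipping would bias downstream CI coverage.
    """
    if b <= 0:
        raise RelatednessError("b must be positive")
    r = 2.0 - x / b
    half = 1.96 * se_x / b
    return r, (r - half, r + half)


def detect_related(x: float, se_x: float, baseline: float | None = None,
                   b: float = DEFAULT_B) -> float:
    """Z = (baseline - x) / se_x; Z > 3 flags a pair as related.

    baseline defaults to the unrelated mismatch level 2b; a per-dataset
    maximum observed pairwise x may be supplied instead.
    """
    if baseline is None:
        baseline = 2.0 * b
    if se_x == 0:
        if x == baseline:
            return 0.0
        raise RelatednessError("se_x = 0 with x != baseline: Z undefined")
    return (baseline - x) / se_x


def classify_degree(r: float, ci95_r: tuple[float, float]) -> str:
    """Degree label from which canonical r values the CI contains.

    Canonical values: 1 (identical), 0.5 (first degree), 0.25 (second
    degree), 0 (unrelated).  Exactly one inside -> that label; two adjacent
    inside -> combined (e.g. first-or-second); otherwise ambiguous.
    """
    lo, hi = ci95_r
    order = ["identical", "first", "second", "unrelated"]
    inside = [name for name in order if lo <= CANONICAL_R[name] <= hi]
    if len(inside) == 1:
        return inside[0]
    if len(inside) == 2 and abs(order.index(inside[0]) - order.index(inside[1])) == 1:
        return f"{inside[0]}-or-{inside[1]}"
    return "ambiguous"


def kin_pair(calls_a: pd.DataFrame, calls_b: pd.DataFrame, pair: tuple[str, str],
             b: float = DEFAULT_B, baseline: float | None = None,
             block_size: int = DEFAULT_BLOCK_SIZE) -> KinPairEstimate:
    """Full per-pair estimate: mismatch, jackknife SE, r_hat, CI, Z, degree."""
    x, n, blocks = pairwise_mismatch(calls_a, calls_b, block_size=block_size)
    if len(blocks) >= 2:
        se = block_jackknife_se(blocks["x"].to_numpy(), blocks["n_sites"].to_numpy())
    else:
        se = float("nan")
    r, ci = estimate_r(x, se, b=b)
    z = detect_related(x, se, baseline=baseline, b=b) if se and np.isfinite(se) else float("nan")
    return KinPairEstimate(pair=pair, n_sites=n, x=x, se_x=se, b=b, r=r,
                           ci95_r=ci, z=z, degree=classify_degree(r, ci))


def kin_table(table: pd.DataFrame, seed: int = 0, b: float | None = DEFAULT_B,
              baseline: float | None = None,
              block_size: int = DEFAULT_BLOCK_SIZE) -> pd.DataFrame:
    """All-pairs relatedness from a SNP read table.

    Applies CpG/autosome filtering, pseudo-haploidizes once per individual,
    and estimates every pair.  ``b=None`` re-derives the correction constant
    from the data as (maximum observed pairwise mismatch) / 2, mirroring how
    the constant is anchored to the approximate maximum unrelated mismatch.
    Output: one row per pair with n_sites, x, se_x, b, r, ci, z and degree.
    """
    filtered = exclude_cpg(table)
    calls = pseudo_haploidize(filtered, seed=seed)
    by_ind = {ind: grp for ind, grp in calls.groupby("individual")}
    inds = sorted(by_ind)
    raw = {}
    for a, c in combinations(inds, 2):
        raw[(a, c)] = pairwise_mismatch(by_ind[a], by_ind[c], block_size=block_size)
    if b is None:
        b = max(x for x, _, _ in raw.values()) / 2.0
    rows = []
    for (a, c), (x, n, blocks) in raw.items():
        se = (block_jackknife_se(blocks["x"].to_numpy(), blocks["n_sites"].to_numpy())
              if len(blocks) >= 2 else float("nan"))
        r, ci = estimate_r(x, se, b=b)
        z = detect_related(x, se, baseline=baseline, b=b) if se and np.isfinite(se) else float("nan")
        rows.append({
            "id_a": a, "id_b": c, "n_sites": n, "x": x, "se_x": se, "b": b,
            "r": r, "ci_low": ci[0], "ci_high": ci[1], "z": z,
            "related": bool(np.isfinite(z) and z > Z_THRESHOLD),
            "degree": classify_degree(r, ci),
        })
    return pd.DataFrame(rows)
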