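"""Synthetic inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here: pedigrees
with known relatedness coefficients, diploid genotypes, low-coverage
single-read SNP observations, mitochondrial haplotype families (including
the haplogroup-B 9-bp deletion), damaged read stacks with geometric
single-strand overhangs, chromosome X/Y read counts, and radiocarbon
calibration curves with or without plateaus.

All generators are deterministic under a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# mitochondrial reference geometry
# ---------------------------------------------------------------------------

MT_LENGTH = 16_569
#: 1-based coordinates of the haplogroup-B diagnostic 9-bp deletion: one copy
#: of the tandem CCCCCTCTA repeat in the COII/tRNA-Lys intergenic region.
B_DELETION_START = 8_271
B_DELETION_END = 8_279
B_DELETION_MOTIF = "CCCCCTCTA"

SNP_READ_COLUMNS = [
    "individual", "chrom", "pos", "ref", "alt", "base",
    "read_start", "read_end", "strand", "baseq", "mapq", "cpg",
]

MT_READ_COLUMNS = ["read_id", "start", "end", "strand", "seq", "baseq", "mapq"]

_BASES = np.array(["A", "C", "G", "T"])


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown parent/individual)."""


# ---------------------------------------------------------------------------
# pedigrees and genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree as a list of individuals and (child, mother, father) links.

    Parents may be absent (``None``): such individuals are founders, assumed
    mutually unrelated and non-inbred.  Validation rejects cycles and links
    to unnamed individuals.
    """

    individuals: tuple[str, ...]
    parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "individuals", tuple(self.individuals))
        known = set(self.individuals)
        if len(known) != len(self.individuals):
            raise PedigreeError("duplicate individual identifiers")
        for child, (mo, fa) in self.parents.items():
            if child not in known:
                raise PedigreeError(f"parent link for unknown individual {child!r}")
            for p in (mo, fa):
                if p is not None and p not in known:
                    raise PedigreeError(f"unknown parent {p!r} of {child!r}")
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[str]:
        """Founders-first ordering; raises PedigreeError on a cycle."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(ind: str, stack: list[str]):
            if state.get(ind) == 1:
                return
            if state.get(ind) == 0:
                raise PedigreeError(f"cycle in pedigree through {ind!r}")
            state[ind] = 0
            for p in self.parents.get(ind, (None, None)):
                if p is not None:
                    visit(p, stack + [ind])
            state[ind] = 1
            order.append(ind)

        for ind in self.individuals:
            visit(ind, [])
        return order

    def founders(self) -> list[str]:
        return [i for i in self.individuals
                if self.parents.get(i, (None, None)) == (None, None)]


def true_relatedness(spec: PedigreeSpec, a: str, b: str) -> float:
    """Ground-truth relatedness coefficient r for a pair of individuals.

    Computed as twice the kinship coefficient from the standard recursive
    path-counting identities (founders unrelated, no inbreeding loops):
    r(self, self) = 1, parent-offspring 0.5, grandparent-grandchild 0.25,
    founder pairs 0.
    """
    known = set(spec.individuals)
    if a not in known or b not in known:
        missing = a if a not in known else b
        raise PedigreeError(f"unknown individual {missing!r}")

    depth_cache: dict[str, int] = {}

    def depth(i: str) -> int:
        if i not in depth_cache:
            ps = [p for p in spec.parents.get(i, (None, None)) if p is not None]
            depth_cache[i] = 0 if not ps else 1 + max(depth(p) for p in ps)
        return depth_cache[i]

    cache: dict[tuple[str, str], float] = {}

    def kinship(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key in cache:
            return cache[key]
        if x == y:
            val = 0.5  # non-inbred
        else:
            # recurse through the parents of the "younger" individual
            if depth(x) < depth(y):
                x, y = y, x
            mo, fa = spec.parents.get(x, (None, None))
            val = 0.0
            if mo is not None:
                val += 0.5 * kinship(mo, y)
            if fa is not None:
                val += 0.5 * kinship(fa, y)
        cache[key] = val
        return val

    return 1.0 if a == b else 2.0 * kinship(a, b)


@dataclass
class GenotypeTable:
    """Diploid genotypes (alt-allele dosage 0/1/2) on a shared SNP panel.

    ``sites`` carries chrom (1-22), 1-based pos, ref/alt alleles, the
    population alternate-allele frequency and a CpG-context flag;
    ``genotypes`` is individuals x sites.
    """

    sites: pd.DataFrame            # chrom, pos, ref, alt, freq, cpg
    genotypes: pd.DataFrame        # index = individuals, columns = site index

    def __post_init__(self):
        g = self.genotypes.to_numpy()
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2")
        f = self.sites["freq"].to_numpy()
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("allele frequencies must lie in (0, 1)")
        for _, chunk in self.sites.groupby("chrom"):
            if not chunk["pos"].is_monotonic_increasing or chunk["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")


@dataclass(frozen=True)
class SimReadParams:
    """Read-sampling parameters shared by the SNP and mt simulators.

    coverage      Poisson rate of reads per site (SNP) / mean fold coverage (mt)
    error         per-base sequencing error probability
    d0            terminal C->T deamination amplitude inside overhangs
    lam           per-base probability of terminating a single-strand
                  overhang; overhang lengths are Geometric(lam), support 1..
    seed          RNG seed
    """

    coverage: float = 0.5
    error: float = 0.001
    d0: float = 0.0
    lam: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for name in ("error", "d0"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.lam <= 1:
            raise ValueError("lam must lie in (0, 1]")


def simulate_pedigree(
    spec: PedigreeSpec,
    n_sites: int,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    cpg_fraction: float = 0.20,
    seed: int = 0,
    n_chrom: int = 22,
) -> GenotypeTable:
    """Drop genotypes down a pedigree by fair Mendelian transmission.

    Founders are drawn from Hardy-Weinberg proportions at each site;
    each non-founder receives one uniformly chosen allele from each named
    parent (an absent parent contributes a population allele).  Allele
    frequencies default to Uniform(0.05, 0.95) so that unrelated-pair
    mismatch stays well away from zero.  CpG flags mark a random fraction
    of sites (default 20%); sites are spread over ``n_chrom`` autosomes.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    order = spec._toposort()

    freq = rng.uniform(freq_low, freq_high, n_sites)
    chrom = np.sort(rng.integers(1, n_chrom + 1, n_sites))
    pos = np.empty(n_sites, dtype=np.int64)
    for c in np.unique(chrom):
        m = chrom == c
        # strictly increasing positions via cumulative gaps
        pos[m] = np.cumsum(rng.integers(100, 5000, int(m.sum())))
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    cpg = rng.random(n_sites) < cpg_fraction
    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
        "freq": freq, "cpg": cpg,
    })

    # maternal / paternal haplotypes per individual, 0 = ref, 1 = alt
    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def gamete(parent: str | None) -> np.ndarray:
        if parent is None:
            return (rng.random(n_sites) < freq).astype(np.int8)
        h_m, h_p = haplo[parent]
        pick = rng.random(n_sites) < 0.5
        return np.where(pick, h_m, h_p).astype(np.int8)

    for ind in order:
        mo, fa = spec.parents.get(ind, (None, None))
        haplo[ind] = (gamete(mo), gamete(fa))

    geno = pd.DataFrame(
        {ind: (haplo[ind][0] + haplo[ind][1]) for ind in spec.individuals}
    ).T
    geno.index.name = "individual"
    return GenotypeTable(sites=sites, genotypes=geno)


def sample_snp_reads(gt: GenotypeTable, p: SimReadParams) -> pd.DataFrame:
    """Sample per-site sequencing reads from diploid genotypes.

    Per individual and site the read count is Poisson(coverage).  Each read
    reports one uniformly chosen allele of the genotype, flipped to the other
    allele with the sequencing error rate.  Deamination damage (C->T on
    either allele, mirrored G->A) is applied only at CpG-flagged sites with
    probability ``d0`` — emulating the elevated post-mortem damage at CpG
    dinucleotides that motivates excluding them from kinship estimation.

    Returns the pipeline's tab-separated SNP read-table layout.
    """
    rng = np.random.default_rng(p.seed)
    sites = gt.sites
    n_sites = len(sites)
    rows = []
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    cpg = sites["cpg"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()

    for ind in gt.genotypes.index:
        g = gt.genotypes.loc[ind].to_numpy()
        counts = rng.poisson(p.coverage, n_sites)
        site_idx = np.repeat(np.arange(n_sites), counts)
        n_reads = len(site_idx)
        if n_reads == 0:
            continue
        # uniformly pick one of the two chromosomes: alt with prob g/2
        is_alt = rng.random(n_reads) < g[site_idx] / 2.0
        base = np.where(is_alt, alt[site_idx], ref[site_idx])
        # sequencing error: flip to the other allele
        flip = rng.random(n_reads) < p.error
        base = np.where(flip, np.where(is_alt, ref[site_idx], alt[site_idx]), base)
        # CpG-context deamination: C->T / G->A on the observed base
        if p.d0 > 0:
            dam = (rng.random(n_reads) < p.d0) & cpg[site_idx]
            base = np.where(dam & (base == "C"), "T", base)
            base = np.where(dam & (base == "G"), "A", base)
        offset = rng.integers(0, 50, n_reads)
        rows.append(pd.DataFrame({
            "individual": ind,
            "chrom": chrom[site_idx],
            "pos": pos[site_idx],
            "ref": ref[site_idx],
            "alt": alt[site_idx],
            "base": base,
            "read_start": pos[site_idx] - offset,
            "read_end": pos[site_idx] - offset + 59,
            "strand": np.where(rng.random(n_reads) < 0.5, "+", "-"),
            "baseq": rng.integers(30, 41, n_reads),
            "mapq": 37,
            "cpg": cpg[site_idx],
        }))
    if not rows:
        return pd.DataFrame(columns=SNP_READ_COLUMNS)
    return pd.concat(rows, ignore_index=True)[SNP_READ_COLUMNS]


# ---------------------------------------------------------------------------
# mitochondrial haplotype families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MtHaplotypeSpec:
    """A family of mitochondrial haplotypes descending from one founder.

    ``mutations`` maps lineage name -> list of (1-based position, base)
    substitutions relative to the founder; ``b_deletion`` flags lineages
    carrying the haplogroup-B deletion, which removes the 9-bp motif at
    reference positions 8,271-8,279.
    """

    founder: str
    mutations: dict[str, tuple[tuple[int, str], ...]] = field(default_factory=dict)
    b_deletion: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        L = len(self.founder)
        for lineage, muts in self.mutations.items():
            for pos, base in muts:
                if not 1 <= pos <= L:
                    raise ValueError(f"mutation position {pos} outside sequence in {lineage!r}")
                if base not in "ACGT":
                    raise ValueError(f"invalid substituted base {base!r}")

    def lineage_sequence(self, lineage: str) -> str:
        """Founder sequence with this lineage's substitutions (and, if
        flagged, the 9-bp deletion) applied; deletion shortens the sequence."""
        seq = list(self.founder)
        for pos, base in self.mutations.get(lineage, ()):
            seq[pos - 1] = base
        if self.b_deletion.get(lineage, False):
            motif = "".join(seq[B_DELETION_START - 1:B_DELETION_END])
            if motif != B_DELETION_MOTIF:
                raise ValueError(
                    f"founder lacks {B_DELETION_MOTIF} at "
                    f"{B_DELETION_START}-{B_DELETION_END}; found {motif}")
            del seq[B_DELETION_START - 1:B_DELETION_END]
        return "".join(seq)


def make_mt_founder(seed: int = 0, length: int = MT_LENGTH) -> str:
    """Random mitochondrial founder sequence carrying the tandem CCCCCTCTA
    repeat at positions 8,262-8,270 and 8,271-8,279, so that the
    haplogroup-B deletion removes one copy of a genuine tandem repeat."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, length)
    rep = list(B_DELETION_MOTIF * 2)
    seq[B_DELETION_START - 10:B_DELETION_START - 10 + 18] = rep
    return "".join(seq)


def simulate_mt_reads(
    truth: str,
    p: SimReadParams,
    n_reads: int | None = None,
    read_length_mean: float = 60.0,
    read_length_sd: float = 15.0,
    read_length_min: int = 15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a damaged single-strand-overhang read stack from a truth
    sequence.

    Reads are stored in reference orientation (as in SAM).  Each read draws
    independent 5' and 3' overhang lengths from Geometric(lam) (support
    1, 2, ...); within the 5' overhang every C is deaminated to T with
    probability ``d0``, and mirrored G->A within the 3' overhang.  Because
    deamination of the complementary strand presents identically after
    complementing into reference orientation, both strands show C->T at the
    left (5') end and G->A at the right (3') end of the stored sequence.
    Sequencing errors are uniform substitutions at rate ``error``.

    Start / end / strand are recorded so duplicate-removal can be exercised;
    n_reads defaults to coverage * len(truth) / mean read length.
    """
    rng = np.random.default_rng(p.seed if seed is None else seed)
    L = len(truth)
    if n_reads is None:
        n_reads = max(1, int(p.coverage * L / read_length_mean))
    lengths = np.clip(
        np.round(rng.normal(read_length_mean, read_length_sd, n_reads)).astype(int),
        read_length_min, L)
    starts = rng.integers(1, L - lengths + 2)  # 1-based, fits in sequence
    ends = starts + lengths - 1
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    truth_arr = np.frombuffer(truth.encode(), dtype="S1")

    seqs = []
    over5 = rng.geometric(p.lam, n_reads)
    over3 = rng.geometric(p.lam, n_reads)
    for i in range(n_reads):
        s = truth_arr[starts[i] - 1:ends[i]].astype("U1").copy()
        n = len(s)
        k5, k3 = min(over5[i], n), min(over3[i], n)
        if p.d0 > 0:
            left = s[:k5]
            hit = (left == "C") & (rng.random(k5) < p.d0)
            left[hit] = "T"
            s[:k5] = left
            right = s[n - k3:]
            hit = (right == "G") & (rng.random(k3) < p.d0)
            right[hit] = "A"
            s[n - k3:] = right
        if p.error > 0:
            err = rng.random(n) < p.error
            if err.any():
                shift = rng.integers(1, 4, int(err.sum()))
                base_idx = np.searchsorted(_BASES, s[err])
                s[err] = _BASES[(base_idx + shift) % 4]
        seqs.append("".join(s))

    return pd.DataFrame({
        "read_id": [f"r{i:06d}" for i in range(n_reads)],
        "start": starts,
        "end": ends,
        "strand": strands,
        "seq": seqs,
        "baseq": np.round(rng.uniform(28, 40, n_reads), 1),
        "mapq": rng.choice([25, 30, 37, 60], n_reads, p=[0.05, 0.15, 0.3, 0.5]),
    })[MT_READ_COLUMNS]


# ---------------------------------------------------------------------------
# X/Y read counts for genetic sexing
# ---------------------------------------------------------------------------

def simulate_xy_counts(
    sex: str,
    n_xy: int,
    male_ry: float = 0.09,
    seed: int = 0,
) -> tuple[int, int]:
    """Simulated (nY, nXY) chromosome-mapped read counts for one individual.

    Under capture "bleed-through" with roughly equal X/Y mappability a male
    yields a Y fraction near ``male_ry`` (default 0.09); a female yields
    (almost) no Y reads.  Returns (nY, nXY).
    """
    rng = np.random.default_rng(seed)
    p_y = male_ry if sex == "male" else 0.001  # trace misalignment in females
    return int(rng.binomial(n_xy, p_y)), int(n_xy)


# ---------------------------------------------------------------------------
# calibration curves
# ---------------------------------------------------------------------------

def make_cal_curve(
    kind: str = "linear",
    cal_bp_min: int = 600,
    cal_bp_max: int = 1400,
    step: int = 5,
    intercept: float = 100.0,
    slope: float = 1.0,
    sigma: float = 10.0,
    plateau_center_ce: float = 1000.0,
    plateau_width: float = 150.0,
    path: str | None = None,
):
    """Build a synthetic radiocarbon calibration curve.

    linear   mu(cal BP) = intercept + slope * cal BP with constant 1-sigma —
             a strictly monotone stand-in for the atmospheric curve.
    plateau  the linear curve with a flat segment of ``plateau_width``
             calendar years centred on ``plateau_center_ce`` (emulating the
             reversal/plateau structure of the real curve between 900 and
             1150 CE).
    from_file  read an IntCal-layout CSV from ``path``.
    """
    from .chronology import CalCurve, read_curve  # local import: avoid cycle

    if kind == "from_file":
        if path is None:
            raise ValueError("from_file requires a path")
        return read_curve(path)
    cal_bp = np.arange(cal_bp_min, cal_bp_max + 1, step, dtype=float)
    mu = intercept + slope * cal_bp
    if kind == "plateau":
        center_bp = 1950.0 - plateau_center_ce
        lo, hi = center_bp - plateau_width / 2, center_bp + plateau_width / 2
        flat = mu[np.searchsorted(cal_bp, lo)]
        inside = (cal_bp >= lo) & (cal_bp <= hi)
        mu = np.where(inside, flat, mu)
        # keep the curve continuous: shift the upper limb down to meet the flat
        above = cal_bp > hi
        mu[above] = flat + slope * (cal_bp[above] - hi)
    elif kind != "linear":
        raise ValueError(f"unknown curve kind {kind!r}")
    return CalCurve(cal_bp=cal_bp, c14_bp=mu, sigma=np.full_like(cal_bp, float(sigma)),
                    kind="atmospheric")


# ---------------------------------------------------------------------------
# plain-text writers (pipeline exchange formats)
# ---------------------------------------------------------------------------

def write_snp_reads(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_snp_reads(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mt_reads(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_mt_reads(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pedigree(spec: PedigreeSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tmother\tfather\n")
        for ind in spec.individuals:
            mo, fa = spec.parents.get(ind, (None, None))
            fh.write(f"{ind}\t{mo or '.'}\t{fa or '.'}\n")


def read_pedigree(path) -> PedigreeSpec:
    df = pd.read_csv(path, sep="\t", dtype=str)
    parents = {}
    for _, row in df.iterrows():
        mo = None if row["mother"] == "." else row["mother"]
        fa = None if row["father"] == "." else row["father"]
        if mo is not None or fa is not None:
            parents[row["individual"]] = (mo, fa)
    return PedigreeSpec(individuals=tuple(df["individual"]), parents=parents)
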