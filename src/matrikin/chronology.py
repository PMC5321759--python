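"""Radiocarbon calibration, phase modelling and plateau-bias simulation.

A conventional radiocarbon age y +/- sigma is calibrated against a curve
(mu(t), sigma_curve(t)) giving, on a 1-calendar-year grid,

    p(t) proportional to exp(-(y - mu(t))^2 / (2 (sigma^2 + sigma_curve(t)^2)))

normalized over the grid; highest-posterior-density (HPD) regions at 68.2%
and 95.4% are extracted by descending-density accumulation.  Marine samples
receive a local reservoir offset Delta-R added to mu in quadrature on sigma.

Stratigraphic phase models place dated events inside ordered intervals
delimited by boundary parameters (B0 <= phase-1 events <= B1 <= ...).
Events and boundaries are sampled by Gibbs steps: an event's conditional is
its calibration density truncated to its phase interval (drawn exactly by
inverse CDF on the grid) and a boundary's conditional is uniform between
its neighbouring constraints.

The plateau-bias study simulates dates at known calendar ages through the
curve (draw y ~ N(mu(t_true), sqrt(sigma_meas^2 + sigma_curve^2)), then
recalibrate), and histograms the conventional ages to show how curve
plateaus stack simulated ages into apparent episodes even under perfectly
continuous deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HPD_LEVELS = (0.682, 0.954)


class CurveError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


def ce_to_bp(ce: float) -> float:
    """Calendar CE year to cal BP (before 1950)."""
    return 1950.0 - ce


def bp_to_ce(bp: float) -> float:
    return 1950.0 - bp


@dataclass
class CalCurve:
    """Calibration curve on a strictly monotone cal BP grid."""

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    sigma: np.ndarray
    kind: str = "atmospheric"

    def __post_init__(self):
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_bp = np.asarray(self.c14_bp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = np.diff(self.cal_bp)
        if len(self.cal_bp) < 2 or not ((d > 0).all() or (d < 0).all()):
            raise CurveError("calendar grid must be strictly monotone")
        if (self.sigma <= 0).any():
            raise CurveError("curve 1-sigma must be positive")
        if self.cal_bp[0] > self.cal_bp[-1]:  # store ascending
            self.cal_bp = self.cal_bp[::-1].copy()
            self.c14_bp = self.c14_bp[::-1].copy()
            self.sigma = self.sigma[::-1].copy()

    def mu(self, cal_bp):
        return np.interp(cal_bp, self.cal_bp, self.c14_bp)

    def sig(self, cal_bp):
        return np.interp(cal_bp, self.cal_bp, self.sigma)

    @property
    def span_bp(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])


def read_curve(path, kind: str = "atmospheric") -> CalCurve:
    """Read an IntCal-layout CSV: columns cal BP, 14C age BP, 1-sigma
    (header optional, comment lines starting with '#' ignored)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise CurveError("curve file needs 3 columns: cal BP, 14C age BP, 1 sigma")
    # tolerate a header-less file read with numeric first row
    try:
        df = df.iloc[:, :3].astype(float)
    except ValueError as exc:
        raise CurveError(f"non-numeric curve data: {exc}") from exc
    return CalCurve(cal_bp=df.iloc[:, 0].to_numpy(),
                    c14_bp=df.iloc[:, 1].to_numpy(),
                    sigma=df.iloc[:, 2].to_numpy(), kind=kind)


def write_curve(curve: CalCurve, path) -> None:
    pd.DataFrame({
        "cal_bp": curve.cal_bp, "c14_bp": curve.c14_bp, "sigma": curve.sigma,
    }).to_csv(path, index=False)


def apply_reservoir(curve: CalCurve, delta_r: float, sigma_delta_r: float,
                    warn=None) -> CalCurve:
    """Local marine reservoir correction: mu' = mu + Delta-R,
    sigma' = sqrt(sigma^2 + sigma_DR^2).  Intended for marine curves; on an
    atmospheric curve the correction is applied but reported via ``warn``."""
    if curve.kind != "marine" and warn is not None:
        warn("reservoir correction applied to a non-marine curve")
    return CalCurve(cal_bp=curve.cal_bp.copy(),
                    c14_bp=curve.c14_bp + delta_r,
                    sigma=np.sqrt(curve.sigma ** 2 + sigma_delta_r ** 2),
                    kind=curve.kind)


@dataclass(frozen=True)
class C14Date:
    """A conventional radiocarbon determination."""

    age_bp: float
    sigma: float
    curve: str = "atmospheric"
    delta_r: float = 0.0
    sigma_delta_r: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("measurement sigma must be positive")


@dataclass
class CalPosterior:
    """Posterior probability mass over a 1-yr calendar grid (cal BP)."""

    cal_bp: np.ndarray
    pmf: np.ndarray
    hpd: dict[float, list[tuple[float, float]]] = field(default_factory=dict)

    def mean_bp(self) -> float:
        return float((self.cal_bp * self.pmf).sum())

    def mean_ce(self) -> float:
        return bp_to_ce(self.mean_bp())

    def hpd_total_width(self, level: float) -> float:
        return sum(hi - lo + 1 for lo, hi in self.hpd[level])


def _hpd_intervals(cal_bp: np.ndarray, pmf: np.ndarray, level: float
                   ) -> list[tuple[float, float]]:
    """Smallest set of grid points reaching ``level`` mass, by descending
    density, merged into contiguous (lo, hi) cal BP intervals."""
    order = np.argsort(pmf)[::-1]
    cum = np.cumsum(pmf[order])
    n_in = int(np.searchsorted(cum, level) + 1)
    chosen = np.sort(order[:n_in])
    intervals = []
    start = prev = chosen[0]
    for idx in chosen[1:]:
        if idx == prev + 1:
            prev = idx
        else:
            intervals.append((float(cal_bp[start]), float(cal_bp[prev])))
            start = prev = idx
    intervals.append((float(cal_bp[start]), float(cal_bp[prev])))
    return intervals


def calibrate(date: C14Date, curve: CalCurve, step: float = 1.0,
              levels: tuple[float, ...] = HPD_LEVELS) -> CalPosterior:
    """Calibrate one date over the curve span on a ``step``-year grid."""
    if date.curve == "marine" or date.delta_r or date.sigma_delta_r:
        curve = apply_reservoir(curve, date.delta_r, date.sigma_delta_r)
    lo, hi = curve.span_bp
    grid = np.arange(lo, hi + step / 2, step)
    mu = curve.mu(grid)
    var = date.sigma ** 2 + curve.sig(grid) ** 2
    log_p = -((date.age_bp - mu) ** 2) / (2.0 * var) - 0.5 * np.log(var)
    log_p -= log_p.max()
    p = np.exp(log_p)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise CalibrationError("date lies off the calibration curve")
    mu_span = (curve.c14_bp.min() - 4 * date.sigma,
               curve.c14_bp.max() + 4 * date.sigma)
    if not mu_span[0] <= date.age_bp <= mu_span[1]:
        raise CalibrationError(
            f"age {date.age_bp} BP outside curve range {mu_span}")
    p /= total
    post = CalPosterior(cal_bp=grid, pmf=p)
    for level in sorted(levels):
        post.hpd[level] = _hpd_intervals(grid, p, level)
    return post


# ---------------------------------------------------------------------------
# Boundary / Phase stratigraphic model
# ---------------------------------------------------------------------------

@dataclass
class PhaseModel:
    """Ordered boundaries with phases of dated events between them.

    ``phases`` is a list of lists of event labels; phase k is constrained to
    [B_k, B_{k+1}] with len(phases)+1 boundaries in *chronological* order
    (earliest first, i.e. decreasing cal BP / increasing CE).
    ``dates`` maps event label -> C14Date.
    """

    phases: list[list[str]]
    dates: dict[str, C14Date]
    boundary_names: list[str] | None = None

    def __post_init__(self):
        labels = [e for ph in self.phases for e in ph]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate event labels across phases")
        missing = [e for e in labels if e not in self.dates]
        if missing:
            raise ValueError(f"no date for events {missing}")
        if self.boundary_names is None:
            self.boundary_names = [f"B{k}" for k in range(len(self.phases) + 1)]
        if len(self.boundary_names) != len(self.phases) + 1:
            raise ValueError("need len(phases)+1 boundary names")


def _truncated_grid_draw(rng, grid_ce, pmf, lo, hi):
    """Exact inverse-CDF draw from a grid pmf truncated to [lo, hi] CE."""
    mask = (grid_ce >= lo) & (grid_ce <= hi)
    if not mask.any():
        return None
    p = pmf[mask]
    tot = p.sum()
    if tot <= 0:
        # flat fallback inside the interval (numerical underflow region)
        return float(rng.uniform(lo, hi))
    p = p / tot
    return float(rng.choice(grid_ce[mask], p=p))


def sample_phase_model(model: PhaseModel, curves: dict[str, CalCurve],
                       n_iter: int = 20_000, burn_in: float = 0.5,
                       n_chains: int = 4, seed: int = 0,
                       step: float = 1.0) -> pd.DataFrame:
    """Gibbs sampler over event years and phase boundaries.

    Works in calendar CE.  Event conditionals are the single-date
    calibration densities truncated to the enclosing boundary interval
    (drawn exactly on the 1-yr grid); boundary conditionals are uniform
    between the neighbouring order constraints, with the outermost
    boundaries bounded by the curve span.  Returns post-burn-in samples of
    all boundaries and events with a ``chain`` column.

    Raises CalibrationError before sampling if the constraints are
    infeasible (some event has no support inside the curve span).
    """
    atm = curves.get("atmospheric") or next(iter(curves.values()))
    span_lo_ce = bp_to_ce(atm.span_bp[1])
    span_hi_ce = bp_to_ce(atm.span_bp[0])

    # precompute each event's calibration pmf on a common CE grid
    event_pmf: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ph in model.phases:
        for label in ph:
            date = model.dates[label]
            curve = curves.get(date.curve, atm)
            post = calibrate(date, curve, step=step)
            grid_ce = bp_to_ce(post.cal_bp)[::-1]
            pmf = post.pmf[::-1]
            if pmf.sum() <= 0:
                raise CalibrationError(f"event {label} has no support on the curve")
            event_pmf[label] = (grid_ce, pmf)

    n_phases = len(model.phases)
    cols = list(model.boundary_names) + [e for ph in model.phases for e in ph]
    keep_from = int(n_iter * burn_in)
    all_rows = []

    for chain in range(n_chains):
        rng = np.random.default_rng((seed + 1) * 1000 + chain)
        # initialize events at their calibration means, clipped into order
        ev: dict[str, float] = {}
        for ph in model.phases:
            for label in ph:
                g, p = event_pmf[label]
                ev[label] = float((g * p).sum())
        # enforce initial ordering by sorting phase means
        phase_means = []
        for k, ph in enumerate(model.phases):
            phase_means.append(np.mean([ev[e] for e in ph]) if ph else None)
        bounds = np.empty(n_phases + 1)
        bounds[0] = span_lo_ce
        bounds[-1] = span_hi_ce
        for k in range(1, n_phases):
            left = [ev[e] for e in model.phases[k - 1]]
            right = [ev[e] for e in model.phases[k]]
            lo = max(left) if left else bounds[k - 1]
            hi = min(right) if right else span_hi_ce
            bounds[k] = (lo + hi) / 2 if lo <= hi else lo
        # repair events violating the initial boundaries
        for k, ph in enumerate(model.phases):
            for e in ph:
                ev[e] = float(np.clip(ev[e], bounds[k], bounds[k + 1]))

        rows = []
        for it in range(n_iter):
            # events: exact truncated draws
            for k, ph in enumerate(model.phases):
                for label in ph:
                    g, p = event_pmf[label]
                    draw = _truncated_grid_draw(rng, g, p, bounds[k], bounds[k + 1])
                    if draw is not None:
                        ev[label] = draw
            # boundaries: uniform between neighbouring constraints
            for k in range(n_phases + 1):
                left_events = [ev[e] for e in model.phases[k - 1]] if k > 0 else []
                right_events = [ev[e] for e in model.phases[k]] if k < n_phases else []
                lo = max(left_events) if left_events else (bounds[k - 1] if k > 0 else span_lo_ce)
                lo = max(lo, bounds[k - 1] if k > 0 else span_lo_ce)
                hi = min(right_events) if right_events else (bounds[k + 1] if k < n_phases else span_hi_ce)
                hi = min(hi, bounds[k + 1] if k < n_phases else span_hi_ce)
                if hi < lo:
                    hi = lo
                bounds[k] = rng.uniform(lo, hi)
            if it >= keep_from:
                row = {name: bounds[k] for k, name in enumerate(model.boundary_names)}
                row.update(ev)
                row["chain"] = chain
                rows.append(row)
        all_rows.extend(rows)

    return pd.DataFrame(all_rows, columns=cols + ["chain"])


def gelman_rubin(samples: pd.DataFrame, column: str) -> float:
    """Potential scale reduction factor (R-hat) across the ``chain`` column."""
    chains = [grp[column].to_numpy() for _, grp in samples.groupby("chain")]
    m = len(chains)
    n = min(len(c) for c in chains)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains of >= 2 samples")
    arr = np.vstack([c[:n] for c in chains])
    means = arr.mean(axis=1)
    variances = arr.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w)) if w > 0 else 1.0


# ---------------------------------------------------------------------------
# plateau-bias simulation (R_Simulate design)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimDesign:
    """Design of the calibration-bias simulation: simulate ``dates_per_point``
    dates of precision ``sigma_meas`` every ``step`` calendar years from
    ``start_ce`` to ``end_ce`` inclusive; histogram conventional ages in
    ``bin_width`` 14C-yr bins."""

    start_ce: float = 750.0
    end_ce: float = 1250.0
    step: float = 25.0
    dates_per_point: int = 10
    sigma_meas: float = 20.0
    bin_width: float = 20.0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.dates_per_point < 1:
            raise ValueError("dates_per_point must be >= 1")

    @property
    def grid_ce(self) -> np.ndarray:
        return np.arange(self.start_ce, self.end_ce + self.step / 2, self.step)

    @property
    def n_dates(self) -> int:
        return len(self.grid_ce) * self.dates_per_point

    @property
    def expected_per_century(self) -> float:
        return self.dates_per_point * 100.0 / self.step


def r_simulate(t_true_ce: float, sigma_meas: float, curve: CalCurve,
               rng=None, seed: int | None = None
               ) -> tuple[float, CalPosterior]:
    """Simulate one radiocarbon determination at a known calendar age.

    Translates the calendar age through the curve — y ~ Normal(mu(t_true),
    sqrt(sigma_meas^2 + sigma_curve(t_true)^2)) — then calibrates the
    conventional age back.  Returns (conventional age BP, posterior).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bp = ce_to_bp(t_true_ce)
    lo, hi = curve.span_bp
    if not lo <= bp <= hi:
        raise CalibrationError(f"{t_true_ce} CE outside the curve span")
    sd = float(np.sqrt(sigma_meas ** 2 + curve.sig(bp) ** 2))
    y = float(rng.normal(curve.mu(bp), sd))
    post = calibrate(C14Date(age_bp=y, sigma=sigma_meas), curve)
    return y, post


def run_sim_design(design: SimDesign, curve: CalCurve, seed: int = 0,
                   keep_posteriors: bool = False) -> dict:
    """Run the full simulation design and histogram conventional ages.

    Returns a dict with the simulated conventional ages, the true calendar
    ages, the histogram (20-14C-yr bins by default), the total count, the
    expected per-century count, and per-bin z-scores against a uniform
    deposition rate (computed over interior bins, away from edge run-off).
    """
    rng = np.random.default_rng(seed)
    ages = []
    truths = []
    posteriors = []
    for t in design.grid_ce:
        for _ in range(design.dates_per_point):
            y, post = r_simulate(t, design.sigma_meas, curve, rng=rng)
            ages.append(y)
            truths.append(t)
            if keep_posteriors:
                posteriors.append(post)
    ages_arr = np.asarray(ages)
    bw = design.bin_width
    lo = np.floor(ages_arr.min() / bw) * bw
    hi = np.ceil(ages_arr.max() / bw) * bw
    edges = np.arange(lo, hi + bw / 2, bw)
    counts, _ = np.histogram(ages_arr, bins=edges)

    # uniform-deposition reference over interior bins (3 sigma from edges)
    mu_grid = curve.mu(ce_to_bp(design.grid_ce))
    sd_tot = np.sqrt(design.sigma_meas ** 2 + curve.sig(ce_to_bp(design.grid_ce)).max() ** 2)
    inner_lo, inner_hi = mu_grid.min() + 3 * sd_tot, mu_grid.max() - 3 * sd_tot
    interior = (edges[:-1] >= inner_lo) & (edges[1:] <= inner_hi)
    z = np.full(len(counts), np.nan)
    if interior.sum() >= 2:
        n_int = counts[interior].sum()
        k = int(interior.sum())
        e = n_int / k
        sd = np.sqrt(n_int * (1 / k) * (1 - 1 / k))
        z[interior] = (counts[interior] - e) / sd
    out = {
        "conventional_ages": ages_arr,
        "true_ce": np.asarray(truths),
        "bin_edges": edges,
        "counts": counts,
        "z_scores": z,
        "n_dates": len(ages_arr),
        "expected_per_century": design.expected_per_century,
    }
    if keep_posteriors:
        out["posteriors"] = posteriors
    return out
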