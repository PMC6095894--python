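"""Statistical core: filters, binned count-weighted regression, and the
decomposition of effective size control into timing (theta) and growth-rate
(gamma) modulation.

The central quantity is the homeostatic exponent ``lambda``: minus the slope
of replicative growth ``G = ln(V_mitosis / V_birth)`` against ``ln V_birth``.
``lambda = 1`` is a sizer, ``0.5`` an adder, ``0`` a timer (no control).
Timing and growth-rate modulation strengths obey the balance relation
``lambda = (theta + gamma) * <alpha> * <tau>``, with ``<alpha><tau>``
approximated by the mean replicative growth ``<G>`` when per-cell growth
rates are not measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedRegressionResult",
    "HomeostasisSummary",
    "FilterReport",
    "filter_3sd",
    "filter_iqr",
    "select_bin_params",
    "make_bins",
    "weighted_binned_fit",
    "homeostasis_regression",
    "estimate_lambda",
    "estimate_theta",
    "estimate_gamma_direct",
    "estimate_gamma_derived",
    "replicative_growth_mean",
    "mechanistic_adder_test",
    "sister_asymmetry",
    "steadiness_qc",
    "theta_gamma_plane",
    "summarize",
]


@dataclass
class BinnedRegressionResult:
    """Count-weighted linear fit on binned data."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    p_slope: float
    r2: float
    n_cells: int
    bins: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class FilterReport:
    rule: str
    n_in: int
    n_removed: int
    removed_ids: list = field(default_factory=list)


@dataclass
class HomeostasisSummary:
    """Per-dataset size-control decomposition."""

    name: str
    lam: float
    se_lam: float
    theta: float
    se_theta: float
    gamma: float
    se_gamma: float
    gamma_mode: str  # "direct" or "derived"
    mean_G: float
    se_mean_G: float
    mean_tau: float = np.nan
    mean_alpha: float = np.nan
    n: int = 0

    @property
    def norm(self) -> float:
        """<alpha><tau> when both are measured, else <G>."""
        if np.isfinite(self.mean_alpha) and np.isfinite(self.mean_tau):
            return self.mean_alpha * self.mean_tau
        return self.mean_G

    @property
    def norm_theta(self) -> float:
        return self.theta * self.norm

    @property
    def norm_gamma(self) -> float:
        return self.gamma * self.norm


# ---------------------------------------------------------------------------
# filters


def filter_3sd(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, FilterReport]:
    """Single-pass removal of rows outside mean +/- 3 s.d. in any column.

    Moments are computed on the input table; a zero-variance column removes
    nothing.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to filter")
    keep = np.ones(len(table), dtype=bool)
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        mu, sd = np.mean(x), np.std(x, ddof=1)
        if sd == 0:
            continue
        keep &= (x >= mu - 3 * sd) & (x <= mu + 3 * sd)
    removed = table.index[~keep].tolist()
    return table.loc[keep], FilterReport("three_sd", len(table), len(removed), removed)


def filter_iqr(
    table: pd.DataFrame,
    birth_col: str = "V_birth",
    mitosis_col: str = "V_mitosis",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove rows whose log birth or log mitotic volume leaves the band
    median +/- 1.5*IQR of the respective log-volume distribution."""
    keep = np.ones(len(table), dtype=bool)
    for col in (birth_col, mitosis_col):
        v = table[col].to_numpy(dtype=float)
        if np.any(v <= 0):
            raise ValueError(f"column {col!r} must be strictly positive")
        x = np.log(v)
        med = np.median(x)
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            warnings.warn(
                f"zero IQR in log {col}; only exact-median values retained",
                stacklevel=2,
            )
        keep &= (x >= med - 1.5 * iqr) & (x <= med + 1.5 * iqr)
    removed = table.index[~keep].tolist()
    return table.loc[keep], FilterReport("iqr", len(table), len(removed), removed)


# ---------------------------------------------------------------------------
# binning and the weighted fit


def select_bin_params(n: int, organism_class: str = "animal") -> tuple[int, int]:
    """Bin count and minimum events per bin, adapted to dataset size.

    Microbe datasets follow the published staircase; animal-cell datasets
    use (8, 4) for n >= 150 and (6, 4) below.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if organism_class == "microbe":
        if n < 100:
            return 8, 8
        if n < 1000:
            return 10, 15
        if n < 5000:
            return 13, 60
        return 15, 150
    if organism_class == "animal":
        return (8, 4) if n >= 150 else (6, 4)
    raise ValueError(f"unknown organism_class {organism_class!r}")


def make_bins(
    x: np.ndarray,
    y: np.ndarray,
    binn: int,
    minn: int,
    statistic: str = "median",
) -> pd.DataFrame:
    """Equal-width bins along x with a per-bin summary statistic of x and y.

    Bins with fewer than ``minn`` events are dropped; the rightmost edge is
    inclusive. Raises when fewer than 2 bins survive (regression impossible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < binn:
        raise ValueError("fewer observations than bins")
    stat = {"median": np.median, "mean": np.mean}[statistic]
    edges = np.linspace(x.min(), x.max(), binn + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, binn - 1)
    rows = []
    for b in range(binn):
        sel = idx == b
        cnt = int(sel.sum())
        if cnt < minn or cnt == 0:
            continue
        rows.append(
            {
                "x_stat": float(stat(x[sel])),
                "y_stat": float(stat(y[sel])),
                "count": cnt,
                "y_sd": float(np.std(y[sel], ddof=1)) if cnt > 1 else 0.0,
            }
        )
    if len(rows) < 2:
        raise ValueError(
            f"only {len(rows)} bin(s) retained (binn={binn}, minn={minn}); "
            "regression impossible"
        )
    return pd.DataFrame(rows)


def weighted_binned_fit(bins: pd.DataFrame, n_cells: int | None = None) -> BinnedRegressionResult:
    """Weighted least squares of bin y-statistic on bin x-statistic.

    Weights are the bin counts. The slope standard error and two-sided
    p-value use a t distribution with ``n_bins - 2`` degrees of freedom;
    R² is the weighted coefficient of determination on the bins. With
    exactly 2 bins the line is exact and se/p are reported missing.
    """
    xb = bins["x_stat"].to_numpy(dtype=float)
    yb = bins["y_stat"].to_numpy(dtype=float)
    w = bins["count"].to_numpy(dtype=float)
    nb = xb.size
    if nb < 2:
        raise ValueError("need at least 2 bins")
    if np.unique(xb).size < 2:
        raise ValueError("bin x positions are not distinct")
    W = w.sum()
    xm = np.sum(w * xb) / W
    ym = np.sum(w * yb) / W
    sxx = np.sum(w * (xb - xm) ** 2)
    if sxx == 0:
        raise ValueError("bin x positions are numerically coincident")
    sxy = np.sum(w * (xb - xm) * (yb - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = yb - (intercept + slope * xb)
    sse = np.sum(w * resid**2)
    sst = np.sum(w * (yb - ym) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if nb > 2:
        df = nb - 2
        s2 = sse / df
        se_slope = float(np.sqrt(s2 / sxx))
        se_intercept = float(np.sqrt(s2 * (1.0 / W + xm**2 / sxx)))
        if se_slope > 0:
            tval = slope / se_slope
            p = float(2 * stats.t.sf(abs(tval), df))
        else:
            p = 0.0
    else:
        se_slope = se_intercept = p = float("nan")
        r2 = 1.0
    n_cells = int(w.sum()) if n_cells is None else int(n_cells)
    return BinnedRegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=se_slope,
        se_intercept=se_intercept,
        p_slope=p,
        r2=float(np.clip(r2, 0.0, 1.0)),
        n_cells=n_cells,
        bins=bins,
    )


def homeostasis_regression(
    cells: pd.DataFrame,
    x: str,
    y: str,
    log_x: bool = False,
    bin_policy: tuple[int, int] | None = None,
    organism_class: str = "animal",
    statistic: str = "median",
) -> BinnedRegressionResult:
    """Generic driver: optional log-transform of x, binning, weighted fit."""
    sub = cells[[x, y]].dropna()
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if log_x:
        if np.any(xv <= 0):
            raise ValueError(f"cannot log-transform non-positive values in {x!r}")
        xv = np.log(xv)
    binn, minn = bin_policy if bin_policy is not None else select_bin_params(
        xv.size, organism_class
    )
    bins = make_bins(xv, yv, binn, minn, statistic=statistic)
    return weighted_binned_fit(bins, n_cells=xv.size)


# ---------------------------------------------------------------------------
# lambda / theta / gamma


def _require_G(cells: pd.DataFrame) -> pd.DataFrame:
    out = cells.copy()
    if "G" not in out.columns:
        out["G"] = np.log(out["V_mitosis"] / out["V_birth"])
    if "log_V_birth" not in out.columns:
        out["log_V_birth"] = np.log(out["V_birth"])
    return out


def estimate_lambda(
    cells: pd.DataFrame, **kwargs
) -> tuple[float, float, BinnedRegressionResult]:
    """Homeostatic exponent: minus the slope of G on ln V_birth."""
    if len(cells) < 30:
        raise ValueError("need at least 30 cells to estimate lambda")
    c = _require_G(cells)
    fit = homeostasis_regression(c, "log_V_birth", "G", **kwargs)
    return -fit.slope, fit.se_slope, fit


def estimate_theta(
    cells: pd.DataFrame, **kwargs
) -> tuple[float, float, BinnedRegressionResult]:
    """Timing-modulation strength: -slope(tau ~ ln V_birth) / <tau>.

    The standard error combines the slope error and the error on <tau>
    by first-order propagation.
    """
    c = _require_G(cells)
    fit = homeostasis_regression(c, "log_V_birth", "tau", **kwargs)
    tau = c["tau"].to_numpy(dtype=float)
    mean_tau = float(np.mean(tau))
    se_mean_tau = float(np.std(tau, ddof=1) / np.sqrt(tau.size))
    theta = -fit.slope / mean_tau
    se = float(
        np.hypot(fit.se_slope / mean_tau, fit.slope * se_mean_tau / mean_tau**2)
    )
    return theta, se, fit


def estimate_gamma_direct(
    cells: pd.DataFrame, **kwargs
) -> tuple[float, float, BinnedRegressionResult]:
    """Growth-rate-modulation strength: -slope(alpha ~ ln V_birth) / <alpha>.

    When no per-cell growth rate is present it is derived as G/tau (with a
    warning), which assumes exponential growth.
    """
    c = _require_G(cells)
    if "alpha" not in c.columns or c["alpha"].isna().all():
        warnings.warn(
            "no per-cell growth rate; deriving alpha = G/tau", stacklevel=2
        )
        c["alpha"] = c["G"] / c["tau"]
    fit = homeostasis_regression(c, "log_V_birth", "alpha", **kwargs)
    a = c["alpha"].to_numpy(dtype=float)
    mean_a = float(np.mean(a))
    se_mean_a = float(np.std(a, ddof=1) / np.sqrt(a.size))
    gamma = -fit.slope / mean_a
    se = float(np.hypot(fit.se_slope / mean_a, fit.slope * se_mean_a / mean_a**2))
    return gamma, se, fit


def estimate_gamma_derived(
    lam: float,
    theta: float,
    mean_G: float,
    se_lam: float = 0.0,
    se_theta: float = 0.0,
    se_mean_G: float = 0.0,
) -> tuple[float, float]:
    """Gamma from the balance relation: gamma = lambda / <G> - theta."""
    if not mean_G > 0:
        raise ValueError("mean replicative growth must be positive")
    gamma = lam / mean_G - theta
    se = float(
        np.sqrt(
            (se_lam / mean_G) ** 2
            + se_theta**2
            + (lam * se_mean_G / mean_G**2) ** 2
        )
    )
    return float(gamma), se


def replicative_growth_mean(cells: pd.DataFrame) -> tuple[float, float]:
    """Mean replicative growth <G> = <ln(V_mitosis/V_birth)> and its s.e."""
    c = _require_G(cells)
    g = c["G"].to_numpy(dtype=float)
    return float(np.mean(g)), float(np.std(g, ddof=1) / np.sqrt(g.size))


def mechanistic_adder_test(
    cells: pd.DataFrame, **kwargs
) -> BinnedRegressionResult:
    """Regression of added volume in S-G2 on added volume in G1.

    A slope of -1 is the signature of a single rate-limiting addition of
    volume from birth to mitosis (fixed total, random split over phases);
    independent phase-wise adders give a slope near 0. The result carries a
    ``distance_to_minus_one`` attribute.
    """
    c = cells.copy()
    c["dV_G1"] = c["V_G1S"] - c["V_birth"]
    c["dV_SG2"] = c["V_mitosis"] - c["V_G1S"]
    fit = homeostasis_regression(c, "dV_G1", "dV_SG2", **kwargs)
    fit.distance_to_minus_one = abs(fit.slope - (-1.0))
    return fit


@dataclass
class SisterAsymmetryResult:
    birth_ratios: np.ndarray
    mitosis_ratios: np.ndarray
    p_value: float
    mean_reldiff_birth: float
    mean_reldiff_mitosis: float
    n_pairs: int
    n_incomplete: int


def sister_asymmetry(cells: pd.DataFrame) -> SisterAsymmetryResult:
    """Volume asymmetry of sister pairs at birth and at the next mitosis.

    Per complete pair, the ratio larger/smaller (>= 1) is computed at birth
    and at mitotic entry, together with the relative difference
    ``|V1 - V2| / (V1 + V2)``. A one-sided paired Wilcoxon signed-rank test
    asks whether the mitosis ratio is smaller than the birth ratio (size
    correction within one cycle).
    """
    by_id = cells.set_index("cell_id")
    seen = set()
    rb, rm, db, dm = [], [], [], []
    n_incomplete = 0
    for cid, row in by_id.iterrows():
        sid = row.get("sister_id")
        if cid in seen or sid in seen:
            continue
        if sid not in by_id.index:
            n_incomplete += 1
            continue
        sis = by_id.loc[sid]
        seen.update((cid, sid))
        vb = np.array([row["V_birth"], sis["V_birth"]], dtype=float)
        vm = np.array([row["V_mitosis"], sis["V_mitosis"]], dtype=float)
        if not (np.all(np.isfinite(vb)) and np.all(np.isfinite(vm))):
            n_incomplete += 1
            continue
        rb.append(vb.max() / vb.min())
        rm.append(vm.max() / vm.min())
        db.append(abs(vb[0] - vb[1]) / vb.sum())
        dm.append(abs(vm[0] - vm[1]) / vm.sum())
    if len(rb) < 10:
        raise ValueError(f"need >= 10 complete sister pairs, got {len(rb)}")
    rb, rm = np.asarray(rb), np.asarray(rm)
    diffs = rm - rb
    if np.allclose(diffs, 0):
        p = float("nan")  # degenerate: perfectly symmetric divisions
    else:
        p = float(stats.wilcoxon(rm, rb, alternative="less").pvalue)
    return SisterAsymmetryResult(
        birth_ratios=rb,
        mitosis_ratios=rm,
        p_value=p,
        mean_reldiff_birth=float(np.mean(db)),
        mean_reldiff_mitosis=float(np.mean(dm)),
        n_pairs=len(rb),
        n_incomplete=n_incomplete,
    )


@dataclass
class SteadinessReport:
    drift_slope: float
    relative_drift: float
    drift_flag: bool
    replicate_tests: pd.DataFrame | None


def steadiness_qc(
    cells: pd.DataFrame,
    replicate_col: str | None = None,
    speed_col: str | None = None,
    drift_threshold: float = 0.10,
    **kwargs,
) -> SteadinessReport:
    """Check that birth volumes are stationary over the experiment.

    Fits V_birth against t_birth (binned, count-weighted) and flags the
    dataset when the fitted relative change of mean birth volume over the
    recorded span exceeds ``drift_threshold``. When a replicate label column
    is given, pairwise Welch t-tests compare mean growth speed (or mean
    birth volume) across replicates.
    """
    fit = homeostasis_regression(cells, "t_birth", "V_birth", **kwargs)
    span = cells["t_birth"].max() - cells["t_birth"].min()
    rel = fit.slope * span / cells["V_birth"].mean()
    tests = None
    if replicate_col is not None and cells[replicate_col].nunique() >= 2:
        col = speed_col if speed_col is not None else "V_birth"
        rows = []
        labels = sorted(cells[replicate_col].unique())
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                xa = cells.loc[cells[replicate_col] == a, col]
                xb = cells.loc[cells[replicate_col] == b, col]
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
                rows.append({"a": a, "b": b, "t": float(t), "p": float(p)})
        tests = pd.DataFrame(rows)
    return SteadinessReport(
        drift_slope=fit.slope,
        relative_drift=float(rel),
        drift_flag=bool(abs(rel) > drift_threshold),
        replicate_tests=tests,
    )


def theta_gamma_plane(summaries: list[HomeostasisSummary]) -> pd.DataFrame:
    """Normalized (gamma, theta) coordinates, one row per dataset.

    x = gamma*norm and y = theta*norm with norm = <alpha><tau> when growth
    rates are measured, else <G>; x + y equals lambda up to estimation error
    (carried as ``balance_residual``).
    """
    rows = []
    for s in summaries:
        rows.append(
            {
                "name": s.name,
                "x_gamma_norm": s.norm_gamma,
                "y_theta_norm": s.norm_theta,
                "lambda": s.lam,
                "balance_residual": s.norm_theta + s.norm_gamma - s.lam,
                "norm": s.norm,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def summarize(
    cells: pd.DataFrame,
    name: str = "dataset",
    gamma_mode: str = "auto",
    **kwargs,
) -> HomeostasisSummary:
    """Full lambda/theta/gamma decomposition of one lineage table.

    ``gamma_mode`` is "direct" (regress per-cell growth rate), "derived"
    (from the balance relation), or "auto" (direct when an alpha column is
    present).
    """
    lam, se_lam, _ = estimate_lambda(cells, **kwargs)
    mean_G, se_G = replicative_growth_mean(cells)
    has_tau = "tau" in cells.columns and cells["tau"].notna().any()
    if has_tau:
        theta, se_theta, _ = estimate_theta(cells, **kwargs)
        mean_tau = float(cells["tau"].mean())
    else:
        theta, se_theta, mean_tau = 0.0, 0.0, float("nan")
    has_alpha = "alpha" in cells.columns and cells["alpha"].notna().any()
    if gamma_mode == "auto":
        gamma_mode = "direct" if has_alpha else "derived"
    if gamma_mode == "direct":
        gamma, se_gamma, _ = estimate_gamma_direct(cells, **kwargs)
    else:
        gamma, se_gamma = estimate_gamma_derived(
            lam, theta, mean_G, se_lam, se_theta, se_G
        )
    mean_alpha = float(cells["alpha"].mean()) if has_alpha else float("nan")
    return HomeostasisSummary(
        name=name,
        lam=lam,
        se_lam=se_lam,
        theta=theta,
        se_theta=se_theta,
        gamma=gamma,
        se_gamma=se_gamma,
        gamma_mode=gamma_mode,
        mean_G=mean_G,
        se_mean_G=se_G,
        mean_tau=mean_tau,
        mean_alpha=mean_alpha,
        n=len(cells),
    )
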