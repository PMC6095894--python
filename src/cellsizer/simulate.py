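"""Stochastic simulation of growing and dividing cell lineages.

Cells grow exponentially at a per-cycle rate alpha for a per-cycle duration
tau, then split into two daughters. In the linear-response mode both alpha
and tau respond linearly to the deviation of log birth volume from its
reference, with additive Gaussian noise:

    alpha = <alpha> * (1 - gamma * delta) + N(0, sd_alpha^2)
    tau   = max(eps, <tau> * (1 - theta * delta) + N(0, sd_tau^2))
    V_mitosis = V_birth * exp(alpha * tau)

where ``delta = ln V_birth - mean_log_birth_volume``. Archetype modes
(sizer / adder / timer / mechanistic adder) replace this update with the
corresponding limit-case rule. A separate per-cell generator produces phase-
structured cycles (G1 with a minimum duration, S-G2 timer or adder) and
sampled volume trajectories with measurement noise, segmentation spikes and
a mitotic volume overshoot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cellsizer.trajectory import Trajectory

__all__ = [
    "ModelParams",
    "PhaseParams",
    "MechanisticMode",
    "MODES",
    "LINEAGE_COLUMNS",
    "simulate_lineages",
    "simulate_phases",
    "render_trajectory",
]

LINEAGE_COLUMNS = [
    "cell_id",
    "parent_id",
    "sister_id",
    "generation",
    "t_birth",
    "V_birth",
    "V_G1S",
    "V_mitosis",
    "tau_G1",
    "tau_SG2",
    "tau",
    "alpha",
]

MODES = ("linear_response", "sizer", "adder", "timer", "mechanistic_adder")

#: lower floor on cycle and phase durations (h), guards against Gaussian noise
DURATION_FLOOR = 0.1

#: default burn-in: generations discarded before analysis export
DEFAULT_BURN_IN = 5


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"parameter {name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Population-level simulator parameters.

    Volumes are in µm³ (log volumes natural-log), times in hours, growth
    rates in 1/h. ``theta`` and ``gamma`` are the linear-response strengths
    of cycle-duration and growth-rate modulation per unit log birth volume.
    """

    mean_log_birth_volume: float = math.log(1300.0)
    mean_growth_rate: float = 0.0462
    mean_cycle_duration: float = 15.0
    theta: float = 0.0
    gamma: float = 0.0
    sd_tau: float = 0.0
    sd_alpha: float = 0.0
    division_asymmetry_sd: float = 0.0
    measurement_noise_cv: float = 0.0
    stationary: bool = False
    founder_log_sd: float = 0.15
    division_bounds: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        for name in (
            "mean_log_birth_volume",
            "mean_growth_rate",
            "mean_cycle_duration",
            "theta",
            "gamma",
            "sd_tau",
            "sd_alpha",
            "division_asymmetry_sd",
            "measurement_noise_cv",
            "founder_log_sd",
        ):
            _check_finite(name, getattr(self, name))
        if self.mean_growth_rate <= 0:
            raise ValueError("mean_growth_rate must be > 0")
        if self.mean_cycle_duration <= 0:
            raise ValueError("mean_cycle_duration must be > 0")
        for name in ("sd_tau", "sd_alpha", "division_asymmetry_sd",
                     "measurement_noise_cv", "founder_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.division_asymmetry_sd >= 0.3:
            raise ValueError("division_asymmetry_sd must be < 0.3")
        if self.stationary:
            if abs(self.mean_growth_rate * self.mean_cycle_duration - math.log(2)) > 1e-9:
                raise ValueError(
                    "stationary populations require <alpha><tau> = ln 2"
                )

    @classmethod
    def stationary_defaults(cls, **overrides) -> "ModelParams":
        """Parameters with <alpha><tau> = ln 2 (population doubling)."""
        kw = dict(
            mean_growth_rate=math.log(2) / 15.0,
            mean_cycle_duration=15.0,
            stationary=True,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class PhaseParams:
    """G1 / S-G2 phase-structure parameters.

    G1 duration decreases linearly with log birth volume down to a hard
    minimum ``g1_min``; S-G2 is either a timer (fixed mean duration, h) or
    an adder (fixed mean added volume, µm³).
    """

    g1_slope: float = 0.0
    g1_mean: float = 8.0
    g1_min: float = 4.0
    g1_sd: float = 0.0
    sg2_mode: str = "timer"
    sg2_mean: float = 8.0
    sg2_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.g1_min < 0:
            raise ValueError("g1_min must be >= 0")
        if self.g1_mean < self.g1_min:
            raise ValueError("g1_mean must be >= g1_min")
        if self.sg2_mean <= 0:
            raise ValueError("sg2_mean must be > 0")
        if self.g1_sd < 0 or self.sg2_sd < 0:
            raise ValueError("noise s.d. must be >= 0")
        if self.sg2_mode not in ("timer", "adder"):
            raise ValueError(f"unknown sg2_mode {self.sg2_mode!r}")


@dataclass(frozen=True)
class MechanisticMode:
    """Division-rule archetype and its dispersion.

    ``mode_sd`` is the s.d. of the target mitotic volume (sizer), of the
    added volume (adder / mechanistic adder), or of the cycle duration
    (timer), in mode units. ``target`` overrides the default target volume /
    added volume; when None, the sizer targets twice the mean birth volume
    and the adders add one mean birth volume. ``split_range`` is the uniform
    range of the G1 fraction of the total addition (mechanistic adder).
    """

    mode: str = "linear_response"
    mode_sd: float = 0.0
    target: float | None = None
    split_range: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode_sd < 0:
            raise ValueError("mode_sd must be >= 0")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    """Truncated normal draws by resampling (sd is small w.r.t. the band)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def _apply_measurement_noise(
    df: pd.DataFrame, cv: float, rng: np.random.Generator
) -> pd.DataFrame:
    if cv <= 0:
        return df
    sigma = math.sqrt(math.log1p(cv**2))
    for col in ("V_birth", "V_G1S", "V_mitosis"):
        vals = df[col].to_numpy()
        noise = rng.lognormal(-sigma**2 / 2, sigma, vals.size)
        df[col] = np.where(np.isfinite(vals), vals * noise, vals)
    return df


def _cycle_update(
    params: ModelParams,
    mode: MechanisticMode,
    Vb: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One cell-cycle update for a cohort of birth volumes.

    Returns per-cell alpha, tau (and phase splits where defined), V_G1S,
    V_mitosis and a boolean mask of cells to discard (non-physical draws).
    """
    n = Vb.size
    mean_V = math.exp(params.mean_log_birth_volume)
    delta = np.log(Vb) - params.mean_log_birth_volume
    nan = np.full(n, np.nan)
    out = {"V_G1S": nan.copy(), "tau_G1": nan.copy(), "tau_SG2": nan.copy()}

    def noise(sd: float) -> np.ndarray:
        return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    if mode.mode == "linear_response":
        alpha = params.mean_growth_rate * (1 - params.gamma * delta) + noise(
            params.sd_alpha
        )
        tau = params.mean_cycle_duration * (1 - params.theta * delta) + noise(
            params.sd_tau
        )
        tau = np.maximum(DURATION_FLOOR, tau)
        Vm = Vb * np.exp(alpha * tau)
        discard = ~(alpha > 0)
    elif mode.mode == "sizer":
        target = mode.target if mode.target is not None else 2.0 * mean_V
        Vm = target + noise(mode.mode_sd)
        alpha = params.mean_growth_rate + noise(params.sd_alpha)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.log(Vm / Vb) / alpha
        discard = ~((Vm > Vb) & (alpha > 0))
    elif mode.mode == "adder":
        added = mode.target if mode.target is not None else mean_V
        dV = added + noise(mode.mode_sd)
        Vm = Vb + dV
        alpha = params.mean_growth_rate + noise(params.sd_alpha)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.log(Vm / Vb) / alpha
        discard = ~((dV > 0) & (alpha > 0))
    elif mode.mode == "timer":
        tau = np.maximum(
            DURATION_FLOOR, params.mean_cycle_duration + noise(mode.mode_sd)
        )
        alpha = params.mean_growth_rate + noise(params.sd_alpha)
        Vm = Vb * np.exp(alpha * tau)
        discard = ~(alpha > 0)
    elif mode.mode == "mechanistic_adder":
        added = mode.target if mode.target is not None else mean_V
        dV = added + noise(mode.mode_sd)
        frac = rng.uniform(*mode.split_range, n)
        Vg1s = Vb + frac * dV
        Vm = Vb + dV
        alpha = params.mean_growth_rate + noise(params.sd_alpha)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau_G1 = np.log(Vg1s / Vb) / alpha
            tau_SG2 = np.log(Vm / Vg1s) / alpha
            tau = tau_G1 + tau_SG2
        discard = ~((dV > 0) & (alpha > 0))
        out["V_G1S"] = Vg1s
        out["tau_G1"] = tau_G1
        out["tau_SG2"] = tau_SG2
    else:  # pragma: no cover - guarded by MechanisticMode validation
        raise ValueError(mode.mode)

    with np.errstate(invalid="ignore"):
        discard = discard | ~np.isfinite(Vm) | (Vm <= 0)
        discard |= ~np.isfinite(tau) | (tau <= 0)
    out.update({"alpha": alpha, "tau": tau, "V_mitosis": Vm, "discard": discard})
    return out


def simulate_lineages(
    params: ModelParams,
    mode: MechanisticMode | str = "linear_response",
    n_founders: int = 10,
    n_generations: int = 10,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    max_cohort_pairs: int | None = None,
) -> pd.DataFrame:
    """Simulate a forest of dividing lineages, one row per completed cycle.

    ``n_generations`` generations are grown from ``n_founders`` founder
    cells with lognormal birth sizes; the first ``burn_in`` generations are
    discarded from the output so that exported populations are close to
    their stationary size distribution. Cells whose stochastic update
    produces a non-physical volume or duration are discarded (and their
    subtree pruned); a warning is emitted when more than 1% of cells are
    lost this way.

    ``max_cohort_pairs`` caps the number of divisions propagated per
    generation (a uniform subsample of whole sister pairs), which keeps the
    population size bounded for long runs instead of growing as 2^g.

    Output is reproducible given the seed.
    """
    if isinstance(mode, str):
        mode = MechanisticMode(mode=mode)
    if n_founders < 1 or n_generations < 1:
        raise ValueError("n_founders and n_generations must be >= 1")
    if burn_in >= n_generations:
        raise ValueError("burn_in must be smaller than n_generations")
    if mode.mode == "linear_response":
        lam_implied = (params.theta + params.gamma) * (
            params.mean_growth_rate * params.mean_cycle_duration
        )
        if lam_implied > 1.5:
            raise ValueError(
                f"implied homeostatic exponent {lam_implied:.3f} > 1.5 "
                "(unstable linear response)"
            )
    rng = np.random.default_rng(seed)

    Vb = np.exp(
        rng.normal(params.mean_log_birth_volume, params.founder_log_sd, n_founders)
    )
    ids = np.arange(n_founders)
    parents = np.full(n_founders, -1)
    sisters = np.full(n_founders, -1)
    t_birth = np.zeros(n_founders)
    next_id = n_founders
    n_discarded = 0
    n_total = 0
    frames = []

    for g in range(n_generations):
        n = Vb.size
        if n == 0:
            break
        n_total += n
        cyc = _cycle_update(params, mode, Vb, rng)
        keep = ~cyc["discard"]
        n_discarded += int(cyc["discard"].sum())
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": ids[keep],
                    "parent_id": parents[keep],
                    "sister_id": sisters[keep],
                    "generation": g,
                    "t_birth": t_birth[keep],
                    "V_birth": Vb[keep],
                    "V_G1S": cyc["V_G1S"][keep],
                    "V_mitosis": cyc["V_mitosis"][keep],
                    "tau_G1": cyc["tau_G1"][keep],
                    "tau_SG2": cyc["tau_SG2"][keep],
                    "tau": cyc["tau"][keep],
                    "alpha": cyc["alpha"][keep],
                }
            )
        )
        if g == n_generations - 1:
            break
        # divide surviving cells into sister pairs
        mothers = np.flatnonzero(keep)
        if max_cohort_pairs is not None and mothers.size > max_cohort_pairs:
            mothers = rng.choice(mothers, size=max_cohort_pairs, replace=False)
            mothers.sort()
        nk = mothers.size
        f = _truncated_normal(
            rng, 0.5, params.division_asymmetry_sd, *params.division_bounds, nk
        )
        Vm = cyc["V_mitosis"][mothers]
        child_t = t_birth[mothers] + cyc["tau"][mothers]
        id1 = next_id + np.arange(nk)
        id2 = next_id + nk + np.arange(nk)
        next_id += 2 * nk
        Vb = np.concatenate([f * Vm, (1 - f) * Vm])
        parents = np.tile(ids[mothers], 2)
        ids = np.concatenate([id1, id2])
        sisters = np.concatenate([id2, id1])
        t_birth = np.tile(child_t, 2)

    if n_total and n_discarded / n_total > 0.01:
        warnings.warn(
            f"{n_discarded}/{n_total} simulated cells discarded "
            "(non-physical volume or duration)",
            stacklevel=2,
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=LINEAGE_COLUMNS
    )
    df = _apply_measurement_noise(df, params.measurement_noise_cv, rng)
    df = df[df["generation"] >= burn_in].reset_index(drop=True)
    return df[LINEAGE_COLUMNS]


def simulate_phases(
    params: ModelParams,
    phases: PhaseParams,
    n_cells: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate independent phase-structured cell cycles.

    Birth volumes are lognormal around the configured mean; G1 duration
    responds linearly to log birth volume with a hard minimum; volume grows
    exponentially at a per-cell rate through both phases; S-G2 is a timer or
    an adder according to ``phases.sg2_mode``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    Vb = np.exp(rng.normal(params.mean_log_birth_volume, params.founder_log_sd, n_cells))
    delta = np.log(Vb) - params.mean_log_birth_volume
    alpha = params.mean_growth_rate * (1 - params.gamma * delta)
    if params.sd_alpha:
        alpha = alpha + rng.normal(0, params.sd_alpha, n_cells)
    tau_G1 = phases.g1_mean - phases.g1_slope * delta
    if phases.g1_sd:
        tau_G1 = tau_G1 + rng.normal(0, phases.g1_sd, n_cells)
    tau_G1 = np.maximum(phases.g1_min, tau_G1)
    V_g1s = Vb * np.exp(alpha * tau_G1)
    if phases.sg2_mode == "timer":
        tau_SG2 = phases.sg2_mean + (
            rng.normal(0, phases.sg2_sd, n_cells) if phases.sg2_sd else 0.0
        )
        tau_SG2 = np.maximum(DURATION_FLOOR, tau_SG2)
        Vm = V_g1s * np.exp(alpha * tau_SG2)
        discard = ~(alpha > 0)
    else:  # adder on S-G2
        dV = phases.sg2_mean + (
            rng.normal(0, phases.sg2_sd, n_cells) if phases.sg2_sd else 0.0
        )
        Vm = V_g1s + dV
        with np.errstate(invalid="ignore", divide="ignore"):
            tau_SG2 = np.log(Vm / V_g1s) / alpha
        discard = ~((dV > 0) & (alpha > 0))
    discard |= ~np.isfinite(Vm) | (Vm <= 0)
    if discard.sum() / n_cells > 0.01:
        warnings.warn(
            f"{int(discard.sum())}/{n_cells} simulated cells discarded",
            stacklevel=2,
        )
    keep = ~discard
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells)[keep],
            "parent_id": -1,
            "sister_id": -1,
            "generation": 0,
            "t_birth": 0.0,
            "V_birth": Vb[keep],
            "V_G1S": V_g1s[keep],
            "V_mitosis": Vm[keep],
            "tau_G1": tau_G1[keep],
            "tau_SG2": tau_SG2 if np.ndim(tau_SG2) == 0 else tau_SG2[keep],
            "tau": (tau_G1 + tau_SG2)[keep],
            "alpha": alpha[keep],
        }
    )
    df = _apply_measurement_noise(df, params.measurement_noise_cv, rng)
    return df[LINEAGE_COLUMNS].reset_index(drop=True)


def render_trajectory(
    record: pd.Series | dict,
    frame_interval: float = 10.0,
    noise_cv: float = 0.0,
    spike_rate: float = 0.0,
    overshoot_amplitude: float = 0.0,
    seed: int | None = None,
    reporter_background: float = 100.0,
    reporter_background_sd: float = 5.0,
    reporter_ramp: float = 10.0,
) -> Trajectory:
    """Render one cell-cycle record as a sampled volume + reporter series.

    The series starts at the cytokinesis onset preceding birth (t = 0 min)
    and ends 20 min after the next onset. Volume follows
    ``V_birth * exp(alpha * (t - t_birth))`` with multiplicative lognormal
    noise of the stated CV; isolated spikes multiply the local value by a
    uniform factor in [2, 10] at the given per-frame probability; the
    mitotic overshoot is a multiplicative bump confined to +/- 20 min of
    each cytokinesis onset. The reporter channel is background noise before
    G1/S and a linear ramp after. Ground-truth event times and spike frames
    are stored on the returned trajectory.
    """
    if not 1.0 <= frame_interval <= 60.0:
        raise ValueError("frame_interval must be within [1, 60] minutes")
    rec = dict(record)
    rng = np.random.default_rng(seed)
    V0 = float(rec["V_birth"])
    alpha = float(rec["alpha"])  # 1/h
    tau = float(rec["tau"])  # h
    t_birth = 40.0
    t_mitosis = t_birth + tau * 60.0
    onset2 = t_mitosis + 60.0
    t_end = onset2 + 20.0
    t = np.arange(0.0, t_end + 1e-9, frame_interval)
    v = V0 * np.exp(alpha * (t - t_birth) / 60.0)

    tau_g1 = rec.get("tau_G1", np.nan)
    t_g1s = t_birth + float(tau_g1) * 60.0 if np.isfinite(tau_g1) else np.nan

    if overshoot_amplitude > 0:
        for onset in (0.0, onset2):
            near = np.abs(t - onset) <= 20.0
            bump = 1.0 + overshoot_amplitude * np.cos(
                np.pi * (t[near] - onset) / 40.0
            ) ** 2
            v[near] *= bump
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        v = v * rng.lognormal(-sigma**2 / 2, sigma, t.size)
    spike_frames = np.zeros(t.size, dtype=bool)
    if spike_rate > 0:
        spike_frames = rng.random(t.size) < spike_rate
        v[spike_frames] *= rng.uniform(2.0, 10.0, int(spike_frames.sum()))

    reporter = rng.normal(reporter_background, reporter_background_sd, t.size)
    if np.isfinite(t_g1s):
        ramp = t >= t_g1s
        reporter[ramp] += reporter_ramp * (t[ramp] - t_g1s) / frame_interval

    return Trajectory(
        cell_id=str(rec.get("cell_id", "sim")),
        t=t,
        volume=v,
        reporter=reporter,
        frame_interval=frame_interval,
        cytokinesis_onsets=[0.0, onset2],
        ground_truth={
            "t_birth": t_birth,
            "t_mitosis": t_mitosis,
            "t_G1S": t_g1s,
            "V_birth": V0,
            "V_mitosis": V0 * math.exp(alpha * tau),
            "alpha": alpha,
            "spike_frames": np.flatnonzero(spike_frames),
        },
    )
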