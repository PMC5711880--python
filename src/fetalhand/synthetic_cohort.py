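"""Synthetic cohort generator emulating the study's statistical structure.

Additive Gaussian model on the millisecond scale: a shared per-fetus speed
offset (between-fetus SD ``sigma_fetus``) induces the within-subject RH/LH
correlation; the dominant-hand advantage ``delta`` is split +-delta/2
between the hands so each condition's pooled mean is centred regardless of
handedness, isolating the asymmetry in the HAA exactly.

Baseline per-target MT/TPV means are implementer defaults (no per-target
means are available to anchor them); effect sizes, group sizes and expected
movement counts follow the published marginals.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from fetalhand.data_model import (
    GESTATIONAL_WEEKS,
    TARGETS,
    Cohort,
    FetusInfo,
    MovementRecord,
)
from fetalhand.errors import ValidationError
from fetalhand.kinematics import Trajectory

log = logging.getLogger("fetalhand.synthetic")

SAMPLING_HZ = 4.0


def _default_mu_mt():
    # Invented baselines (no per-target means are published).  Tuned jointly
    # so that (i) the pooled eye-MT trend recovers a rank correlation ~0.47
    # given the anchored variance components (the 900->1300 spread is too
    # narrow for that once the 450 ms between-fetus SD is in play), and
    # (ii) every baseline sits >2.3 SD above the 200 ms truncation floor so
    # truncation stays below 1% of movements.  Ordering preserves the
    # reported precision gradient: eye slowest, wall fastest.
    mu = {("eye", 14): 1800.0, ("eye", 18): 2150.0, ("eye", 22): 2500.0}
    for gw in GESTATIONAL_WEEKS:
        mu[("mouth", gw)] = 1700.0
        mu[("wall", gw)] = 1500.0
    return mu


def _default_delta_mt():
    # Dominant-hand MT advantage for precision targets from GW18, plus the
    # reported mouth asymmetry already present at GW14.
    d = {(t, gw): 0.0 for t in TARGETS for gw in GESTATIONAL_WEEKS}
    for t in ("eye", "mouth"):
        for gw in (18, 22):
            d[(t, gw)] = 318.0
    d[("mouth", 14)] = 318.0
    return d


def _default_mu_tpv():
    return {"eye": 40.0, "mouth": 45.0, "wall": 55.0}


def _default_delta_tpv():
    d = {(t, gw): 0.0 for t in TARGETS for gw in GESTATIONAL_WEEKS}
    for t in ("eye", "mouth"):
        for gw in (18, 22):
            d[(t, gw)] = 2.1
    return d


def _default_rh_use_prob():
    return {
        ("right", 14): 0.55, ("right", 18): 0.60, ("right", 22): 0.60,
        ("left", 14): 0.50, ("left", 18): 0.45, ("left", 22): 0.45,
    }


def _default_movements_per_fetus_week():
    # Poisson means chosen so expected group-by-week totals match the
    # published count marginals: right 120/138/158 over 25 fetuses,
    # left 19/26/27 over 4 fetuses.
    return {
        ("right", 14): 120 / 25, ("right", 18): 138 / 25, ("right", 22): 158 / 25,
        ("left", 14): 19 / 4, ("left", 18): 26 / 4, ("left", 22): 27 / 4,
    }


@dataclass
class SyntheticConfig:
    """Full parameterization of the data-generating model.

    ``exact_group_sizes=True`` (default) assigns exactly
    ``round(n_fetuses * p_right)`` right-handers so small cohorts always
    contain both classes; set it to False for i.i.d. Bernoulli(p_right)
    handedness.
    """

    n_fetuses: int = 29
    p_right: float = 25 / 29
    mu_mt: dict = field(default_factory=_default_mu_mt)  # (target, gw) -> ms
    delta_mt: dict = field(default_factory=_default_delta_mt)  # (target, gw) -> ms
    mu_tpv: dict = field(default_factory=_default_mu_tpv)  # target -> pp
    delta_tpv: dict = field(default_factory=_default_delta_tpv)  # (target, gw) -> pp
    sigma_fetus: float = 450.0  # between-fetus MT SD, ms
    sigma_resid: float = 300.0  # within-fetus movement SD, ms
    sigma_tpv: float = 5.0  # TPV residual SD, pp
    rh_use_prob: dict = field(default_factory=_default_rh_use_prob)  # (group, gw)
    movements_per_fetus_week: dict = field(default_factory=_default_movements_per_fetus_week)
    mt_floor: float = 200.0  # truncation bound, ms
    exact_group_sizes: bool = True
    lognormal_resid: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n_fetuses < 1:
            raise ValidationError("n_fetuses must be >= 1")
        if not 0 < self.p_right < 1:
            raise ValidationError("p_right must lie in (0, 1)")
        for name in ("sigma_fetus", "sigma_resid", "sigma_tpv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.mu_mt.values()):
            raise ValidationError("mu_mt entries must be > 0")
        if any(not 0 < v < 1 for v in self.rh_use_prob.values()):
            raise ValidationError("rh_use_prob entries must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        """Build a config from a plain (YAML/JSON-friendly) mapping.

        Nested tables use string keys: ``mu_mt: {eye: {'14': 900, ...}}``,
        ``rh_use_prob: {right: {'14': 0.55, ...}}``, ``mu_tpv: {eye: 40}``.
        """
        kwargs = dict(raw)

        def unfold(key):
            if key in kwargs and isinstance(kwargs[key], dict):
                nested = kwargs[key]
                kwargs[key] = {
                    (outer, int(inner)): float(v)
                    for outer, row in nested.items()
                    for inner, v in row.items()
                }

        for key in ("mu_mt", "delta_mt", "delta_tpv", "rh_use_prob",
                    "movements_per_fetus_week"):
            unfold(key)
        if "mu_tpv" in kwargs and isinstance(kwargs["mu_tpv"], dict):
            kwargs["mu_tpv"] = {t: float(v) for t, v in kwargs["mu_tpv"].items()}
        base = cls()
        merged = {f.name: getattr(base, f.name) for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - set(merged)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key, value in kwargs.items():
            if isinstance(merged[key], dict) and isinstance(value, dict):
                merged[key] = {**merged[key], **value}
            else:
                merged[key] = value
        return cls(**merged)


def recovery_config(**overrides) -> SyntheticConfig:
    """Dense-sampling configuration for parameter-recovery checks.

    Roughly 4 movements per hand per (target x week) cell: Poisson mean 24
    movements per fetus-week, balanced hand use.  Per-fetus/week counts are
    far above the published marginals on purpose -- at the published counts
    (~1 movement per hand per cell) per-condition HAA is undefined for many
    fetuses and the variance-components predictions do not apply.
    """
    dense = {(g, gw): 24.0 for g in ("right", "left") for gw in GESTATIONAL_WEEKS}
    balanced = {(g, gw): 0.5 for g in ("right", "left") for gw in GESTATIONAL_WEEKS}
    kwargs = {"movements_per_fetus_week": dense, "rh_use_prob": balanced}
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Draw one synthetic cohort; bit-reproducible from the seed.

    Handedness per fetus, a shared per-fetus offset b_i ~ N(0, sigma_fetus^2),
    Poisson movement counts per week, uniform targets, Bernoulli hand choice,
    and MT = mu + b_i -/+ delta/2 (dominant/non-dominant) + N(0, sigma_resid^2)
    truncated below at ``mt_floor``; TPV analogous, clipped into (1, 99).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_fetuses
    ids = [f"f{i + 1:03d}" for i in range(n)]

    if config.exact_group_sizes:
        n_right = int(round(n * config.p_right))
        n_right = min(max(n_right, 1), n - 1) if n > 1 else n_right
        handed = ["right"] * n_right + ["left"] * (n - n_right)
    else:
        handed = ["right" if u < config.p_right else "left" for u in rng.random(n)]
    offsets = rng.normal(0.0, config.sigma_fetus, size=n)

    records: list[MovementRecord] = []
    n_clipped = 0
    for fid, group, b in zip(ids, handed, offsets):
        for gw in GESTATIONAL_WEEKS:
            count = rng.poisson(config.movements_per_fetus_week[(group, gw)])
            for _ in range(count):
                target = TARGETS[rng.integers(len(TARGETS))]
                hand = "right" if rng.random() < config.rh_use_prob[(group, gw)] else "left"
                dominant = hand == group
                half = config.delta_mt[(target, gw)] / 2.0
                if config.lognormal_resid:
                    s = 0.5
                    eps = config.sigma_resid * (
                        (rng.lognormal(0.0, s) - np.exp(s * s / 2.0))
                        / np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
                    )
                else:
                    eps = rng.normal(0.0, config.sigma_resid)
                mt = config.mu_mt[(target, gw)] + b + (-half if dominant else half) + eps
                half_tpv = config.delta_tpv[(target, gw)] / 2.0
                tpv = (
                    config.mu_tpv[target]
                    + (half_tpv if dominant else -half_tpv)
                    + rng.normal(0.0, config.sigma_tpv)
                )
                if mt < config.mt_floor or not 1.0 <= tpv <= 99.0:
                    n_clipped += 1
                mt = max(mt, config.mt_floor)
                tpv = float(np.clip(tpv, 1.0, 99.0))
                records.append(MovementRecord(fid, gw, target, hand, float(mt), float(tpv)))

    if records:
        log.debug("truncated/clipped %d of %d movements (%.2f%%)",
                  n_clipped, len(records), 100.0 * n_clipped / len(records))
    fetuses = [FetusInfo(fid, h) for fid, h in zip(ids, handed)]
    return Cohort(fetuses=fetuses, records=records)


def generate_null_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """As :func:`generate_cohort` with all effects removed.

    Every delta is forced to 0 and all right-hand-use probabilities to 0.5;
    everything else (counts, variance components) is kept.
    """
    null_cfg = dataclasses.replace(
        config,
        delta_mt={k: 0.0 for k in config.delta_mt},
        delta_tpv={k: 0.0 for k in config.delta_tpv},
        rh_use_prob={k: 0.5 for k in config.rh_use_prob},
    )
    return generate_cohort(null_cfg, seed=seed)


def generate_trajectory(
    mt_ms: float,
    tpv_pct: float,
    seed: int | None = None,
    jitter: float = 0.0,
    fs: float = SAMPLING_HZ,
) -> Trajectory:
    """A 2-D path with a triangular speed profile, sampled at ``fs`` Hz.

    Speed rises linearly from 0 at t=0 to 1 intraocular unit/s at
    tpv_pct% of mt_ms, then falls linearly back to 0 at mt_ms.  Positions
    are the exact closed-form integral of that profile (optionally with
    Gaussian positional jitter), so metric extraction on the noiseless
    output recovers mt within one sample period and tpv within
    100 * (sample period) / mt.
    """
    if not mt_ms > 500:
        raise ValidationError("mt_ms must exceed 500 ms (>= 3 samples at 4 Hz)")
    if not 0 < tpv_pct < 100:
        raise ValidationError("tpv_pct must lie in (0, 100)")
    mt_s = mt_ms / 1000.0
    tp = tpv_pct / 100.0 * mt_s
    h = 1.0 / fs
    times = np.arange(0.0, mt_s + 1e-12, h)

    x = np.empty_like(times)
    rise = times <= tp
    x[rise] = times[rise] ** 2 / (2.0 * tp)
    fall = ~rise
    x[fall] = tp / 2.0 + (mt_s - tp) / 2.0 - (mt_s - times[fall]) ** 2 / (2.0 * (mt_s - tp))
    positions = np.column_stack([x, np.zeros_like(x)])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, jitter, size=positions.shape)
    return Trajectory(times=times, positions=positions, calibration_length=1.0)
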