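"""Seeded synthetic-data generators.

Each generator emits data with the statistical structure the analysis
modules assume, so the full pipeline is testable without any download:

* :func:`gen_expression` — FPKM matrices over a checkpoint panel with
  log-normal sample noise and per-gene planted fold changes, emulating a
  small-vs-large-tumor bulk RNA-seq design (3 samples per group by
  default, matching the sequenced tumor groups).
* :func:`gen_growth` — exponential tumor growth V(t) = v0 exp(r t) with
  log-normal measurement noise; treated responders carry a reduced or
  negative effective growth rate.
* :func:`gen_cohort` — patient tables either expanded exactly from a
  2x2x2 contingency table (continuous TPS/BTV drawn within the correct
  bands) or sampled generatively from cell frequencies and a logistic
  response model.
* :func:`gen_survival` — exponential overall-survival times with a target
  group hazard ratio and independent censoring.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hiskit.cohort import JointTable2x2x2, LogisticModel
from hiskit.expression import DEFAULT_PANEL, ExpressionMatrix, GenePanel
from hiskit.growth import GrowthCurve
from hiskit.presets import BTV_CUTOFF

__all__ = [
    "ExpressionSimConfig",
    "GrowthSimConfig",
    "CohortSimConfig",
    "gen_expression",
    "gen_growth",
    "gen_cohort",
    "gen_survival",
]


def _sigma_from_cv(cv: float) -> float:
    """Log-normal sigma with the given coefficient of variation."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass
class ExpressionSimConfig:
    """Two-group FPKM simulation over a gene panel.

    ``planted_fc`` sets each gene's comparison/baseline median ratio; the
    noise is log-normal with coefficient of variation ``noise_cv`` applied
    multiplicatively to every sample, so at ``noise_cv=0`` the planted
    fold changes are reproduced exactly.
    """

    panel: GenePanel = field(default_factory=lambda: DEFAULT_PANEL)
    n_per_group: int = 3
    base_mean: float = 20.0  # FPKM
    planted_fc: np.ndarray | float = 1.0
    noise_cv: float = 0.2
    baseline_group: str = "small"
    comparison_group: str = "large"
    seed: int = 0

    def fc_vector(self) -> np.ndarray:
        fc = np.broadcast_to(np.asarray(self.planted_fc, dtype=float),
                             (len(self.panel),)).copy()
        if np.any(fc <= 0):
            raise ValueError("planted fold changes must be > 0")
        return fc


def gen_expression(config: ExpressionSimConfig) -> ExpressionMatrix:
    """Simulate a gene x sample FPKM matrix with planted fold changes."""
    if config.base_mean <= 0:
        raise ValueError("base_mean must be > 0")
    rng = np.random.default_rng(config.seed)
    fc = config.fc_vector()
    g = len(config.panel)
    n = config.n_per_group
    sigma = _sigma_from_cv(config.noise_cv)

    base_median = np.full(g, config.base_mean)
    comp_median = base_median * fc
    noise = rng.standard_normal((g, 2 * n)) * sigma
    values = np.concatenate(
        [base_median[:, None] * np.exp(noise[:, :n]),
         comp_median[:, None] * np.exp(noise[:, n:])],
        axis=1,
    )
    sample_ids = tuple(
        [f"{config.baseline_group}_{i+1}" for i in range(n)]
        + [f"{config.comparison_group}_{i+1}" for i in range(n)]
    )
    groups = {s: config.baseline_group for s in sample_ids[:n]}
    groups.update({s: config.comparison_group for s in sample_ids[n:]})
    return ExpressionMatrix(panel=config.panel, sample_ids=sample_ids,
                            group_labels=groups, values=values)


@dataclass
class GrowthSimConfig:
    """Two-arm exponential tumor-growth simulation.

    ``treatment_effect`` is the multiplicative reduction of the growth
    rate in treated responders (values > 1 produce shrinkage);
    ``responder_fraction`` is the probability a treated mouse responds.
    Control mice always grow at ``growth_rate``.
    """

    n_per_arm: int = 10
    v0: float = 50.0  # mm^3, a 4-5 mm tumor
    growth_rate: float = 0.18  # per day
    treatment_effect: float = 1.6
    responder_fraction: float = 0.8
    measurement_days: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18, 21)
    noise_cv: float = 0.10
    control_arm: str = "IgG"
    treated_arm: str = "aPD1"
    seed: int = 0


def gen_growth(config: GrowthSimConfig) -> list[GrowthCurve]:
    """Simulate control and treated growth curves; returns both arms."""
    if config.growth_rate < 0 or config.v0 <= 0:
        raise ValueError("v0 and growth_rate must be positive")
    if not 0 <= config.responder_fraction <= 1:
        raise ValueError("responder_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    sigma = _sigma_from_cv(config.noise_cv)
    days = np.asarray(config.measurement_days, dtype=float)

    curves: list[GrowthCurve] = []
    for arm, treated in ((config.control_arm, False), (config.treated_arm, True)):
        for i in range(config.n_per_arm):
            rate = config.growth_rate
            if treated and rng.random() < config.responder_fraction:
                rate = config.growth_rate * (1.0 - config.treatment_effect)
            noise = np.exp(rng.standard_normal(len(days)) * sigma)
            vols = config.v0 * np.exp(rate * days) * noise
            curves.append(GrowthCurve(
                mouse_id=f"{arm}_{i+1}",
                arm=arm,
                days=tuple(int(d) for d in config.measurement_days),
                volumes=tuple(float(v) for v in vols),
            ))
    return curves


@dataclass
class CohortSimConfig:
    """Clinical cohort simulation.

    Exactly one of ``joint_table`` (explicit cell counts, expanded
    deterministically) or ``cell_frequencies`` + ``model`` (generative
    multinomial sampling with logistic response probabilities) must be
    given. Continuous covariates are drawn within the stated band: TPS
    uniformly over the positive/negative percent range at ``tps_cut``,
    BTV log-normally on the correct side of ``btv_cutoff``. Analyses in
    this package use only the band indicators, so these draws affect no
    measurable statistic.
    """

    joint_table: JointTable2x2x2 | None = None
    cell_frequencies: dict[tuple[bool, bool], float] | None = None
    model: LogisticModel | None = None
    n_patients: int | None = None
    tps_cut: float = 50.0
    btv_cutoff: float = BTV_CUTOFF
    seed: int = 0


def _draw_covariates(rng, btv_small: bool, tps_pos: bool, tps_cut: float,
                     btv_cutoff: float) -> tuple[float, float]:
    if tps_pos:
        tps = rng.uniform(tps_cut, 100.0)
    else:
        tps = rng.uniform(0.0, tps_cut)
    # log-normal spread on the correct side of the BTV cutoff
    offset = abs(rng.standard_normal()) * 0.8 + 0.05
    btv = btv_cutoff * np.exp(-offset if btv_small else offset)
    return float(tps), float(btv)


def gen_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a patient table (patient_id, tps, btv, indicators, response).

    With ``joint_table``, cell membership is exact (deterministic counts);
    with ``cell_frequencies``/``model``, patients are sampled multinomially
    and respond with the model's cell probability.
    """
    rng = np.random.default_rng(config.seed)
    rows = []

    if config.joint_table is not None:
        if config.cell_frequencies is not None or config.model is not None:
            raise ValueError("give either joint_table or cell_frequencies+model")
        for (b, t), (n_resp, n_non) in sorted(config.joint_table.cells.items(),
                                              reverse=True):
            for resp, count in ((1, n_resp), (0, n_non)):
                for _ in range(count):
                    tps, btv = _draw_covariates(rng, b, t, config.tps_cut,
                                                config.btv_cutoff)
                    rows.append((b, t, resp, tps, btv))
    else:
        if config.cell_frequencies is None or config.model is None:
            raise ValueError("generative mode needs cell_frequencies and model")
        if config.n_patients is None:
            raise ValueError("generative mode needs n_patients")
        keys = sorted(config.cell_frequencies, reverse=True)
        freqs = np.array([config.cell_frequencies[k] for k in keys], dtype=float)
        if not np.isclose(freqs.sum(), 1.0):
            raise ValueError("cell frequencies must sum to 1")
        counts = rng.multinomial(config.n_patients, freqs)
        for (b, t), count in zip(keys, counts):
            if count == 0:
                continue
            p = float(config.model.predict_probability(b, t))
            responses = rng.random(count) < p
            for resp in responses:
                tps, btv = _draw_covariates(rng, b, t, config.tps_cut,
                                            config.btv_cutoff)
                rows.append((b, t, int(resp), tps, btv))

    df = pd.DataFrame(rows, columns=["btv_small", "tps_positive", "response",
                                     "tps", "btv"])
    df.insert(0, "patient_id", [f"P{i+1:04d}" for i in range(len(df))])
    return df


def gen_survival(
    cohort: pd.DataFrame,
    hr_target: float,
    baseline_median_months: float = 20.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    group_col: str = "tps_positive",
) -> pd.DataFrame:
    """Attach exponential overall-survival times with a target hazard ratio.

    Group 0 (``group_col`` false) has hazard ln2 / baseline_median_months;
    group 1's hazard is that times ``hr_target``. Each subject is censored
    independently with probability ``censor_rate``, at a uniform fraction
    of its event time. Returns a copy with ``os_months`` and ``event``.
    """
    if hr_target <= 0:
        raise ValueError("hr_target must be > 0")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    lam0 = np.log(2.0) / baseline_median_months
    group = out[group_col].to_numpy(dtype=bool)
    lam = np.where(group, lam0 * hr_target, lam0)
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(len(out)) < censor_rate
    t_obs = np.where(censored, t_event * rng.random(len(out)), t_event)
    out["os_months"] = t_obs
    out["event"] = (~censored).astype(int)
    return out
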