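"""Seeded synthetic cohorts with planted outliers.

The real obstetric cohort behind this method is private, so testing and
benchmarking run on synthetic strata that mirror its published structure:
sample sizes of roughly 800-2700 per parity stratum, outcome prevalence
between 1.3% and 16.5%, and predominantly binary risk factors.

The generative model is deliberately simple. Every feature is Bernoulli.
Normal patients draw all features at ``base_rate``. Abnormal ("planted
outlier") patients draw ``n_informative`` designated features at
``base_rate + effect_delta`` and the rest at ``base_rate``. The abnormal
count is exact — ``round(prevalence * n)`` rows, placed by sampling without
replacement — so tiny-prevalence strata are reproducible rather than
occasionally empty.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, FeatureSpec, RiskFactorSchema

_DEFAULT_N_FEATURES = 20
_DEFAULT_N_INFORMATIVE = 5
_DEFAULT_BASE_RATE = 0.2
_DEFAULT_EFFECT_DELTA = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic stratum.

    ``n_informative`` of the ``n_features`` binary features carry the signal:
    their Bernoulli rate is shifted by ``effect_delta`` in the abnormal class.
    The remaining features are pure noise at ``base_rate`` in both classes.
    """

    n_patients: int
    prevalence: float
    n_features: int = _DEFAULT_N_FEATURES
    n_informative: int = _DEFAULT_N_INFORMATIVE
    base_rate: float = _DEFAULT_BASE_RATE
    effect_delta: float = _DEFAULT_EFFECT_DELTA
    parity_label: str = "parous"
    outcome: str = "PTB"
    missing_rate: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate outside [0, 1]")
        if not 0.0 <= self.base_rate + self.effect_delta <= 1.0:
            raise ValueError("base_rate + effect_delta outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")

    @property
    def n_abnormal(self) -> int:
        return int(round(self.prevalence * self.n_patients))


def _schema_for(config: SimulationConfig) -> RiskFactorSchema:
    feats = [FeatureSpec(f"rf{i:02d}", "binary") for i in range(config.n_features)]
    return RiskFactorSchema(feats)


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw one cohort under ``config``; bit-reproducible from its seed.

    One master seed fans out to independent substreams for label placement,
    feature draws, and missingness, so varying the noise stream leaves the
    planted-outlier positions fixed.
    """
    n, f = config.n_patients, config.n_features
    ss = np.random.SeedSequence(config.seed)
    label_rng, feat_rng, miss_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    abnormal_idx = label_rng.choice(n, size=config.n_abnormal, replace=False)
    labels = np.zeros(n, dtype=int)
    labels[abnormal_idx] = 1

    rates = np.full((n, f), config.base_rate)
    informative = np.arange(config.n_informative)
    rates[np.ix_(abnormal_idx, informative)] = config.base_rate + config.effect_delta
    X = (feat_rng.random((n, f)) < rates).astype(float)

    if config.missing_rate > 0:
        X[miss_rng.random((n, f)) < config.missing_rate] = np.nan

    schema = _schema_for(config)
    ids = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="patient_id")
    return CohortTable(
        patient_id=ids,
        features=pd.DataFrame(X, columns=schema.names),
        parity=pd.Series([config.parity_label] * n, name="parity"),
        labels=pd.DataFrame({config.outcome: labels}),
        schema=schema,
    )


#: (name, outcome, parity, total, abnormal) for the six published strata.
_STRATA = (
    ("lbw-parous", "LBW", "parous", 2668, 261),
    ("lbw-nulliparous", "LBW", "nulliparous", 785, 130),
    ("ptb-parous", "PTB", "parous", 2708, 297),
    ("ptb-nulliparous", "PTB", "nulliparous", 801, 97),
    ("vptb-parous", "vPTB", "parous", 2708, 35),
    ("vptb-nulliparous", "vPTB", "nulliparous", 801, 22),
)


def stratum_presets(seed: int = 0) -> list[SimulationConfig]:
    """The six cohort strata of the study, as simulation configs.

    Prevalence is set to abnormal/total exactly, so the generated abnormal
    count reproduces the published one (round(prevalence * n) = abnormal).
    """
    return [
        SimulationConfig(
            n_patients=total,
            prevalence=abnormal / total,
            parity_label=parity,
            outcome=outcome,
            seed=seed,
            name=name,
        )
        for name, outcome, parity, total, abnormal in _STRATA
    ]


def preset_by_name(name: str, seed: int = 0) -> SimulationConfig:
    """Look up a stratum preset (e.g. ``"ptb-nulliparous"``) by name."""
    for cfg in stratum_presets(seed):
        if cfg.name == name:
            return cfg
    raise KeyError(f"unknown preset {name!r}; options: {[s[0] for s in _STRATA]}")


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
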