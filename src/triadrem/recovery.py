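"""Parameter-recovery experiments: can the fitting pipeline find the
generator's parameters back?

The generator works on unnormalised history counts while the fitted model
sees z-scaled statistics, so the recovery target for each count effect is
the generating coefficient multiplied by the realized sample standard
deviation of its column (centring cancels within strata and the binary
unfamiliarity indicator is never rescaled).  For each simulated study both
models are fitted on the strata pooled over all days and triads of that
study, and a nominal 95% Wald interval per effect is checked against the
rescaled truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import STAT_NAMES, normalize_statistics, pool_strata
from .fit import FitResult, fit_conditional_logit
from .simulate import SimConfig, Study, simulate_study

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ModelRecovery:
    """One study × model-type comparison of estimate against truth."""

    model_type: str
    fit: FitResult
    truth_scaled: np.ndarray
    covered: np.ndarray  # bool per effect

    @property
    def error(self) -> np.ndarray:
        return self.fit.theta - self.truth_scaled


def rescale_truth(theta_raw, sd: np.ndarray) -> np.ndarray:
    """Generating coefficients on the z-scaled statistic scale."""
    theta_raw = np.asarray(theta_raw, dtype=float)
    scaled = theta_raw.copy()
    scaled[1:] = theta_raw[1:] * sd
    return scaled


def recover_study(study: Study, hour_window_s: int | None = None) -> dict[str, ModelRecovery]:
    """Fit pair and group models to one simulated study and compare each
    effect's Wald interval with the rescaled generative truth."""
    cfg = study.config
    if hour_window_s is None:
        hour_window_s = cfg.hour_window_s
    out: dict[str, ModelRecovery] = {}
    for model_type, theta_raw in (
        ("pair", cfg.theta_pair),
        ("group", cfg.theta_group),
    ):
        strata = pool_strata(study.streams, model_type, hour_window_s=hour_window_s)
        strata, norm = normalize_statistics(strata, return_scales=True)
        fit = fit_conditional_logit(strata, effects=STAT_NAMES)
        truth = rescale_truth(theta_raw, norm.sd)
        covered = np.abs(fit.theta - truth) <= Z_95 * fit.se
        out[model_type] = ModelRecovery(model_type, fit, truth, covered)
    return out


@dataclass
class CoverageResult:
    """Wald-interval coverage over replicated simulated studies."""

    n_studies: int
    effects: tuple[str, ...]
    covered_pair: np.ndarray  # (n_studies, 5) booleans
    covered_group: np.ndarray
    n_converged: int

    def coverage(self, model_type: str) -> np.ndarray:
        arr = self.covered_pair if model_type == "pair" else self.covered_group
        return arr.mean(axis=0)


def coverage_experiment(
    config: SimConfig,
    n_studies: int,
    seed: int,
) -> CoverageResult:
    """Simulate ``n_studies`` independent studies and record, per effect and
    model, whether the nominal 95% interval covered the rescaled truth."""
    rng = np.random.default_rng(seed)
    study_seeds = rng.integers(0, 2**31 - 1, size=n_studies)
    cov_pair, cov_group = [], []
    n_converged = 0
    for s in study_seeds:
        study = simulate_study(replace(config, seed=int(s)))
        rec = recover_study(study)
        if rec["pair"].fit.converged and rec["group"].fit.converged:
            n_converged += 1
        cov_pair.append(rec["pair"].covered)
        cov_group.append(rec["group"].covered)
    return CoverageResult(
        n_studies=n_studies,
        effects=STAT_NAMES,
        covered_pair=np.vstack(cov_pair),
        covered_group=np.vstack(cov_group),
        n_converged=n_converged,
    )
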