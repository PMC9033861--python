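"""Associative (Rescorla-Wagner) models of momentary self-esteem.

All variants share a learning "hub": each rater group g carries an expected
social value ESV_g in [0, 1], updated after feedback R in {0, 1} by

    SPE_t   = R_t - ESV_g(t)                     (social prediction error)
    ESV_g(t+1) = ESV_g(t) + eta_c * SPE_t        (delta rule)

where the learning rate eta_c is common (baseline) or valenced
(eta_pos / eta_neg, the dual-learning-rate variants).

The self-esteem "spoke" reads out a leaky sum of prediction errors.  For a
probe following trial t,

    SE_t = w0 + w1 * sum_j gamma^(t-j) SPE_j + eps,   eps ~ N(0, sigma)

optionally extended by a separate expectation term w_EV * sum gamma^(t-j)
ESV_j, or mixing approval and competence prediction errors through w3, or
replacing the affine readout by a sigmoid of the leaky SPE sum (the
sigmoid variant).  The leaky sums are maintained by the equivalent
recursion X_t = gamma * X_{t-1} + PE_t.

The choice "spoke" predicts approval by a two-action softmax over
Q_accept = ESV_g + B and Q_reject = 1 - ESV_g at temperature tau.

Competence: a prediction that matches the outcome earns a return of 1
(else 0); its action value is Q_a = ESV_g for predicting approval and
1 - ESV_g for predicting disapproval, giving a competence prediction error
CPE = return - Q_a.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import exp, log, pi
from typing import Sequence

import numpy as np

from . import config
from .errors import ParameterError
from .registry import register
from .task import ParticipantRecord, TaskSchedule

__all__ = [
    "AssocParams",
    "AssociativeModel",
    "spe",
    "update_esv",
    "cpe",
    "choice_prob_assoc",
    "se_mean",
    "se_sigmoid_assoc",
    "se_loglik_gaussian",
    "leaky_sum",
]

_LOG_2PI = log(2.0 * pi)
_CLAMP_LO, _CLAMP_HI = config.RATING_CLAMP

INITIAL_ESV = 0.5  # uninformative midpoint; groups start indistinguishable


def _expit(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + exp(-x))
    e = exp(x)
    return e / (1.0 + e)


def _clamp(r: float) -> float:
    return min(max(r, _CLAMP_LO), _CLAMP_HI)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssocParams:
    """Free parameters of the associative family.

    Variant-specific fields are simply ignored by variants that do not use
    them; each variant's ``fit_param_names`` selects the free subset.  The
    fixed-positivity-bias variant pins ``B_choice`` to 0.
    """

    eta: float = 0.3          # learning rate (single-rate variants)
    eta_pos: float = 0.3      # learning rate for positive SPEs (2LR)
    eta_neg: float = 0.3      # learning rate for negative SPEs (2LR)
    gamma: float = 0.5        # forgetting factor of the leaky PE sum
    w0: float = 0.5           # baseline self-esteem on the [0,1] rating scale
    w1: float = 0.1           # weight of the leaky SPE sum
    w_EV: float = 0.0         # weight of the separate expectation sum
    w3: float = 1.0           # approval (1) vs competence (0) mixture
    sigma: float = 0.1        # rating noise SD
    B_choice: float = 0.0     # positivity bias on predicting approval
    tau: float = 0.2          # decision temperature
    m_sig: float = 1.0        # sigmoid-readout sensitivity (sigmoid variant)
    B_sig: float = 0.0        # sigmoid-readout bias (sigmoid variant)


# ---------------------------------------------------------------------------
# Elementary operations (exposed for direct use and testing)
# ---------------------------------------------------------------------------

def spe(outcome: int, esv_g: float) -> float:
    """Social prediction error R - ESV_g."""
    return outcome - esv_g


def update_esv(esv: Sequence[float], group: int, spe_val: float,
               params: AssocParams, variant: str = "associative") -> list[float]:
    """Delta-rule update of the encountered group's expected social value.

    ``group`` is 0-based.  Dual-learning-rate variants pick eta by the sign
    of the prediction error.  Returns a new list; other groups unchanged.
    """
    out = list(esv)
    if "2lr" in variant:
        lr = params.eta_pos if spe_val > 0 else params.eta_neg if spe_val < 0 else 0.0
    else:
        lr = params.eta
    out[group] = out[group] + lr * spe_val
    return out


def cpe(prediction: int, esv_g: float, outcome: int) -> float:
    """Competence prediction error: realised prediction success minus its action value."""
    q_a = esv_g if prediction == 1 else 1.0 - esv_g
    competence = 1.0 if prediction == outcome else 0.0
    return competence - q_a


def choice_prob_assoc(esv_g: float, params: AssocParams) -> float:
    """Probability of predicting approval: softmax over Q_accept = ESV + B
    and Q_reject = 1 - ESV at temperature tau."""
    if params.tau <= 0:
        raise ParameterError("tau must be > 0")
    return _expit((2.0 * esv_g - 1.0 + params.B_choice) / params.tau)


def leaky_sum(values: Sequence[float], gamma: float) -> float:
    """Leaky accumulation X_t = gamma * X_{t-1} + v_t (equals the explicit
    kernel sum sum_j gamma^(t-j) v_j with the most recent value unweighted)."""
    x = 0.0
    for v in values:
        x = gamma * x + v
    return x


def se_mean(spe_history: Sequence[float], params: AssocParams,
            variant: str = "associative",
            esv_history: Sequence[float] | None = None,
            cpe_history: Sequence[float] | None = None) -> float:
    """Expected self-esteem rating at a probe, from realised PE histories.

    Histories are ordered oldest first and include every feedback trial up
    to and including the trial immediately preceding the probe.
    """
    x_spe = leaky_sum(spe_history, params.gamma)
    if variant == "associative_sigmoid":
        return _expit((x_spe + params.B_sig) * params.m_sig)
    if variant == "associative_competence":
        x_cpe = leaky_sum(cpe_history or (), params.gamma)
        return params.w0 + params.w1 * (params.w3 * x_spe + (1.0 - params.w3) * x_cpe)
    mean = params.w0 + params.w1 * x_spe
    if variant == "associative_2lr_expectation":
        mean += params.w_EV * leaky_sum(esv_history or (), params.gamma)
    return mean


def se_sigmoid_assoc(spe_history: Sequence[float], params: AssocParams) -> float:
    """Sigmoid readout 1/(1 + exp(-(X + B_sig) * m_sig)) of the leaky SPE sum."""
    if params.m_sig <= 0:
        raise ParameterError("m_sig must be > 0")
    return _expit((leaky_sum(spe_history, params.gamma) + params.B_sig) * params.m_sig)


def se_loglik_gaussian(rating: float, mean: float, sigma: float) -> float:
    """Gaussian log density of an observed rating at the model mean."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    z = (rating - mean) / sigma
    return -0.5 * _LOG_2PI - log(sigma) - 0.5 * z * z


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------

_VARIANT_PARAMS: dict[str, tuple[str, ...]] = {
    "associative": ("eta", "gamma", "w0", "w1", "sigma", "B_choice", "tau"),
    "associative_2lr": ("eta_pos", "eta_neg", "gamma", "w0", "w1",
                        "sigma", "B_choice", "tau"),
    "associative_2lr_expectation": ("eta_pos", "eta_neg", "gamma", "w0", "w1",
                                    "w_EV", "sigma", "B_choice", "tau"),
    "associative_2lr_fixedbias": ("eta_pos", "eta_neg", "gamma", "w0", "w1",
                                  "sigma", "tau"),
    "associative_competence": ("eta", "gamma", "w0", "w1", "w3",
                               "sigma", "B_choice", "tau"),
    "associative_sigmoid": ("eta", "gamma", "m_sig", "B_sig",
                            "sigma", "B_choice", "tau"),
}

_UNIT_INTERVAL = {"eta", "eta_pos", "eta_neg", "gamma", "w0", "w1", "w_EV", "w3"}


class AssociativeModel:
    """One variant of the associative family, registered under its name."""

    def __init__(self, name: str):
        if name not in _VARIANT_PARAMS:
            raise ValueError(f"unknown associative variant {name!r}")
        self.name = name
        self.fit_param_names: tuple[str, ...] = _VARIANT_PARAMS[name]
        self._two_lr = "2lr" in name
        self._expectation = name == "associative_2lr_expectation"
        self._fixed_bias = name == "associative_2lr_fixedbias"
        self._competence = name == "associative_competence"
        self._sigmoid = name == "associative_sigmoid"

    # -- parameter plumbing -------------------------------------------------

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.fit_param_names)

    def params_from_fit_dict(self, d: dict) -> AssocParams:
        extra = set(d) - set(self.fit_param_names)
        if extra:
            raise ParameterError(f"{self.name}: unknown parameters {sorted(extra)}")
        p = AssocParams(**d)
        return dataclasses.replace(p, B_choice=0.0) if self._fixed_bias else p

    def params_to_dict(self, params: AssocParams) -> dict:
        return {n: getattr(params, n) for n in self.fit_param_names}

    def params_from_vector(self, v: Sequence[float]) -> AssocParams:
        return self.params_from_fit_dict(dict(zip(self.fit_param_names, v)))

    def params_to_vector(self, params: AssocParams) -> list[float]:
        return [getattr(params, n) for n in self.fit_param_names]

    def validate_params(self, params: AssocParams) -> None:
        problems = []
        for n in self.fit_param_names:
            v = getattr(params, n)
            if n in _UNIT_INTERVAL and not 0.0 <= v <= 1.0:
                problems.append(f"{n}={v} outside [0, 1]")
            elif n in ("tau", "m_sig") and v <= 0:
                problems.append(f"{n}={v} must be > 0")
            elif n == "sigma" and v < 0:
                problems.append(f"sigma={v} must be >= 0")
        if self._fixed_bias and params.B_choice != 0.0:
            problems.append("B_choice is pinned to 0 in the fixed-bias variant")
        if problems:
            raise ParameterError(f"{self.name}: " + "; ".join(problems))

    # -- forward pass -------------------------------------------------------

    def _run(self, p: AssocParams, sched: TaskSchedule,
             predictions=None, ratings=None, rng=None):
        """Single forward pass over the schedule.

        With observed ``predictions``/``ratings``: accumulates the two
        log-likelihood streams.  With ``rng``: samples missing predictions
        and ratings.  Returns (predictions, ratings, choice_probs,
        se_means, ll_choice, ll_se).
        """
        n_groups = sched.n_groups
        esv = [INITIAL_ESV] * n_groups
        x_spe = x_ev = x_cpe = 0.0
        gamma = p.gamma
        inv_tau = 1.0 / p.tau
        bc = 0.0 if self._fixed_bias else p.B_choice
        ll_choice = 0.0
        ll_se = 0.0
        out_pred: list[int] = []
        out_rat: list[float | None] = []
        cps: list[float] = []
        means: list[float] = []
        sample = rng is not None

        for t in range(sched.n_trials):
            g = sched.group[t] - 1
            o = sched.outcome[t]
            e = esv[g]
            cp = _expit((2.0 * e - 1.0 + bc) * inv_tau)
            cps.append(cp)
            if predictions is not None:
                pred = predictions[t]
            else:
                pred = 1 if rng.random() < cp else 0
            out_pred.append(pred)
            ll_choice += log(cp if pred == 1 else 1.0 - cp)

            if o is not None:
                d = o - e
                x_spe = gamma * x_spe + d
                if self._expectation:
                    x_ev = gamma * x_ev + e  # pre-update expectation
                if self._competence:
                    q_a = e if pred == 1 else 1.0 - e
                    x_cpe = gamma * x_cpe + ((1.0 if pred == o else 0.0) - q_a)
                if self._two_lr:
                    lr = p.eta_pos if d > 0 else p.eta_neg if d < 0 else 0.0
                else:
                    lr = p.eta
                esv[g] = e + lr * d
            else:
                # no-feedback trial: the trial counter advances, so the
                # leaky sums decay, but nothing is learned
                x_spe *= gamma
                x_ev *= gamma
                x_cpe *= gamma

            if sched.probe_after[t]:
                if self._sigmoid:
                    mean = _expit((x_spe + p.B_sig) * p.m_sig)
                elif self._competence:
                    mean = p.w0 + p.w1 * (p.w3 * x_spe + (1.0 - p.w3) * x_cpe)
                else:
                    mean = p.w0 + p.w1 * x_spe
                    if self._expectation:
                        mean += p.w_EV * x_ev
                means.append(mean)
                if ratings is not None and ratings[t] is not None:
                    r = _clamp(ratings[t])
                    z = (r - mean) / p.sigma
                    ll_se += -0.5 * _LOG_2PI - log(p.sigma) - 0.5 * z * z
                    out_rat.append(ratings[t])
                elif sample:
                    out_rat.append(_clamp(mean + p.sigma * rng.standard_normal()))
                else:
                    out_rat.append(None)
            else:
                out_rat.append(None)

        return out_pred, out_rat, cps, means, ll_choice, ll_se

    # -- public surface -----------------------------------------------------

    def simulate(self, params: AssocParams, schedule: TaskSchedule, rng):
        preds, rats, *_ = self._run(params, schedule, rng=rng)
        return preds, rats

    def loglik(self, params: AssocParams, record: ParticipantRecord):
        """(choice log-likelihood, rating log-density) at fixed parameters."""
        if params.sigma <= 0:
            raise ParameterError("sigma must be > 0 for likelihood evaluation")
        *_, llc, lls = self._run(params, record.schedule,
                                 predictions=record.predictions,
                                 ratings=record.se_rating)
        return llc, lls

    def expected_se(self, params: AssocParams, record: ParticipantRecord) -> np.ndarray:
        """Deterministic expected rating at each probe (the noiseless trajectory)."""
        _, _, _, means, _, _ = self._run(params, record.schedule,
                                         predictions=record.predictions)
        return np.asarray(means)

    def choice_probs(self, params: AssocParams, record: ParticipantRecord) -> np.ndarray:
        _, _, cps, *_ = self._run(params, record.schedule,
                                  predictions=record.predictions)
        return np.asarray(cps)


for _name in _VARIANT_PARAMS:
    register(AssociativeModel(_name))
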