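"""Beta-belief model: leaky beliefs about groups and a self "momentum of approval".

The learner holds a beta distribution Beta(alpha_g, beta_g) over each rater
group's approval probability, with alpha/beta acting as approval and
disapproval pseudo-counts ("1 in 4 people will like me" is alpha=1,
beta=3).  Beliefs leak toward the uninformative (1, 1) each trial,

    alpha' = (1 - lambda_acc) * alpha + lambda_acc      (same for beta),

modelling limited working memory, and are then incremented by the outcome
o in {0, 1} for the encountered group only (alpha += o, beta += 1 - o).
Initial group alphas interpolate linearly between alpha0_min (least
accepting group) and alpha0_max (most accepting), with every group's total
count fixed at n0 = 2 + 1/lambda_acc so that the notional data behind the
prior matches the amount retained at steady state.

The prediction error on a feedback trial is delta = o - alpha'/n' (primed
= post-decay, pre-increment values).  Positive and negative errors are
accumulated separately, with leak varsigma and gain w, into a second
beta-belief about the *momentum* of approval -- how fast one's approval is
currently improving or worsening:

    alpha_S <- (alpha_S - 1) * varsigma + 1 + w * max(delta, 0)
    beta_S  <- (beta_S  - 1) * varsigma + 1 + w * max(-delta, 0)

(both pseudo-counts thus never drop below 1).  A momentary self-esteem
rating is generated by drawing P_acc ~ Beta(alpha_S, beta_S) and passing it
through the sigmoid readout

    SE = 1 / (1 + ((1 - P_acc) / (P_acc * B_se))^m_se),

equivalently logit(SE) = m_se * (logit(P_acc) + ln B_se): an affine map in
log-odds space with sensitivity m_se and baseline bias B_se.  Because the
map is strictly monotone, the rating likelihood is the exact pushforward of
the beta density through it (change of variables), not a Monte-Carlo
approximation.  Approval predictions use a sigmoid in the group's expected
approval probability G_acc = alpha/n, centred on the indifference point
0.5, with positivity bias B_choice and temperature T.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import exp, lgamma, log, log1p
from typing import Sequence

import numpy as np

from . import config
from .errors import ParameterError
from .registry import register
from .task import ParticipantRecord, TaskSchedule

__all__ = [
    "BeliefParams",
    "BeliefState",
    "BeliefModel",
    "beta_counts",
    "init_beliefs",
    "decay_group_beliefs",
    "group_pe",
    "update_group_beliefs",
    "update_self_belief",
    "choice_prob_belief",
    "se_readout",
    "inverse_readout",
    "se_rating_logdensity",
    "expected_se",
    "initial_p_acc",
]

_CLAMP_LO, _CLAMP_HI = config.RATING_CLAMP


def _expit(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + exp(-x))
    e = exp(x)
    return e / (1.0 + e)


def _log_expit(x: float) -> float:
    """log(sigmoid(x)), stable for large |x|."""
    if x >= 0.0:
        return -log1p(exp(-x))
    return x - log1p(exp(x))


def _logit(p: float) -> float:
    return log(p) - log1p(-p)


def _betaln(a: float, b: float) -> float:
    return lgamma(a) + lgamma(b) - lgamma(a + b)


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeliefParams:
    """Free parameters of the belief model (9 fitted quantities).

    The total initial pseudo-count n0 is not free: n0 = 2 + 1/lambda_acc.
    The printed equations use one symbol for both choice and readout bias
    (and sensitivity); here they are disambiguated as B_choice/T (choice)
    vs B_se/m_se (readout).
    """

    lambda_acc: float = 0.2   # group-belief decay coefficient, (0, 1]
    alpha0_min: float = 1.5   # initial alpha of the least accepting group
    alpha0_max: float = 5.0   # initial alpha of the most accepting group
    w: float = 1.0            # prediction-error gain on the self-belief
    varsigma: float = 0.8     # self-belief decay per feedback trial, (0, 1]
    m_se: float = 1.0         # readout sensitivity (> 0)
    B_se: float = 1.0         # readout baseline bias (> 0, multiplicative)
    T: float = 0.15           # decision temperature (> 0)
    B_choice: float = 0.0     # positivity bias on predicting approval

    @property
    def n0(self) -> float:
        """Initial total pseudo-count per group, tied to the decay rate."""
        return 2.0 + 1.0 / self.lambda_acc


@dataclass
class BeliefState:
    """Per-group beta-beliefs plus the self momentum belief.

    Invariant: every alpha and beta stays >= 1 under decay and updates.
    """

    alpha: list[float]
    beta: list[float]
    alpha_s: float = 1.0
    beta_s: float = 1.0

    @property
    def n(self) -> list[float]:
        return [a + b for a, b in zip(self.alpha, self.beta)]

    def copy(self) -> "BeliefState":
        return BeliefState(list(self.alpha), list(self.beta), self.alpha_s, self.beta_s)


def beta_counts(n_approve: int, n_total: int) -> tuple[int, int]:
    """Map a frequency belief ("k in n people will like me") to beta
    pseudo-counts (alpha, beta) = (k, n - k)."""
    if not 0 <= n_approve <= n_total:
        raise ValueError("need 0 <= n_approve <= n_total")
    return n_approve, n_total - n_approve


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def init_beliefs(params: BeliefParams, n_groups: int) -> BeliefState:
    """Initial state: group alphas interpolated from alpha0_min to
    alpha0_max, every total count at n0 = 2 + 1/lambda_acc; the self-belief
    starts at the uniform (1, 1), the fixed point of its decay."""
    if n_groups < 2:
        raise ParameterError("belief model requires n_groups >= 2")
    n0 = params.n0
    if params.alpha0_max > n0 - 1.0 + 1e-12:
        raise ParameterError(
            f"alpha0_max={params.alpha0_max} > n0 - 1 = {n0 - 1.0:.4g}; "
            "the most accepting group's beta would drop below 1")
    span = params.alpha0_max - params.alpha0_min
    alpha = [params.alpha0_min + (m - 1) * span / (n_groups - 1)
             for m in range(1, n_groups + 1)]
    beta = [n0 - a for a in alpha]
    return BeliefState(alpha, beta)


def decay_group_beliefs(state: BeliefState, params: BeliefParams) -> BeliefState:
    """Shrink every group's pseudo-counts toward 1 by factor (1 - lambda_acc)."""
    lam = params.lambda_acc
    out = state.copy()
    out.alpha = [(1.0 - lam) * a + lam for a in state.alpha]
    out.beta = [(1.0 - lam) * b + lam for b in state.beta]
    return out


def group_pe(state: BeliefState, group: int, outcome: int) -> float:
    """Prediction error delta = o - alpha'/n' for the encountered group
    (0-based), computed on the post-decay, pre-increment state."""
    a = state.alpha[group]
    n = a + state.beta[group]
    return outcome - a / n


def update_group_beliefs(state: BeliefState, group: int,
                         outcome: int | None) -> BeliefState:
    """Increment the encountered group's counts by the outcome; a None
    outcome (no feedback) leaves counts unchanged."""
    out = state.copy()
    if outcome is not None:
        out.alpha[group] += outcome
        out.beta[group] += 1 - outcome
    return out


def update_self_belief(state: BeliefState, delta: float,
                       params: BeliefParams) -> BeliefState:
    """Leaky-accumulate the signed prediction error into the momentum belief.

    Approvals (delta > 0) feed alpha_S, disapprovals feed beta_S.  With
    ``config.LITERAL_SELF_UPDATE`` both lines take max(delta, 0), the form
    the source equations print.
    """
    vs = params.varsigma
    dpos = delta if delta > 0.0 else 0.0
    dneg = dpos if config.LITERAL_SELF_UPDATE else (-delta if delta < 0.0 else 0.0)
    out = state.copy()
    out.alpha_s = (state.alpha_s - 1.0) * vs + 1.0 + params.w * dpos
    out.beta_s = (state.beta_s - 1.0) * vs + 1.0 + params.w * dneg
    return out


def choice_prob_belief(state: BeliefState, group: int,
                       params: BeliefParams) -> float:
    """Probability of predicting approval: sigmoid of the group's expected
    approval probability, centred on the 0.5 indifference point (the
    ``config.LITERAL_CHOICE_RULE`` switch restores the uncentred printed
    form)."""
    if params.T <= 0:
        raise ParameterError("T must be > 0")
    a = state.alpha[group]
    g_acc = a / (a + state.beta[group])
    centre = 0.0 if config.LITERAL_CHOICE_RULE else 0.5
    return _expit((g_acc - centre + params.B_choice) / params.T)


def initial_p_acc(state: BeliefState) -> float:
    """Pooled initial approval expectation sum(alpha_i) / sum(n_i), used to
    set the initial point of the expected self-esteem trajectory."""
    return sum(state.alpha) / sum(state.n)


# ---------------------------------------------------------------------------
# Sigmoid readout and rating likelihood
# ---------------------------------------------------------------------------

def se_readout(p_acc: float, params: BeliefParams) -> float:
    """Self-esteem readout SE = 1/(1 + ((1 - p)/(p * B_se))^m_se).

    Monotone in p_acc; equals 0.5 where p_acc * B_se = 1 - p_acc; reduces
    to the identity for B_se = 1, m_se = 1.
    """
    if params.B_se <= 0 or params.m_se <= 0:
        raise ParameterError("B_se and m_se must be > 0")
    p = min(max(p_acc, _CLAMP_LO), _CLAMP_HI)
    return _expit(params.m_se * (_logit(p) + log(params.B_se)))


def inverse_readout(rating: float, params: BeliefParams) -> float:
    """Inverse of :func:`se_readout`: the P_acc that produces the rating."""
    r = min(max(rating, _CLAMP_LO), _CLAMP_HI)
    return _expit(_logit(r) / params.m_se - log(params.B_se))


def se_rating_logdensity(rating: float, alpha_s: float, beta_s: float,
                         params: BeliefParams) -> float:
    """Log density of an observed rating under the pushforward of
    Beta(alpha_s, beta_s) through the sigmoid readout.

    Change of variables: with z = logit(r)/m_se - ln(B_se) and
    p = sigmoid(z), the density is Beta_pdf(p) * dp/dr, which simplifies to
    exp(alpha_s * log sigmoid(z) + beta_s * log sigmoid(-z)
        - B(alpha_s, beta_s)) / (m_se * r * (1 - r)).
    """
    if params.B_se <= 0 or params.m_se <= 0:
        raise ParameterError("B_se and m_se must be > 0")
    # guard only exact endpoints: the density must stay the exact
    # pushforward on (0,1) (it integrates to 1 there)
    r = min(max(rating, 1e-15), 1.0 - 1e-15)
    z = _logit(r) / params.m_se - log(params.B_se)
    return (alpha_s * _log_expit(z) + beta_s * _log_expit(-z)
            - _betaln(alpha_s, beta_s)
            - log(params.m_se) - log(r) - log1p(-r))


_QUAD_NODES, _QUAD_WEIGHTS = np.polynomial.legendre.leggauss(256)
_QUAD_X = 0.5 * (_QUAD_NODES + 1.0)       # map [-1,1] -> (0,1)
_QUAD_W = 0.5 * _QUAD_WEIGHTS


def expected_se(alpha_s: float, beta_s: float, params: BeliefParams) -> float:
    """Mean rating under the pushforward distribution, by Gauss-Legendre
    quadrature over the beta density (the smooth expected-SE trajectory)."""
    x = _QUAD_X
    log_pdf = ((alpha_s - 1.0) * np.log(x) + (beta_s - 1.0) * np.log1p(-x)
               - _betaln(alpha_s, beta_s))
    se = 1.0 / (1.0 + np.exp(-params.m_se * (np.log(x) - np.log1p(-x)
                                             + log(params.B_se))))
    return float(np.sum(_QUAD_W * np.exp(log_pdf) * se))


# ---------------------------------------------------------------------------
# Model class
# ---------------------------------------------------------------------------

_FIT_NAMES = ("lambda_acc", "a0_lo_u", "a0_span_u", "w", "varsigma",
              "m_se", "B_se", "T", "B_choice")


class BeliefModel:
    """The belief model, registered as "belief".

    Fitting coordinates replace (alpha0_min, alpha0_max) by unit-interval
    coordinates (a0_lo_u, a0_span_u): alpha0_min = 1 + a0_lo_u * (n0 - 2)
    and alpha0_max = alpha0_min + a0_span_u * (n0 - 1 - alpha0_min), which
    keeps every initial pseudo-count >= 1 for any lambda_acc.
    """

    name = "belief"
    fit_param_names = _FIT_NAMES

    @property
    def k(self) -> int:
        return len(self.fit_param_names)

    # -- parameter plumbing -------------------------------------------------

    def params_from_fit_dict(self, d: dict) -> BeliefParams:
        d = dict(d)
        lam = d["lambda_acc"]
        n0 = 2.0 + 1.0 / lam
        lo_u = d.pop("a0_lo_u")
        span_u = d.pop("a0_span_u")
        a_min = 1.0 + lo_u * (n0 - 2.0)
        a_max = a_min + span_u * ((n0 - 1.0) - a_min)
        return BeliefParams(alpha0_min=a_min, alpha0_max=a_max, **d)

    def params_to_dict(self, params: BeliefParams) -> dict:
        return dataclasses.asdict(params)

    def params_from_vector(self, v: Sequence[float]) -> BeliefParams:
        return self.params_from_fit_dict(dict(zip(self.fit_param_names, v)))

    def params_to_vector(self, params: BeliefParams) -> list[float]:
        n0 = params.n0
        lo_u = (params.alpha0_min - 1.0) / (n0 - 2.0)
        denom = (n0 - 1.0) - params.alpha0_min
        span_u = (params.alpha0_max - params.alpha0_min) / denom if denom > 1e-12 else 0.0
        vals = {"lambda_acc": params.lambda_acc, "a0_lo_u": lo_u,
                "a0_span_u": span_u, "w": params.w, "varsigma": params.varsigma,
                "m_se": params.m_se, "B_se": params.B_se, "T": params.T,
                "B_choice": params.B_choice}
        return [vals[n] for n in self.fit_param_names]

    def validate_params(self, params: BeliefParams) -> None:
        problems = []
        if not 0.0 < params.lambda_acc <= 1.0:
            problems.append(f"lambda_acc={params.lambda_acc} outside (0, 1]")
        if not 0.0 < params.varsigma <= 1.0:
            problems.append(f"varsigma={params.varsigma} outside (0, 1]")
        if params.alpha0_min < 1.0:
            problems.append(f"alpha0_min={params.alpha0_min} < 1")
        if params.alpha0_max < params.alpha0_min:
            problems.append("alpha0_max < alpha0_min")
        if 0.0 < params.lambda_acc <= 1.0 and params.alpha0_max > params.n0 - 1.0 + 1e-12:
            problems.append(
                f"alpha0_max={params.alpha0_max} > n0 - 1 = {params.n0 - 1.0:.4g}")
        if params.w < 0:
            problems.append(f"w={params.w} must be >= 0")
        for nme in ("m_se", "B_se", "T"):
            if getattr(params, nme) <= 0:
                problems.append(f"{nme} must be > 0")
        if problems:
            raise ParameterError("belief: " + "; ".join(problems))

    # -- forward pass -------------------------------------------------------

    def _run(self, p: BeliefParams, sched: TaskSchedule,
             predictions=None, ratings=None, rng=None):
        """One pass: decay -> choice -> prediction error (primed values) ->
        count update -> self-belief update -> readout at probes."""
        n_groups = max(sched.n_groups, 2)
        state = init_beliefs(p, n_groups)
        alpha, beta = state.alpha, state.beta
        a_s, b_s = state.alpha_s, state.beta_s
        lam = p.lambda_acc
        keep = 1.0 - lam
        vs = p.varsigma
        w = p.w
        inv_t = 1.0 / p.T
        centre = 0.0 if config.LITERAL_CHOICE_RULE else 0.5
        bc = p.B_choice
        literal_self = config.LITERAL_SELF_UPDATE
        log_bse = log(p.B_se)
        m_se = p.m_se
        ll_choice = 0.0
        ll_se = 0.0
        lbeta_cache_key = None
        out_pred: list[int] = []
        out_rat: list[float | None] = []
        cps: list[float] = []
        se_beliefs: list[tuple[float, float]] = []
        sample = rng is not None

        for t in range(sched.n_trials):
            # leaky decay of every group belief
            for g in range(n_groups):
                alpha[g] = keep * alpha[g] + lam
                beta[g] = keep * beta[g] + lam

            g = sched.group[t] - 1
            o = sched.outcome[t]
            a_p = alpha[g]
            n_p = a_p + beta[g]
            g_acc = a_p / n_p
            cp = _expit((g_acc - centre + bc) * inv_t)
            cps.append(cp)
            if predictions is not None:
                pred = predictions[t]
            else:
                pred = 1 if rng.random() < cp else 0
            out_pred.append(pred)
            ll_choice += log(cp if pred == 1 else 1.0 - cp)

            if o is not None:
                delta = o - g_acc
                alpha[g] = a_p + o
                beta[g] = beta[g] + 1 - o
                dpos = delta if delta > 0.0 else 0.0
                dneg = dpos if literal_self else (-delta if delta < 0.0 else 0.0)
                a_s = (a_s - 1.0) * vs + 1.0 + w * dpos
                b_s = (b_s - 1.0) * vs + 1.0 + w * dneg
            else:
                # no-feedback trial: beliefs (including the self momentum)
                # keep leaking, no evidence arrives
                a_s = (a_s - 1.0) * vs + 1.0
                b_s = (b_s - 1.0) * vs + 1.0

            if sched.probe_after[t]:
                se_beliefs.append((a_s, b_s))
                if ratings is not None and ratings[t] is not None:
                    r = ratings[t]
                    r = _CLAMP_LO if r < _CLAMP_LO else _CLAMP_HI if r > _CLAMP_HI else r
                    z = _logit(r) / m_se - log_bse
                    if lbeta_cache_key != (a_s, b_s):
                        lbeta_cache_key = (a_s, b_s)
                        lbeta = _betaln(a_s, b_s)
                    ll_se += (a_s * _log_expit(z) + b_s * _log_expit(-z) - lbeta
                              - log(m_se) - log(r) - log1p(-r))
                    out_rat.append(ratings[t])
                elif sample:
                    draw = rng.beta(a_s, b_s)
                    r = se_readout(draw, p)
                    out_rat.append(
                        _CLAMP_LO if r < _CLAMP_LO else _CLAMP_HI if r > _CLAMP_HI else r)
                else:
                    out_rat.append(None)
            else:
                out_rat.append(None)

        return out_pred, out_rat, cps, se_beliefs, ll_choice, ll_se

    # -- public surface -----------------------------------------------------

    def simulate(self, params: BeliefParams, schedule: TaskSchedule, rng):
        preds, rats, *_ = self._run(params, schedule, rng=rng)
        return preds, rats

    def loglik_slow(self, params: BeliefParams, record: ParticipantRecord):
        """Trial-stepped likelihood (reference path; the vectorized
        :meth:`loglik_fn` is checked against it)."""
        *_, llc, lls = self._run(params, record.schedule,
                                 predictions=record.predictions,
                                 ratings=record.se_rating)
        return llc, lls

    def loglik_fn(self, record: ParticipantRecord):
        """Pre-compile the record into arrays and return a fast
        ``params -> (ll_choice, ll_se)`` closure.

        Because the group and self beliefs evolve independently of the
        participant's responses, both leaky accumulations are linear
        recursions and evaluate as IIR filters over the whole session.
        """
        from scipy.signal import lfilter
        from scipy.special import gammaln, log_expit

        sched = record.schedule
        n_groups = max(sched.n_groups, 2)
        groups = np.asarray(sched.group) - 1
        fb = np.array([o is not None for o in sched.outcome])
        o = np.array([0 if v is None else v for v in sched.outcome], dtype=float)
        probe_idx = np.asarray(sched.probe_trials, dtype=int)
        pred1 = np.asarray(record.predictions) == 1
        r = np.clip([record.se_rating[t] for t in probe_idx], _CLAMP_LO, _CLAMP_HI)
        logit_r = np.log(r) - np.log1p(-r)
        log_r_sum = np.sum(np.log(r) + np.log1p(-r))
        enc = [(groups == g) & fb for g in range(n_groups)]
        cue = [groups == g for g in range(n_groups)]
        u_a = [np.where(e, o, 0.0) for e in enc]
        u_b = [np.where(e, 1.0 - o, 0.0) for e in enc]
        ones = np.ones(1)

        def fn(p: BeliefParams):
            lam = p.lambda_acc
            keep = 1.0 - lam
            a_iir = np.array([1.0, -keep])
            span = p.alpha0_max - p.alpha0_min
            g_acc = np.empty(len(groups))
            n0 = p.n0
            for g in range(n_groups):
                a0 = p.alpha0_min + g * span / (n_groups - 1)
                b0 = n0 - a0
                a = lfilter(ones, a_iir, u_a[g] + lam, zi=np.array([keep * a0]))[0]
                b = lfilter(ones, a_iir, u_b[g] + lam, zi=np.array([keep * b0]))[0]
                a_p = a - u_a[g]  # post-decay, pre-increment (primed) counts
                b_p = b - u_b[g]
                sel = cue[g]
                g_acc[sel] = (a_p[sel] / (a_p[sel] + b_p[sel]))
            delta = np.where(fb, o - g_acc, 0.0)
            dpos = np.maximum(delta, 0.0)
            dneg = dpos if config.LITERAL_SELF_UPDATE else np.maximum(-delta, 0.0)
            s_iir = np.array([1.0, -p.varsigma])
            a_s = 1.0 + lfilter(ones, s_iir, p.w * dpos)[probe_idx]
            b_s = 1.0 + lfilter(ones, s_iir, p.w * dneg)[probe_idx]

            centre = 0.0 if config.LITERAL_CHOICE_RULE else 0.5
            x = (g_acc - centre + p.B_choice) / p.T
            ll_choice = float(np.sum(np.where(pred1, log_expit(x), log_expit(-x))))

            z = logit_r / p.m_se - log(p.B_se)
            ll_se = float(np.sum(
                a_s * log_expit(z) + b_s * log_expit(-z)
                - (gammaln(a_s) + gammaln(b_s) - gammaln(a_s + b_s))
            ) - len(r) * log(p.m_se) - log_r_sum)
            return ll_choice, ll_se

        return fn

    def loglik(self, params: BeliefParams, record: ParticipantRecord):
        """(choice log-likelihood, rating log-density) at fixed parameters."""
        return self.loglik_fn(record)(params)

    def expected_se(self, params: BeliefParams,
                    record: ParticipantRecord) -> np.ndarray:
        """Expected rating at each probe: the beta-belief pushed through the
        readout, integrated by quadrature."""
        _, _, _, se_beliefs, _, _ = self._run(params, record.schedule,
                                              predictions=record.predictions)
        return np.asarray([expected_se(a, b, params) for a, b in se_beliefs])

    def choice_probs(self, params: BeliefParams,
                     record: ParticipantRecord) -> np.ndarray:
        _, _, cps, *_ = self._run(params, record.schedule,
                                  predictions=record.predictions)
        return np.asarray(cps)

    def se_belief_trajectory(self, params: BeliefParams,
                             record: ParticipantRecord) -> list[tuple[float, float]]:
        """Per-probe (alpha_S, beta_S) of the momentum belief."""
        _, _, _, se_beliefs, _, _ = self._run(params, record.schedule,
                                              predictions=record.predictions)
        return se_beliefs


register(BeliefModel())
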