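"""Shared configuration: task design constants, parameter bounds, generation ranges.

All fitting bounds and synthetic-cohort generation ranges live here so they
can be revised in one place.  Bounds are the box constraints used by the
fitter (optimisation itself runs in an unconstrained logit-transformed
space); generation ranges are the narrower, behaviourally plausible
intervals from which synthetic-participant parameters are drawn for
recovery studies (see docs/methods.md).
"""

from __future__ import annotations

# Ratings live on the open unit interval; densities on (0,1) diverge at the
# bounds, so observed and simulated ratings are clamped to this range.
RATING_CLAMP: tuple[float, float] = (1e-4, 1.0 - 1e-4)

# Social-evaluation task design: four rater groups whose approval
# probabilities straddle 50% symmetrically, so that overall feedback is
# half approvals and half disapprovals.
DEFAULT_APPROVAL_RATES: tuple[float, ...] = (0.15, 0.30, 0.70, 0.85)
DISCOVERY_RATERS_PER_GROUP: tuple[int, ...] = (48, 48, 48, 48)  # 192 raters
TEST_SAMPLE_RATERS_PER_GROUP: tuple[int, ...] = (46, 46, 46, 46)  # 184 raters
N_NO_FEEDBACK_SCANNER: int = 24  # extra no-feedback trials in scanned sessions
FIRST_PROBE_AFTER: int = 2  # first self-esteem probe after trial 2
PROBE_GAPS: tuple[int, ...] = (2, 3)  # inter-probe gaps drawn from this set

# Multi-start maximum likelihood: number of starting points for the
# quasi-Newton minimiser (midpoint + scrambled low-discrepancy design).
DEFAULT_N_STARTS: int = 129
# Documented fast mode for large recovery batches (see docs/methods.md).
FAST_N_STARTS: int = 12

# Literal-form switches for two printed equations whose implemented form
# differs from the printed one (see docs/methods.md "Equation conventions").
# When True the printed forms are used instead.
LITERAL_SELF_UPDATE: bool = False   # beta-line of the self-belief update
LITERAL_CHOICE_RULE: bool = False   # omit the -0.5 centering in the belief choice rule

# Box constraints per parameter name, shared by every model that uses the
# parameter.  u-suffixed names are unit-interval coordinates for the belief
# model's initial-belief interpolation (see belief.BeliefModel).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    # learning rates, decays and [0,1] weights
    "eta": (1e-3, 1 - 1e-3),
    "eta_pos": (1e-3, 1 - 1e-3),
    "eta_neg": (1e-3, 1 - 1e-3),
    "gamma": (1e-3, 1 - 1e-3),
    "w0": (1e-3, 1 - 1e-3),
    "w1": (1e-3, 1 - 1e-3),
    "w_EV": (1e-3, 1 - 1e-3),
    "w3": (1e-3, 1 - 1e-3),
    "lambda_acc": (1e-3, 1 - 1e-3),
    "varsigma": (1e-3, 1 - 1e-3),
    "a0_lo_u": (1e-3, 1 - 1e-3),
    "a0_span_u": (1e-3, 1 - 1e-3),
    # positive scale parameters
    "sigma": (1e-3, 20.0),
    "tau": (1e-3, 20.0),
    "T": (1e-3, 20.0),
    "m_sig": (1e-3, 20.0),
    "m_se": (1e-3, 20.0),
    "w": (1e-3, 20.0),
    # additive biases
    "B_choice": (-1.0, 1.0),
    "B_sig": (-1.0, 1.0),
    # multiplicative readout bias
    "B_se": (1e-2, 100.0),
}

# Generation ranges for synthetic recovery cohorts.  For parameters whose
# natural scale is the unit interval these are the interior 10-90% of the
# fitting bound; for scale parameters (noise SDs, temperatures,
# sensitivities) the fitting bounds are deliberately loose, so generation
# uses behaviourally plausible intervals instead -- drawing sigma or tau
# uniformly up to 20 on a [0,1] rating scale would produce cohorts carrying
# no information about the dynamic parameters of interest.
GENERATION_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "associative": {
        "eta": (0.1, 0.9),
        "gamma": (0.1, 0.9),
        "w0": (0.1, 0.9),
        "w1": (0.1, 0.9),
        "sigma": (0.05, 0.2),
        "B_choice": (-0.8, 0.8),
        "tau": (0.1, 0.4),
    },
    "associative_2lr": {
        "eta_pos": (0.1, 0.9),
        "eta_neg": (0.1, 0.9),
        "gamma": (0.1, 0.9),
        "w0": (0.1, 0.9),
        "w1": (0.1, 0.9),
        "sigma": (0.05, 0.2),
        "B_choice": (-0.8, 0.8),
        "tau": (0.1, 0.4),
    },
    "associative_sigmoid": {
        "eta": (0.1, 0.9),
        "gamma": (0.1, 0.9),
        "m_sig": (0.5, 3.0),
        "B_sig": (-0.8, 0.8),
        "sigma": (0.05, 0.2),
        "B_choice": (-0.8, 0.8),
        "tau": (0.1, 0.4),
    },
    "belief": {
        "lambda_acc": (0.1, 0.5),
        "a0_lo_u": (0.05, 0.35),
        "a0_span_u": (0.4, 0.9),
        "w": (0.5, 3.0),
        "varsigma": (0.5, 0.95),
        "m_se": (0.8, 3.0),
        "B_se": (0.5, 2.5),
        "T": (0.08, 0.3),
        "B_choice": (-0.2, 0.2),
    },
}


# Joint constraints on generation draws.  The Gaussian-readout associative
# variants are only self-consistent generators while their rating mean stays
# on the [0,1] scale: the leaky PE sum is bounded by 1/(1-gamma), so draws
# with w1 > 1 - gamma routinely emit means outside the scale and produce
# rating piles at the clamp bounds that the (un-censored) Gaussian
# likelihood cannot represent.  Such degenerate generators are excluded by
# rejection sampling, mirroring the exclusion of unidentifiable belief
# configurations from the belief generation ranges.
def _swing_on_scale(draw: dict) -> bool:
    return draw["w1"] <= 1.0 - draw["gamma"]


GENERATION_CONSTRAINTS: dict[str, object] = {
    "associative": _swing_on_scale,
    "associative_2lr": _swing_on_scale,
}


def bounds_for(names: tuple[str, ...],
               override: dict[str, tuple[float, float]] | None = None,
               ) -> list[tuple[float, float]]:
    """Box bounds for an ordered tuple of fit-parameter names."""
    src = dict(PARAM_BOUNDS)
    if override:
        src.update(override)
    missing = [n for n in names if n not in src]
    if missing:
        raise KeyError(f"no bounds declared for parameters: {missing}")
    return [src[n] for n in names]
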