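"""Cohort-level model comparison and the parameter/model recovery harness.

Comparison tables aggregate per-participant BIC as sum, mean and median,
with per-model deltas against a reference model (the belief model by
convention, when present).  Recovery closes the loop on the pipeline:
cohorts are simulated from known parameters, re-fitted, and scored by rank
correlation (parameter recovery) or by a confusion matrix of generating
versus BIC-winning model (model recovery).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .inference import FitResult, FitSpec, fit_participant
from .registry import get_model
from .task import ParticipantRecord

__all__ = [
    "ComparisonTable",
    "RecoveryReport",
    "compare",
    "parameter_recovery",
    "model_recovery",
    "plot_bic_scatter",
    "plot_trajectory",
]


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Cohort summary: per-participant BIC matrix plus aggregate columns."""

    per_participant: pd.DataFrame  # index participant, columns model -> BIC
    summary: pd.DataFrame          # index model, aggregate columns
    reference: str

    @property
    def winner(self) -> str:
        """Model with the lowest sum BIC."""
        return self.summary["sum_bic"].idxmin()

    def scatter_data(self, candidate: str) -> pd.DataFrame:
        """Per-participant (reference BIC, candidate BIC) pairs."""
        return pd.DataFrame({
            "reference_bic": self.per_participant[self.reference],
            "candidate_bic": self.per_participant[candidate],
        })

    def to_text(self) -> str:
        lines = [f"Model comparison (reference: {self.reference}; lower BIC is better)",
                 self.summary.round(2).to_string()]
        return "\n".join(lines)


def compare(fits: Iterable[FitResult], reference: str | None = None) -> ComparisonTable:
    """Aggregate a full participants x models grid of fits.

    Every participant must be fitted by every model; gaps are an error
    listing the missing cells.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    models = sorted({f.model for f in fits})
    participants = sorted({f.participant_id for f in fits}, key=str)
    cell = {(f.participant_id, f.model): f for f in fits}
    missing = [(p, m) for p in participants for m in models if (p, m) not in cell]
    if missing:
        raise ValueError(f"missing (participant, model) fits: {missing}")

    bic_mat = pd.DataFrame(
        {m: [cell[(p, m)].bic for p in participants] for m in models},
        index=pd.Index(participants, name="participant_id"))

    if reference is None:
        reference = "belief" if "belief" in models else models[0]
    if reference not in models:
        raise ValueError(f"reference model {reference!r} not among fits {models}")

    rows = {}
    for m in models:
        llc = np.array([cell[(p, m)].loglik_choice for p in participants])
        lls = np.array([cell[(p, m)].logdens_se for p in participants])
        col = bic_mat[m]
        rows[m] = {
            "sum_bic": col.sum(),
            "mean_bic": col.mean(),
            "median_bic": col.median(),
            "sum_ll_choice": llc.sum(),
            "median_ll_choice": float(np.median(llc)),
            "sum_ll_se": lls.sum(),
            "median_ll_se": float(np.median(lls)),
            "delta_sum_bic": (bic_mat[reference] - col).sum(),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "model"
    return ComparisonTable(bic_mat, summary, reference)


# ---------------------------------------------------------------------------
# Recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Scores from re-fitting synthetic cohorts with known ground truth."""

    generating: pd.DataFrame = field(default_factory=pd.DataFrame)
    recovered: pd.DataFrame = field(default_factory=pd.DataFrame)
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)  # rho/bias/rmse per param
    confusion: pd.DataFrame | None = None  # generating model x winning model
    fits: list = field(default_factory=list)

    def rho(self, param: str) -> float:
        return float(self.scores.loc[param, "rho"])


def _generating_frame(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        gp = rec.meta.get("generating_params")
        if gp is None:
            raise ValueError(
                f"participant {rec.participant_id}: no generating params in meta")
        rows.append({"participant_id": rec.participant_id, **gp})
    return pd.DataFrame(rows).set_index("participant_id")


def parameter_recovery(model: str, cohort: Sequence[ParticipantRecord],
                       spec: FitSpec | None = None) -> RecoveryReport:
    """Refit a cohort simulated with stored parameters; score each shared
    parameter by Spearman rank correlation, mean bias and RMSE."""
    spec = spec or FitSpec(model=model)
    if spec.model != model:
        spec = dataclasses.replace(spec, model=model)
    gen = _generating_frame(cohort)
    fits = [fit_participant(spec, rec) for rec in cohort]
    rec_df = pd.DataFrame(
        [{"participant_id": f.participant_id, **f.params_hat} for f in fits]
    ).set_index("participant_id")

    scores = {}
    for name in gen.columns.intersection(rec_df.columns):
        g = gen[name].to_numpy(dtype=float)
        r = rec_df[name].to_numpy(dtype=float)
        if np.ptp(g) == 0:  # parameter held fixed in generation
            rho = np.nan
        else:
            rho = spearmanr(g, r).statistic
        scores[name] = {"rho": rho,
                        "bias": float(np.mean(r - g)),
                        "rmse": float(np.sqrt(np.mean((r - g) ** 2)))}
    score_df = pd.DataFrame.from_dict(scores, orient="index")
    score_df.index.name = "parameter"
    return RecoveryReport(gen, rec_df, score_df, None, fits)


def model_recovery(models: Sequence[str],
                   cohorts_per_model: Mapping[str, Sequence[ParticipantRecord]],
                   spec: FitSpec | None = None) -> RecoveryReport:
    """Fit every cohort under every candidate model and tabulate the
    confusion matrix of generating model versus BIC winner (rows sum to the
    cohort sizes)."""
    base = spec or FitSpec(model=models[0])
    counts = pd.DataFrame(0, index=pd.Index(models, name="generating"),
                          columns=pd.Index(models, name="winner"))
    all_fits = []
    for gen_model in models:
        cohort = cohorts_per_model[gen_model]
        for rec in cohort:
            results = {}
            for cand in models:
                f = fit_participant(dataclasses.replace(base, model=cand), rec)
                results[cand] = f
                all_fits.append(f)
            winner = min(results, key=lambda m: results[m].bic)
            counts.loc[gen_model, winner] += 1
    return RecoveryReport(confusion=counts, fits=all_fits)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_bic_scatter(table: ComparisonTable, candidates: Sequence[str], path) -> None:
    """Per-participant BIC of each candidate against the reference model,
    with the identity line marking equal fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ref = table.per_participant[table.reference]
    for cand in candidates:
        ax.scatter(ref, table.per_participant[cand], s=14, alpha=0.7, label=cand)
    lims = [table.per_participant.min().min(), table.per_participant.max().max()]
    ax.plot(lims, lims, "k-", lw=0.8)
    ax.set_xlabel(f"BIC ({table.reference})")
    ax.set_ylabel("BIC (candidate)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(model: str, params, record: ParticipantRecord, path) -> None:
    """Observed ratings, the model's expected-SE curve and its choice
    probabilities across the session."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mod = get_model(model)
    probes = np.asarray(record.schedule.probe_trials) + 1
    observed = np.asarray(record.ratings, dtype=float)
    expected = mod.expected_se(params, record)
    cps = mod.choice_probs(params, record)

    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(probes, observed, "o", ms=4, color="0.3", label="observed SE")
    ax.plot(probes, expected, "-", color="C0", label="expected SE")
    ax.plot(np.arange(1, record.schedule.n_trials + 1), cps, "-", lw=0.8,
            color="C3", alpha=0.7, label="P(predict approve)")
    ax.set_xlabel("trial")
    ax.set_ylabel("rating / probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
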