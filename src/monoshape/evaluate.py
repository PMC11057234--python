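"""Trial-level evaluation: dissimilarity summaries, cumulative
distributions, per-slant means and slant correlations."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family import dissimilarity

__all__ = ["TrialResult", "SummaryTable", "evaluate_trials", "results_frame"]


@dataclass
class TrialResult:
    trial_id: int
    object_type: str
    projection: str
    slant_true_deg: float
    slant_model_deg: float
    slant_response_deg: float = float("nan")

    @property
    def condition(self) -> str:
        return f"{self.object_type}/{self.projection}"

    @property
    def dissim_model_truth(self) -> float:
        return dissimilarity(self.slant_true_deg, self.slant_model_deg)

    @property
    def dissim_model_response(self) -> float:
        if math.isnan(self.slant_response_deg):
            return float("nan")
        return dissimilarity(self.slant_response_deg, self.slant_model_deg)


def results_frame(results: list[TrialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in results],
            "condition": [r.condition for r in results],
            "object_type": [r.object_type for r in results],
            "projection": [r.projection for r in results],
            "slant_true_deg": [r.slant_true_deg for r in results],
            "slant_model_deg": [r.slant_model_deg for r in results],
            "slant_response_deg": [r.slant_response_deg for r in results],
            "dissim_model_truth": [r.dissim_model_truth for r in results],
            "dissim_model_response": [r.dissim_model_response for r in results],
        }
    )


@dataclass
class SummaryTable:
    """Per-condition summaries. ``cumulative`` maps a condition to the
    (sorted |dissimilarity|, empirical CDF) samples; medians are the 50th
    percentiles of those values by linear interpolation."""

    per_condition: pd.DataFrame
    per_slant: pd.DataFrame
    cumulative: dict[str, tuple[np.ndarray, np.ndarray]]
    correlations: pd.DataFrame


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_trials(results: list[TrialResult]) -> SummaryTable:
    """Summaries of model-vs-truth (and, when responses are present,
    model-vs-response) dissimilarities, per condition."""
    if not results:
        raise ValueError("no trial results to evaluate")
    df = results_frame(results)
    rows, corr_rows, cumulative = [], [], {}
    for cond, grp in df.groupby("condition"):
        if len(grp) == 0:
            warnings.warn(f"empty condition {cond!r} omitted", stacklevel=2)
            continue
        ad = np.sort(np.abs(grp["dissim_model_truth"].to_numpy()))
        ecdf = np.arange(1, len(ad) + 1) / len(ad)
        cumulative[cond] = (ad, ecdf)
        row = {
            "condition": cond,
            "n": len(grp),
            "median_abs_dissim_truth": float(np.percentile(np.abs(grp["dissim_model_truth"]), 50)),
            "mean_dissim_truth": float(grp["dissim_model_truth"].mean()),
        }
        has_resp = np.isfinite(grp["slant_response_deg"]).any()
        if has_resp:
            dmr = grp["dissim_model_response"].dropna()
            row["median_abs_dissim_response"] = float(np.percentile(np.abs(dmr), 50))
        rows.append(row)
        corr = {
            "condition": cond,
            "r_model_truth": _pearson(
                grp["slant_true_deg"].to_numpy(), grp["slant_model_deg"].to_numpy()
            ),
        }
        if has_resp:
            mask = np.isfinite(grp["slant_response_deg"])
            corr["r_model_response"] = _pearson(
                grp.loc[mask, "slant_response_deg"].to_numpy(),
                grp.loc[mask, "slant_model_deg"].to_numpy(),
            )
            corr["r_response_truth"] = _pearson(
                grp.loc[mask, "slant_response_deg"].to_numpy(),
                grp.loc[mask, "slant_true_deg"].to_numpy(),
            )
        if np.isnan(corr["r_model_truth"]):
            corr["undefined"] = True
        corr_rows.append(corr)
    per_slant = (
        df.groupby(["condition", "slant_true_deg"])["dissim_model_truth"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_dissim", "count": "n"})
    )
    return SummaryTable(
        per_condition=pd.DataFrame(rows),
        per_slant=per_slant,
        cumulative=cumulative,
        correlations=pd.DataFrame(corr_rows),
    )
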