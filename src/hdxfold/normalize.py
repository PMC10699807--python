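"""Uptake normalization and multi-condition time-axis merging.

Centroid uptake values are corrected in a fixed order that makes the
maximally-labeled endpoint exact:

1. subtract the in-exchange control (label picked up in quench),
2. divide by the deuterium fraction of the labeling solution,
3. rescale so the maximally-labeled (full-D) control maps to the number of
   exchange-competent residues (back-exchange correction).

Measurements taken under a slower labeling condition are mapped onto the
reference condition's time axis by dividing their labeling times by the
intrinsic-rate ratio between the two conditions (the EX2 assumption: observed
rates scale with k_chem, so equal products k_chem * t give equal uptake).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem_rates import ExchangeConditions, condition_time_factor
from .hdx_io import ControlSet, PeptideRecord, StateData, exchangeable_count

__all__ = [
    "UptakeCurve",
    "EX2ConsistencyWarning",
    "d_fraction_correct",
    "back_exchange_correct",
    "merge_time_axes",
    "normalize_state_data",
]


class EX2ConsistencyWarning(UserWarning):
    """Merged dual-condition uptake values disagree beyond pooled noise."""


@dataclass
class UptakeCurve:
    """A peptide's replicate-averaged time course on the reference time axis."""

    peptide: PeptideRecord
    state: str
    times: np.ndarray  # s, strictly increasing, reference-condition axis
    uptake: np.ndarray  # mean uptake per time, Da
    sd: np.ndarray  # replicate SD per time, Da (0 where single replicate)
    n_exchangeable: int
    d_fraction_applied: bool = False
    back_exchange_applied: bool = False
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.uptake = np.asarray(self.uptake, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def percent_d(self) -> np.ndarray:
        """Derived %D view: uptake over the exchange-competent residue count."""
        return 100.0 * self.uptake / self.n_exchangeable


def d_fraction_correct(uptake_da, cond: ExchangeConditions):
    """Divide uptake by the labeling solution's deuterium fraction."""
    return np.asarray(uptake_da, dtype=float) / cond.d_fraction


def back_exchange_correct(
    uptake_da,
    controls: ControlSet,
    n_exchangeable: int,
    d_fraction: float = 1.0,
    control_d_fraction: float | None = None,
):
    """Map uptake onto [0, n_exchangeable] using the peptide's controls.

    The in-exchange centroid is subtracted first; the result is divided by the
    labeling deuterium fraction and rescaled so the full-D control lands
    exactly on ``n_exchangeable``.  ``control_d_fraction`` is the deuterium
    fraction under which the controls themselves were labeled (defaults to
    ``d_fraction``), which matters when a cosolute dilutes the labeling
    buffer relative to the control buffer.
    """
    if control_d_fraction is None:
        control_d_fraction = d_fraction
    span = controls.full_d - controls.in_exchange
    if span <= 0:
        raise ValueError(
            "degenerate controls: full-D centroid must exceed in-exchange centroid"
        )
    u = (np.asarray(uptake_da, dtype=float) - controls.in_exchange) / d_fraction
    frac = u / (span / control_d_fraction)  # fraction of the maximal label
    return frac * n_exchangeable * d_fraction


def merge_time_axes(
    points: pd.DataFrame,
    factors: dict[str, float],
    rel_window: float = 0.05,
) -> pd.DataFrame:
    """Merge per-condition time courses onto one effective time axis.

    ``points`` needs columns ``condition``, ``time_s``, ``uptake_da`` (one row
    per replicate measurement); ``factors`` maps each condition label to its
    intrinsic-rate ratio relative to the reference (1.0 for the reference
    itself; > 1 for faster reference).  Effective time = time_s / factor.
    Effective times agreeing within ``rel_window`` (relative) are averaged
    with propagated SD; cross-condition disagreement beyond 3 pooled SD
    raises an :class:`EX2ConsistencyWarning` (exchange may deviate from EX2).
    """
    for cond in points["condition"].unique():
        if cond not in factors:
            raise ValueError(f"no time factor supplied for condition {cond!r}")
        if factors[cond] <= 0:
            raise ValueError("time factors must be positive")
    pts = points.copy()
    pts["t_eff"] = pts["time_s"] / pts["condition"].map(factors)
    pts = pts.sort_values("t_eff").reset_index(drop=True)

    # group effective times within the relative window
    group_ids = np.zeros(len(pts), dtype=int)
    gid = 0
    for i in range(1, len(pts)):
        if pts.loc[i, "t_eff"] > pts.loc[i - 1, "t_eff"] * (1 + rel_window):
            gid += 1
        group_ids[i] = gid
    pts["group"] = group_ids

    rows = []
    for _, grp in pts.groupby("group"):
        mean_u = grp["uptake_da"].mean()
        sd_u = grp["uptake_da"].std(ddof=1) if len(grp) > 1 else 0.0
        if grp["condition"].nunique() > 1:
            by_cond = grp.groupby("condition")["uptake_da"].agg(["mean", "std", "count"])
            rep_vars = by_cond.loc[by_cond["count"] > 1, "std"] ** 2
            pooled = float(np.sqrt(rep_vars.mean())) if len(rep_vars) else np.nan
            if not np.isfinite(pooled) or pooled == 0:
                pooled = max(sd_u, 0.06)  # fall back to replicate-level repeatability
            spread = by_cond["mean"].max() - by_cond["mean"].min()
            if spread > 3 * pooled:
                warnings.warn(
                    f"dual-condition uptake disagrees by {spread:.3f} Da "
                    f"(> 3 x pooled SD {pooled:.3f}) at effective time "
                    f"{grp['t_eff'].mean():.3g} s: exchange may not be EX2",
                    EX2ConsistencyWarning,
                    stacklevel=2,
                )
        rows.append(
            {"t_eff": grp["t_eff"].mean(), "uptake_da": mean_u, "sd": sd_u, "n_obs": len(grp)}
        )
    return pd.DataFrame(rows)


def normalize_state_data(
    data: StateData,
    conditions: dict[str, ExchangeConditions],
    reference_condition: str,
    sequences: dict[str, str],
    apply_back_exchange: bool = True,
) -> dict[tuple[str, str], UptakeCurve]:
    """Produce merged, corrected uptake curves for every (peptide, state).

    Returns a dict keyed by ``(peptide_name, state)``.  Peptides lacking a
    control set are normalized by d-fraction only (flagged in ``notes``).
    """
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} not defined")
    ref = conditions[reference_condition]
    factors = {
        label: (
            1.0
            if label == reference_condition
            else condition_time_factor(ref, cond, sequences[next(iter(sequences))])
        )
        for label, cond in conditions.items()
    }

    curves: dict[tuple[str, str], UptakeCurve] = {}
    pep_by_span = {(p.start, p.end): p for p in data.peptides}
    for (start, end, state), grp in data.measurements.groupby(["start", "end", "state"]):
        peptide = pep_by_span[(int(start), int(end))]
        n_ex = exchangeable_count(peptide)
        controls = data.controls.get((int(start), int(end)))
        notes: list[str] = []

        grp = grp.copy()
        if apply_back_exchange and controls is not None:
            corrected = []
            for _, row in grp.iterrows():
                cond = conditions[row["condition"]]
                val = back_exchange_correct(
                    row["uptake_da"],
                    controls,
                    n_ex,
                    d_fraction=cond.d_fraction,
                    control_d_fraction=ref.d_fraction,
                )
                corrected.append(float(d_fraction_correct(val, cond)))
            # replicate noise on controls can push corrected values slightly
            # outside the physical range; clip to [0, n_exchangeable]
            grp["uptake_da"] = np.clip(corrected, 0.0, n_ex)
            bx_applied = True
            d_applied = True
            notes.append("in-exchange subtracted; d-fraction and back-exchange corrected")
        else:
            if apply_back_exchange and controls is None:
                notes.append("no control set: back-exchange correction skipped")
            grp["uptake_da"] = [
                float(d_fraction_correct(row["uptake_da"], conditions[row["condition"]]))
                for _, row in grp.iterrows()
            ]
            bx_applied = False
            d_applied = True
            notes.append("d-fraction corrected")

        merged = merge_time_axes(grp, factors)
        curves[(peptide.name, str(state))] = UptakeCurve(
            peptide=peptide,
            state=str(state),
            times=merged["t_eff"].to_numpy(),
            uptake=merged["uptake_da"].to_numpy(),
            sd=merged["sd"].to_numpy(),
            n_exchangeable=n_ex,
            d_fraction_applied=d_applied,
            back_exchange_applied=bx_applied,
            notes=notes,
        )
    return curves


def display_curve(curve: UptakeCurve) -> UptakeCurve:
    """Display-grade copy of a corrected curve (no back-exchange rescaling).

    Only meaningful when built alongside :func:`normalize_state_data` with
    ``apply_back_exchange=False``; provided so callers can carry both views.
    """
    return replace(curve)
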