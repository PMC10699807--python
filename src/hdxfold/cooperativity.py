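"""Fraying-directed residue rate assignment and the sigma_dG cooperativity statistic.

Helices unfold preferentially from their ends ("fraying"), so within a
peptide the residues nearest the frayed terminus exchange fastest.  The
fitted exchange rates of a peptide are therefore mapped onto its
exchange-competent residues in order of distance from the fraying end.  When
a residue sits on the boundary between two rate classes and cannot be
assigned a single rate, the geometric mean of the candidate rates is used.

Per-residue stability follows ``dG = -R T ln(k_chem / k_i - 1)`` and the
cooperativity statistic ``sigma_dG`` is the sample standard deviation of the
finite per-residue dG values: zero for a fully cooperative unit (all residues
share one opening equilibrium), large for a frayed helix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import R_KCAL, T_REF

__all__ = [
    "HelixAnnotation",
    "amplitude_block_assignment",
    "ResidueStability",
    "CooperativityResult",
    "read_helix_table",
    "assign_rates",
    "residue_delta_g",
    "sigma_delta_g",
    "classify_sigma",
    "peptide_cooperativity",
    "UnprotectedResidueWarning",
]

#: Default classification thresholds on sigma_dG, kcal/mol.
SIGMA_COOPERATIVE = 0.5
SIGMA_FRAYING = 1.5


class UnprotectedResidueWarning(UserWarning):
    """A residue's assigned rate reached k_chem; its dG is undefined."""


@dataclass(frozen=True)
class HelixAnnotation:
    """A helix span with the terminus that frays first.

    ``fraying_end`` is ``"N"`` or ``"C"``: the terminus nearest the binding
    site / solvent, where unfolding begins and exchange is fastest.
    """

    helix_id: str
    start: int
    end: int
    fraying_end: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 3:
            raise ValueError(f"helix {self.helix_id}: span must be >= 3 residues")
        if self.fraying_end not in ("N", "C"):
            raise ValueError("fraying_end must be 'N' or 'C'")


@dataclass(frozen=True)
class ResidueStability:
    residue_index: int
    rate: float  # assigned exchange rate, s^-1
    k_chem: float  # intrinsic rate, s^-1
    protection_factor: float  # k_chem / rate
    delta_g: float  # kcal/mol; NaN when PF <= 1

    @property
    def protected(self) -> bool:
        return math.isfinite(self.delta_g)


@dataclass
class CooperativityResult:
    peptide_name: str
    residues: list[ResidueStability]
    sigma_dg: float  # kcal/mol
    classification: str
    n_unprotected: int = 0


def read_helix_table(path) -> list[HelixAnnotation]:
    """Read a delimited helix annotation table: helix, start, end, fraying_end."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return [
        HelixAnnotation(str(r["helix"]), int(r["start"]), int(r["end"]),
                        str(r["fraying_end"]).upper())
        for _, r in df.iterrows()
    ]


def assign_rates(m: int, rates, direction: str = "N") -> np.ndarray:
    """Spread ``n`` fitted rates over ``m`` residues by fraying order.

    ``rates`` must be sorted fastest to slowest.  Residues are ordered from
    the fraying end inward and partitioned into ``n`` contiguous blocks of
    ``m // n`` residues sharing one rate; the ``m mod n`` leftover residues
    sit on block boundaries (nearest the fraying end first) and take the
    geometric mean ``(k_i * k_i * k_{i+1})**(1/3)`` of the flanking block's
    rate (doubled) and the next rate.  The returned array is in peptide
    order (N to C): for ``direction == "C"`` the ladder is reversed.
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if n < 1 or n > m:
        raise ValueError(f"need 1 <= n_rates <= m ({n} rates, {m} residues)")
    if np.any(np.diff(rates) > 0):
        raise ValueError("rates must be sorted fastest to slowest")
    if direction not in ("N", "C"):
        raise ValueError("direction must be 'N' or 'C'")

    block = m // n
    leftover = m - block * n  # placed at the first `leftover` block boundaries
    out: list[float] = []
    for i in range(n):
        out.extend([rates[i]] * block)
        if i < leftover:  # boundary residue between block i and block i+1
            out.append(float((rates[i] * rates[i] * rates[i + 1]) ** (1.0 / 3.0)))
    out_arr = np.asarray(out)
    assert out_arr.size == m
    return out_arr if direction == "N" else out_arr[::-1]


def amplitude_block_assignment(
    m: int, rates, amplitudes, direction: str = "N"
) -> np.ndarray:
    """Spread rates over residues with block sizes taken from fit amplitudes.

    When a multi-exponential fit supplies amplitude estimates, each rate
    class carries ``a_i / sum(a) * m`` residues; block sizes are the largest-
    remainder rounding of those shares and blocks are laid out contiguously
    from the fraying end (fastest class first).  With equal amplitudes and
    ``n | m`` this coincides with :func:`assign_rates`.  Classes rounded to
    zero residues are dropped.
    """
    rates = np.asarray(rates, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if rates.shape != amplitudes.shape:
        raise ValueError("rates and amplitudes must align")
    if np.any(np.diff(rates) > 0):
        raise ValueError("rates must be sorted fastest to slowest")
    share = amplitudes / amplitudes.sum() * m
    counts = np.floor(share).astype(int)
    remainder = share - counts
    for i in np.argsort(-remainder)[: m - counts.sum()]:
        counts[i] += 1
    out = np.repeat(rates, counts)
    return out if direction == "N" else out[::-1]


def residue_delta_g(rate: float, k_chem: float, temperature: float = T_REF) -> float:
    """Per-residue free energy of unfolding, ``-R T ln(k_chem / k - 1)``.

    Requires protection (``rate < k_chem``); at PF = 2 the opening
    equilibrium is balanced and dG = 0.  Unprotected residues (PF <= 1) have
    no defined dG: NaN is returned with an :class:`UnprotectedResidueWarning`.
    """
    if rate <= 0 or k_chem <= 0:
        raise ValueError("rates must be positive")
    pf = k_chem / rate
    if pf <= 1.0:
        warnings.warn(
            f"assigned rate {rate:.3g} >= k_chem {k_chem:.3g}: unprotected residue, "
            "dG undefined",
            UnprotectedResidueWarning,
            stacklevel=2,
        )
        return math.nan
    return -R_KCAL * temperature * math.log(pf - 1.0)


def classify_sigma(
    sigma: float,
    cooperative_below: float = SIGMA_COOPERATIVE,
    fraying_above: float = SIGMA_FRAYING,
) -> str:
    if sigma < cooperative_below:
        return "cooperative"
    if sigma <= fraying_above:
        return "mildly cooperative"
    return "fraying"


def sigma_delta_g(delta_gs, **thresholds) -> tuple[float, str]:
    """Sample (n-1) standard deviation of finite per-residue dG values.

    Non-finite entries (unprotected residues) are excluded; at least two
    finite values are required.
    """
    dg = np.asarray(delta_gs, dtype=float)
    dg = dg[np.isfinite(dg)]
    if dg.size < 2:
        raise ValueError("sigma_dG needs >= 2 residues with finite dG")
    sigma = float(np.std(dg, ddof=1))
    return sigma, classify_sigma(sigma, **thresholds)


def peptide_cooperativity(
    peptide_name: str,
    residue_indices,
    rates,
    k_chem,
    fraying_end: str = "N",
    temperature: float = T_REF,
    amplitudes=None,
    **thresholds,
) -> CooperativityResult:
    """Assign fitted rates to a peptide's residues and compute sigma_dG.

    ``residue_indices`` are the protein coordinates of the exchange-competent
    residues in N-to-C order; ``k_chem`` is a scalar or a matching array of
    intrinsic rates; ``rates`` are the fitted exchange rates sorted fastest
    to slowest.  When the fit also provides ``amplitudes``, block sizes come
    from :func:`amplitude_block_assignment`; otherwise the equal-block
    geometric-mean scheme of :func:`assign_rates` is used.
    """
    residue_indices = list(residue_indices)
    m = len(residue_indices)
    if amplitudes is not None:
        assigned = amplitude_block_assignment(m, rates, amplitudes, direction=fraying_end)
    else:
        assigned = assign_rates(m, rates, direction=fraying_end)
    k_chem_arr = np.broadcast_to(np.asarray(k_chem, dtype=float), (m,))

    residues: list[ResidueStability] = []
    n_unprotected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnprotectedResidueWarning)
        for idx, k, kc in zip(residue_indices, assigned, k_chem_arr):
            dg = residue_delta_g(float(k), float(kc), temperature)
            if not math.isfinite(dg):
                n_unprotected += 1
            residues.append(
                ResidueStability(
                    residue_index=int(idx),
                    rate=float(k),
                    k_chem=float(kc),
                    protection_factor=float(kc / k),
                    delta_g=dg,
                )
            )
    if n_unprotected:
        warnings.warn(
            f"{peptide_name}: {n_unprotected} unprotected residue(s) excluded from sigma_dG",
            UnprotectedResidueWarning,
            stacklevel=2,
        )
    sigma, label = sigma_delta_g([r.delta_g for r in residues], **thresholds)
    return CooperativityResult(
        peptide_name=peptide_name,
        residues=residues,
        sigma_dg=sigma,
        classification=label,
        n_unprotected=n_unprotected,
    )


def cooperativity_report(results: list[CooperativityResult]) -> pd.DataFrame:
    """Flat table of per-peptide sigma_dG and classification."""
    return pd.DataFrame(
        {
            "peptide": [r.peptide_name for r in results],
            "n_residues": [len(r.residues) for r in results],
            "n_unprotected": [r.n_unprotected for r in results],
            "sigma_dg_kcal_mol": [r.sigma_dg for r in results],
            "classification": [r.classification for r in results],
        }
    )
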