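"""Sequence- and condition-dependent intrinsic amide exchange rates.

The intrinsic (chemical) exchange rate ``k_chem`` of a backbone amide in a
fully unstructured chain is modeled, following the standard poly-DL-alanine
reference treatment, as the sum of acid-, base- and water-catalyzed limbs::

    k_chem = k_A * [D+] + k_B * [OD-] + k_W

where each catalytic constant carries log-additive corrections for the side
chains flanking the amide (the residue owning the NH and the preceding
residue), plus terminal corrections for the protonated N-terminal amine and
the C-terminal carboxylate.  Temperature enters through Arrhenius scaling of
the three catalytic constants (activation energies 14, 17 and 19 kcal/mol for
the acid, base and water limbs); the D2O ionization constant is held at its
reference value, so the ionic terms shift with temperature only through the
catalytic constants.  Urea slows chemical exchange; the correction is
log-linear in molarity, anchored at a factor of 0.5 per 4 M.

Rates are returned in s^-1 on the D2O labeling-time axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache

import numpy as np

from .constants import PD_OFFSET, R_KCAL

__all__ = [
    "ExchangeConditions",
    "residue_intrinsic_rate",
    "sequence_intrinsic_rates",
    "mean_intrinsic_rate",
    "tau_chem",
    "condition_time_factor",
    "urea_rate_correction",
    "NoExchangeableAmideError",
]

# Poly-DL-alanine reference catalytic constants for H->D exchange in D2O at
# 293.15 K, log10 units; k_A, k_B in M^-1 min^-1, k_W in min^-1.
_LOG_KA_REF = 1.62
_LOG_KB_REF = 10.05
_LOG_KW_REF = -1.5
_T_PARAM_REF = 293.15  # K
#: D2O autoionization constant (molar scale) at the reference temperature.
PKD = 15.05
#: Arrhenius activation energies, kcal/mol.
EA_ACID, EA_BASE, EA_WATER = 14.0, 17.0, 19.0

_SECONDS_PER_MINUTE = 60.0


class NoExchangeableAmideError(ValueError):
    """Raised when a position carries no exchange-competent amide proton."""


@dataclass(frozen=True)
class ExchangeConditions:
    """One labeling condition.

    Parameters
    ----------
    pD_read : float
        Uncorrected glass-electrode reading of the D2O labeling solution;
        the operative pD is ``pD_read + 0.4``.
    temperature : float
        Labeling temperature in kelvin.
    d_fraction : float
        Final deuterium mole fraction of the labeling solution (0-1].
    urea_molarity : float
        Urea concentration in mol/L (>= 0).
    """

    pD_read: float
    temperature: float = 298.15
    d_fraction: float = 1.0
    urea_molarity: float = 0.0

    def __post_init__(self) -> None:
        if not 2.0 <= self.pD_read <= 10.0:
            raise ValueError(f"pD_read {self.pD_read} outside [2, 10]")
        if not 270.0 <= self.temperature <= 320.0:
            raise ValueError(f"temperature {self.temperature} K outside [270, 320]")
        if not 0.0 < self.d_fraction <= 1.0:
            raise ValueError(f"d_fraction {self.d_fraction} outside (0, 1]")
        if self.urea_molarity < 0.0:
            raise ValueError("urea_molarity must be >= 0")

    @property
    def pD(self) -> float:
        return self.pD_read + PD_OFFSET


@lru_cache(maxsize=1)
def _load_factors() -> dict[str, tuple[float, float, float, float]]:
    """Load the side-chain log10 correction table shipped with the package."""
    table: dict[str, tuple[float, float, float, float]] = {}
    text = (
        resources.files("hdxfold.data")
        .joinpath("intrinsic_rate_factors.tsv")
        .read_text()
    )
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        res, *vals = line.split("\t")
        table[res] = tuple(float(v) for v in vals)  # type: ignore[assignment]
    return table


def _arrhenius(ea_kcal: float, temperature: float) -> float:
    return math.exp(-ea_kcal / R_KCAL * (1.0 / temperature - 1.0 / _T_PARAM_REF))


def urea_rate_correction(rate: float, urea_molarity: float) -> float:
    """Slow a chemical exchange rate for the presence of urea.

    Log-linear in molarity and anchored at a factor of 0.5 at 4 M, i.e.
    ``rate * 0.5 ** (urea_molarity / 4)``.
    """
    if urea_molarity < 0:
        raise ValueError("urea_molarity must be >= 0")
    return rate * 0.5 ** (urea_molarity / 4.0)


def residue_intrinsic_rate(sequence: str, index: int, cond: ExchangeConditions) -> float:
    """Intrinsic exchange rate (s^-1) of the amide of ``sequence[index-1]``.

    ``index`` is 1-based.  The first residue has no backbone amide within
    scope and prolines carry no amide proton; both raise
    :class:`NoExchangeableAmideError`.
    """
    sequence = sequence.upper()
    if index < 2 or index > len(sequence):
        raise NoExchangeableAmideError(
            f"position {index}: no exchangeable amide (valid 2..{len(sequence)})"
        )
    factors = _load_factors()
    self_res = sequence[index - 1]
    prev_res = sequence[index - 2]
    for r in (self_res, prev_res):
        if r not in factors or r in ("N_TERM", "C_TERM"):
            raise ValueError(f"unknown residue letter {r!r}")
    if self_res == "P":
        raise NoExchangeableAmideError(f"position {index}: proline has no amide proton")

    acid_log = factors[prev_res][0] + factors[self_res][1]
    base_log = factors[prev_res][2] + factors[self_res][3]
    if index == 2:  # protonated N-terminal amine perturbs the second amide
        acid_log += factors["N_TERM"][0]
        base_log += factors["N_TERM"][2]
    if index == len(sequence):  # C-terminal carboxylate perturbs its own amide
        acid_log += factors["C_TERM"][1]
        base_log += factors["C_TERM"][3]

    t = cond.temperature
    conc_d = 10.0 ** (-cond.pD)
    conc_od = 10.0 ** (cond.pD - PKD)
    k_a = 10.0 ** (_LOG_KA_REF + acid_log) * _arrhenius(EA_ACID, t) * conc_d
    k_b = 10.0 ** (_LOG_KB_REF + base_log) * _arrhenius(EA_BASE, t) * conc_od
    k_w = 10.0 ** (_LOG_KW_REF + base_log) * _arrhenius(EA_WATER, t)
    k = (k_a + k_b + k_w) / _SECONDS_PER_MINUTE
    return urea_rate_correction(k, cond.urea_molarity)


def sequence_intrinsic_rates(sequence: str, cond: ExchangeConditions) -> np.ndarray:
    """Per-residue k_chem over a whole chain.

    Returns an array of length ``len(sequence)`` with NaN at positions that
    carry no exchangeable amide (position 1 and prolines).
    """
    out = np.full(len(sequence), np.nan)
    for i in range(2, len(sequence) + 1):
        try:
            out[i - 1] = residue_intrinsic_rate(sequence, i, cond)
        except NoExchangeableAmideError:
            continue
    return out


def mean_intrinsic_rate(sequence: str, cond: ExchangeConditions) -> float:
    """Arithmetic mean of per-residue k_chem over exchange-competent residues."""
    rates = sequence_intrinsic_rates(sequence, cond)
    rates = rates[np.isfinite(rates)]
    if rates.size == 0:
        raise NoExchangeableAmideError("sequence has no exchange-competent residues")
    return float(rates.mean())


def tau_chem(sequence: str, cond: ExchangeConditions) -> float:
    """Characteristic chemical-exchange time 1 / mean(k_chem), in seconds."""
    return 1.0 / mean_intrinsic_rate(sequence, cond)


def condition_time_factor(
    cond_a: ExchangeConditions,
    cond_b: ExchangeConditions,
    sequence: str = "A" * 21,
) -> float:
    """Ratio of mean intrinsic rates between two labeling conditions.

    This is the factor by which labeling times measured under ``cond_b`` are
    divided to place them on the ``cond_a`` time axis; it is > 1 when
    ``cond_a`` exchanges faster.  Both conditions must sit in the
    base-catalysis-dominated regime (pD_read >= 5).
    """
    for c in (cond_a, cond_b):
        if c.pD_read < 5.0:
            raise ValueError("condition_time_factor requires pD_read >= 5")
    return mean_intrinsic_rate(sequence, cond_a) / mean_intrinsic_rate(sequence, cond_b)
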