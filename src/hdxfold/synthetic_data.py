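"""Ground-truth EX2 data generation for end-to-end pipeline testing.

The generator emulates the statistical structure of a peptide-level HDX-MS
experiment on a membrane protein measured under two labeling conditions:

* per-residue EX2 exchange, ``D_i(t) = d * (1 - exp(-k_chem_i * t / PF_i))``,
  driven by a per-residue protection-factor landscape;
* an overlapping proteolytic peptide map (mean length ~12 residues, mean
  per-residue redundancy ~4);
* per-peptide back-exchange drawn from a logit-normal distribution matched
  to mean 0.27 / IQR 0.14, and in-exchange matched to mean 0.031 / IQR 0.020;
* Gaussian replicate noise (SD 0.06 Da) on every centroid;
* non-deuterated, in-exchange and maximally-labeled control rows.

Everything is driven by one seeded generator, so outputs are reproducible
bit for bit.  Profiles can include frayed helices (stability increasing
residue by residue away from the frayed end), cooperative units (shared
stability with small jitter), micelle shielding (a uniform apparent-PF
multiplier on unfolded spans) and, optionally, EX1-like spans whose exchange
does not scale with k_chem — useful only for exercising the EX2-consistency
check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit
from scipy.stats import norm

from .chem_rates import ExchangeConditions, sequence_intrinsic_rates
from .constants import R_KCAL, T_REF
from .cooperativity import HelixAnnotation
from .hdx_io import PeptideRecord, exchangeable_positions

__all__ = [
    "GroundTruthProfile",
    "SimulationSpec",
    "cooperativity_study",
    "binding_study",
    "flat_profile",
    "add_fraying_helix",
    "add_cooperative_unit",
    "add_shielding",
    "ligand_linked_profile",
    "linkage_ddg",
    "make_peptide_map",
    "simulate_ex2_uptake",
    "paper_style_conditions",
    "paper_style_timepoints",
]


@dataclass
class GroundTruthProfile:
    """Per-residue ln(protection factor) landscape over a sequence."""

    sequence: str
    ln_pf: np.ndarray
    helices: list[HelixAnnotation] = field(default_factory=list)
    ex1_spans: list[tuple[int, int, float]] = field(default_factory=list)  # start, end, k_open

    def __post_init__(self) -> None:
        self.ln_pf = np.asarray(self.ln_pf, dtype=float)
        if self.ln_pf.size != len(self.sequence):
            raise ValueError("ln_pf must have one entry per residue")
        if not np.all(np.isfinite(self.ln_pf)):
            raise ValueError("ln_pf must be finite everywhere")

    def copy(self) -> "GroundTruthProfile":
        return replace(self, ln_pf=self.ln_pf.copy(), helices=list(self.helices),
                       ex1_spans=list(self.ex1_spans))

    def delta_g(self, temperature: float = T_REF) -> np.ndarray:
        """Per-residue dG via ``-R T ln(PF - 1)`` (NaN where PF <= 1)."""
        pf = np.exp(self.ln_pf)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(pf > 1.0, -R_KCAL * temperature * np.log(pf - 1.0), np.nan)


def flat_profile(sequence: str, ln_pf: float = 0.0) -> GroundTruthProfile:
    return GroundTruthProfile(sequence, np.full(len(sequence), float(ln_pf)))


def add_fraying_helix(
    profile: GroundTruthProfile,
    helix: HelixAnnotation,
    ln_pf_start: float,
    ln_pf_step: float,
) -> GroundTruthProfile:
    """Install a frayed helix: ln PF = start at the fraying end, rising by
    ``ln_pf_step`` per residue inward."""
    out = profile.copy()
    span = np.arange(helix.start - 1, helix.end)
    steps = np.arange(span.size, dtype=float)
    if helix.fraying_end == "C":
        steps = steps[::-1]
    out.ln_pf[span] = ln_pf_start + ln_pf_step * steps
    out.helices.append(helix)
    return out


def add_cooperative_unit(
    profile: GroundTruthProfile,
    start: int,
    end: int,
    ln_pf: float,
    jitter_sd_kcal: float = 0.0,
    rng: np.random.Generator | None = None,
    helix_id: str | None = None,
    temperature: float = T_REF,
) -> GroundTruthProfile:
    """Install a cooperative (foldon-like) unit: one shared stability, with
    optional per-residue jitter given as a dG standard deviation in kcal/mol."""
    out = profile.copy()
    span = np.arange(start - 1, end)
    values = np.full(span.size, float(ln_pf))
    if jitter_sd_kcal > 0:
        if rng is None:
            raise ValueError("jitter requires a seeded Generator")
        values = values + rng.normal(0.0, jitter_sd_kcal / (R_KCAL * temperature), span.size)
    out.ln_pf[span] = values
    if helix_id is not None:
        out.helices.append(HelixAnnotation(helix_id, start, end, "N"))
    return out


def add_shielding(
    profile: GroundTruthProfile, start: int, end: int, factor: float = 100.0
) -> GroundTruthProfile:
    """Micelle shielding: multiply the apparent PF of an unfolded span by a
    constant factor (restricted catalyst access, not structural protection)."""
    if factor < 1:
        raise ValueError("shielding factor must be >= 1")
    out = profile.copy()
    out.ln_pf[start - 1 : end] += np.log(factor)
    return out


def linkage_ddg(kd: float, ligand_conc: float, temperature: float = T_REF) -> float:
    """Thermodynamic-linkage stabilization, ``R T ln(1 + [L]/Kd)`` kcal/mol."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if ligand_conc < 0:
        raise ValueError("ligand concentration must be >= 0")
    return R_KCAL * temperature * np.log1p(ligand_conc / kd)


def ligand_linked_profile(
    apo: GroundTruthProfile,
    kd: float,
    ligand_conc: float,
    site_residues,
    temperature: float = T_REF,
) -> GroundTruthProfile:
    """Stabilize binding-site residues of an apo profile by ligand linkage.

    Each site residue's protection factor is multiplied by ``1 + [L]/Kd``,
    i.e. its stability grows by ``R T ln(1 + [L]/Kd)``.
    """
    ddg = linkage_ddg(kd, ligand_conc, temperature)
    out = apo.copy()
    idx = np.asarray(list(site_residues), dtype=int) - 1
    out.ln_pf[idx] += ddg / (R_KCAL * temperature)
    return out


# ---------------------------------------------------------------------------
# experiment-level statistics

@lru_cache(maxsize=8)
def _logit_normal_params(mean: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a logit-normal matched to a target mean and IQR."""
    z = norm.ppf(0.75)
    grid = np.linspace(-8, 8, 2001)
    dens_base = norm.pdf(grid) * (grid[1] - grid[0])

    def moments(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        m = float(np.sum(expit(mu + sigma * grid) * dens_base))
        q = float(expit(mu + z * sigma) - expit(mu - z * sigma))
        return np.array([m - mean, q - iqr])

    sol = least_squares(moments, x0=[float(logit(mean)), np.log(0.3)], xtol=1e-14)
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    if np.max(np.abs(sol.fun)) > 1e-4:
        raise ValueError(f"could not match logit-normal to mean {mean}, IQR {iqr}")
    return mu, sigma


@dataclass
class SimulationSpec:
    """Study design for a synthetic HDX-MS dataset.

    Defaults reproduce the experimental statistics this generator emulates:
    two labeling conditions (pD_read 7.1 / 25 degC and 6.1 / 0 degC, both at
    93% D), peptide maps of mean length 12.2 with redundancy 4.3, 3
    replicates, replicate SD 0.06 Da, back-exchange mean 0.27 / IQR 0.14 and
    in-exchange mean 0.031 / IQR 0.020.
    """

    seed: int
    conditions: dict[str, ExchangeConditions] = field(
        default_factory=lambda: paper_style_conditions()
    )
    timepoints: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: paper_style_timepoints()
    )
    reference_condition: str = "pD7.1_25C"
    replicates: int = 3
    noise_sd: float = 0.06
    back_exchange_mean: float = 0.27
    back_exchange_iqr: float = 0.14
    in_exchange_mean: float = 0.031
    in_exchange_iqr: float = 0.020
    mean_peptide_length: float = 12.2
    redundancy: float = 4.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("back_exchange_mean", "in_exchange_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reference_condition not in self.conditions:
            raise ValueError("reference_condition missing from conditions")
        for label, ts in self.timepoints.items():
            if label not in self.conditions:
                raise ValueError(f"timepoints given for unknown condition {label!r}")
            if any(t <= 0 for t in ts):
                raise ValueError("labeling times must be positive")


def paper_style_conditions() -> dict[str, ExchangeConditions]:
    return {
        "pD7.1_25C": ExchangeConditions(pD_read=7.1, temperature=298.15, d_fraction=0.93),
        "pD6.1_0C": ExchangeConditions(pD_read=6.1, temperature=273.15, d_fraction=0.93),
    }


def paper_style_timepoints() -> dict[str, tuple[float, ...]]:
    return {
        "pD7.1_25C": (6.0, 10.0, 30.0, 90.0, 300.0, 900.0, 2700.0, 9000.0, 97200.0),
        "pD6.1_0C": (1.0, 10.0, 90.0),
    }


def make_peptide_map(
    sequence: str,
    spec: SimulationSpec | None = None,
    rng: np.random.Generator | None = None,
    protein_id: str = "SYN",
    mean_length: float | None = None,
    redundancy: float | None = None,
    min_length: int = 5,
    max_length: int = 24,
) -> list[PeptideRecord]:
    """Sample a random overlapping proteolytic peptide map.

    Peptide lengths are drawn around ``mean_length`` and starts uniformly;
    peptides are added until the mean per-residue coverage depth reaches the
    requested redundancy.  ``redundancy <= 1`` produces a non-overlapping
    tiling instead.
    """
    if len(sequence) < 30:
        raise ValueError("peptide map needs a sequence of >= 30 residues")
    if spec is not None:
        mean_length = mean_length if mean_length is not None else spec.mean_peptide_length
        redundancy = redundancy if redundancy is not None else spec.redundancy
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if rng is None:
        raise ValueError("supply a SimulationSpec or a seeded Generator")
    mean_length = 12.2 if mean_length is None else mean_length
    redundancy = 4.3 if redundancy is None else redundancy
    L = len(sequence)

    def record(start: int, length: int) -> PeptideRecord:
        end = start + length - 1
        return PeptideRecord(protein_id, start, end, sequence[start - 1 : end])

    if redundancy <= 1.0:
        peptides, pos = [], 1
        step = max(int(round(mean_length)), min_length)
        while pos <= L - min_length + 1:
            length = min(step, L - pos + 1)
            peptides.append(record(pos, length))
            pos += length
        return peptides

    target = redundancy * L
    covered = 0.0
    peptides = []
    seen: set[tuple[int, int]] = set()
    max_iter = int(20 * target / mean_length) + 100
    for _ in range(max_iter):
        if covered >= target:
            break
        length = int(np.clip(round(rng.normal(mean_length, 3.0)), min_length, max_length))
        length = min(length, L)
        start = int(rng.integers(1, L - length + 2))
        if (start, length) in seen:  # each proteolytic species appears once
            continue
        seen.add((start, length))
        peptides.append(record(start, length))
        covered += length
    else:
        warnings.warn(
            f"requested redundancy {redundancy} not reached for length-{L} sequence",
            stacklevel=2,
        )
    return peptides


def _residue_rates(
    profile: GroundTruthProfile, cond: ExchangeConditions
) -> np.ndarray:
    """Observed per-residue exchange rates (s^-1) under EX2, NaN where no amide."""
    k_chem = sequence_intrinsic_rates(profile.sequence, cond)
    pf = np.maximum(np.exp(profile.ln_pf), 1.0)  # PF < 1 simulated as unprotected
    rates = k_chem / pf
    for start, end, k_open in profile.ex1_spans:
        rates[start - 1 : end] = k_open  # EX1-like: opening-limited, no k_chem scaling
    return rates


def simulate_ex2_uptake(
    profiles: dict[str, GroundTruthProfile],
    spec: SimulationSpec,
    peptides: list[PeptideRecord] | None = None,
    protein_id: str = "SYN",
) -> pd.DataFrame:
    """Simulate a full state-data table (labeled rows plus control rows).

    ``profiles`` maps state labels to ground-truth landscapes sharing one
    sequence.  Controls (non-deuterated / in-exchange / maximally labeled)
    are emitted per peptide from the same per-peptide back- and in-exchange
    draws used for the labeled rows, under the reference condition's
    deuterium fraction.  Deterministic given ``spec.seed``.
    """
    sequences = {p.sequence for p in profiles.values()}
    if len(sequences) != 1:
        raise ValueError("all state profiles must share one sequence")
    sequence = sequences.pop()
    rng = np.random.default_rng(spec.seed)
    if peptides is None:
        peptides = make_peptide_map(sequence, spec, rng=rng, protein_id=protein_id)

    mu_bx, sd_bx = _logit_normal_params(spec.back_exchange_mean, spec.back_exchange_iqr)
    mu_in, sd_in = _logit_normal_params(spec.in_exchange_mean, spec.in_exchange_iqr)
    bx = expit(rng.normal(mu_bx, sd_bx, len(peptides)))
    f_in = expit(rng.normal(mu_in, sd_in, len(peptides)))

    rates_by_state = {
        state: {label: _residue_rates(prof, cond) for label, cond in spec.conditions.items()}
        for state, prof in profiles.items()
    }
    d_ref = spec.conditions[spec.reference_condition].d_fraction

    rows: list[dict] = []
    for p_idx, pep in enumerate(peptides):
        competent = np.asarray(exchangeable_positions(pep), dtype=int) - 1
        n_ex = competent.size
        if n_ex == 0:
            continue
        max_ref = n_ex * d_ref
        # control rows (shared across states)
        for row_type, centroid in (
            ("nd", 0.0),
            ("inx", (1.0 - bx[p_idx]) * f_in[p_idx] * max_ref),
            ("fd", (1.0 - bx[p_idx]) * max_ref),
        ):
            noisy = centroid + rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else centroid
            rows.append(
                {
                    "protein": pep.protein_id,
                    "start": pep.start,
                    "end": pep.end,
                    "sequence": pep.sequence,
                    "state": "control",
                    "condition": "control",
                    "row_type": row_type,
                    "time_s": 0.0,
                    "replicate": "ctrl",
                    "uptake_da": max(noisy, 0.0) if row_type != "nd" else 0.0,
                }
            )
        for state in profiles:
            for label, ts in spec.timepoints.items():
                cond = spec.conditions[label]
                k = rates_by_state[state][label][competent]
                max_cond = n_ex * cond.d_fraction
                for t in ts:
                    true = float(np.sum(cond.d_fraction * (1.0 - np.exp(-k * t))))
                    measured = (1.0 - bx[p_idx]) * (
                        true + f_in[p_idx] * (max_cond - true)
                    )
                    for rep in range(spec.replicates):
                        noisy = measured + (
                            rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                        )
                        rows.append(
                            {
                                "protein": pep.protein_id,
                                "start": pep.start,
                                "end": pep.end,
                                "sequence": pep.sequence,
                                "state": state,
                                "condition": label,
                                "row_type": "uptake",
                                "time_s": t,
                                "replicate": f"r{rep + 1}",
                                "uptake_da": max(noisy, 0.0),
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# predefined study designs

#: 60-residue construct: a frayed 7-residue peptide (4 exchange-competent
#: residues, one proline) and a cooperative 10-residue poly-Ala peptide
#: (8 competent residues with identical intrinsic rates).
_COOP_SEQUENCE = (
    "MKTAYIAKQR"  # 1-10 filler
    "LSSPSNS"  # 11-17 frayed helix peptide (fast-exchanging contexts at the fray end)
    "SDVKHWQTFRMIE"  # 18-30 filler
    "AAAAAAAAAA"  # 31-40 cooperative peptide
    "GSTKLVDERWQHNFMIYCLK"  # 41-60 filler
)

_FRAY_SPAN = (11, 17)
_COOP_SPAN = (31, 40)
#: Target observed rates for the 4 frayed residues: evenly log-spaced over
#: five decades, anchored inside the sampled dual-condition time window
#: (effective times 7e-3 .. 1e5 s).
_FRAY_TARGET_RATES = tuple(float(r) for r in 3.0 * 10.0 ** -np.linspace(0, 5, 4))
#: Target observed rate for the cooperative unit (tau ~ 5.5 min).
_COOP_TARGET_RATE = 3e-3
#: dG jitter of the cooperative unit, kcal/mol.
_COOP_JITTER_SD = 0.3


def cooperativity_study(seed: int, noise_sd: float = 0.06):
    """Seeded fixture: one state holding a frayed and a cooperative peptide.

    Returns ``(profiles, spec, peptides, helices, truth)`` where ``truth``
    holds the generating per-residue dG and sigma_dG of both peptides.
    """
    seq = _COOP_SEQUENCE
    spec = SimulationSpec(seed=seed, noise_sd=noise_sd)
    cond_ref = spec.conditions[spec.reference_condition]
    k_chem = sequence_intrinsic_rates(seq, cond_ref)

    profile = flat_profile(seq, ln_pf=8.0)
    fray = HelixAnnotation("H_fray", *_FRAY_SPAN, "N")
    coop = HelixAnnotation("H_coop", *_COOP_SPAN, "N")
    profile.helices.extend([fray, coop])

    pep_fray = PeptideRecord("SYN", _FRAY_SPAN[0], _FRAY_SPAN[1],
                             seq[_FRAY_SPAN[0] - 1 : _FRAY_SPAN[1]])
    pep_coop = PeptideRecord("SYN", _COOP_SPAN[0], _COOP_SPAN[1],
                             seq[_COOP_SPAN[0] - 1 : _COOP_SPAN[1]])

    fray_residues = exchangeable_positions(pep_fray)
    for idx, k_target in zip(fray_residues, _FRAY_TARGET_RATES):
        profile.ln_pf[idx - 1] = np.log(k_chem[idx - 1] / k_target)

    rng = np.random.default_rng(seed + 1)
    coop_residues = exchangeable_positions(pep_coop)
    # variance-exact jitter: the realized per-unit dG dispersion equals the
    # requested jitter SD, so the unit's ground-truth sigma_dG is well defined
    jitter = rng.normal(size=len(coop_residues))
    jitter = (jitter - jitter.mean()) / jitter.std(ddof=1)
    jitter *= _COOP_JITTER_SD / (R_KCAL * T_REF)
    for idx, j in zip(coop_residues, jitter):
        profile.ln_pf[idx - 1] = np.log(k_chem[idx - 1] / _COOP_TARGET_RATE) + j

    dg = profile.delta_g()
    truth = {
        "fray_residues": fray_residues,
        "coop_residues": coop_residues,
        "fray_dg": dg[np.asarray(fray_residues) - 1],
        "coop_dg": dg[np.asarray(coop_residues) - 1],
        "fray_sigma": float(np.std(dg[np.asarray(fray_residues) - 1], ddof=1)),
        "coop_sigma": float(np.std(dg[np.asarray(coop_residues) - 1], ddof=1)),
    }
    profiles = {"Cl": profile}
    return profiles, spec, [pep_fray, pep_coop], [fray, coop], truth


def binding_study(
    seed: int,
    length: int = 220,
    site: tuple[int, int] = (51, 170),
    ddg_kcal: float = 1.8,
    kd_mM: float = 6.0,
    noise_sd: float = 0.06,
):
    """Seeded fixture: apo vs ligand-bound states of a synthetic protein.

    The binding-site span is uniformly stabilized by ``ddg_kcal`` through
    thermodynamic linkage (the ligand concentration is chosen so that
    ``R T ln(1 + [L]/Kd)`` equals the requested ddG).  Returns
    ``(profiles, spec, site_residues, ddg_kcal)``.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ADEFGHIKLMNQRSTVWY"))  # no proline, no cysteine
    seq = "".join(rng.choice(alphabet, size=length))
    spec = SimulationSpec(seed=seed, noise_sd=noise_sd)
    cond_ref = spec.conditions[spec.reference_condition]
    k_chem = sequence_intrinsic_rates(seq, cond_ref)

    # apo landscape: every residue relaxes at ~2e-3 s^-1 (tau ~ 8 min)
    target = 2e-3
    ln_pf = np.where(np.isfinite(k_chem), np.log(np.maximum(k_chem, 1e-30) / target), 8.0)
    apo = GroundTruthProfile(seq, ln_pf)

    site_residues = list(range(site[0], site[1] + 1))
    ligand_conc = kd_mM * (np.exp(ddg_kcal / (R_KCAL * T_REF)) - 1.0)
    bound = ligand_linked_profile(apo, kd_mM, ligand_conc, site_residues)
    return {"apo": apo, "bound": bound}, spec, site_residues, ddg_kcal
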