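"""Differential HDX: uptake-difference matrices, hybrid significance, residue maps.

Significance of a per-peptide, per-time uptake difference is decided by a
hybrid two-criterion test: the absolute difference must exceed a global
threshold derived from pooled replicate noise
(``z_{1-alpha/2} * sqrt(2) * SD_pooled``), and a Welch two-sample t-test on
the replicate means must pass at the same alpha.  Peptide-level ddG values
are aggregated to residues by averaging over all peptides covering the
residue, and residue values can be written into the B-factor column of a
PDB/mmCIF file for structure mapping.
"""

from __future__ import annotations

import math
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

from .hdx_io import PeptideRecord, exchangeable_positions

__all__ = [
    "global_threshold",
    "hybrid_significance",
    "differential_matrix",
    "residue_ddg",
    "write_structure_map",
    "read_structure_bfactors",
]

#: B-factor written for residues absent from the map.
SENTINEL_B = 0.0


def global_threshold(pooled_sd: float, alpha: float = 0.05) -> float:
    """Global significance threshold in Da: ``z_{1-alpha/2} * sqrt(2) * SD``."""
    if pooled_sd <= 0:
        raise ValueError("pooled replicate SD must be positive")
    return float(stats.norm.ppf(1 - alpha / 2) * math.sqrt(2.0) * pooled_sd)


def differential_matrix(
    measurements: pd.DataFrame,
    state_a: str,
    state_b: str,
) -> pd.DataFrame:
    """Per-(peptide, time) replicate summaries for two states.

    ``measurements`` is a long table with columns ``start``, ``end``,
    ``state``, ``time_s``, ``replicate``, ``uptake_da`` (same condition/time
    axis for both states).  Returns one row per cell with replicate means,
    SDs, counts and ``delta_da = mean(B) - mean(A)``.
    """
    rows = []
    sub = measurements[measurements["state"].isin([state_a, state_b])]
    for (start, end, t), grp in sub.groupby(["start", "end", "time_s"]):
        ga = grp[grp["state"] == state_a]["uptake_da"]
        gb = grp[grp["state"] == state_b]["uptake_da"]
        if ga.empty or gb.empty:
            continue
        rows.append(
            {
                "start": int(start),
                "end": int(end),
                "time_s": float(t),
                "mean_a": ga.mean(),
                "mean_b": gb.mean(),
                "sd_a": ga.std(ddof=1) if len(ga) > 1 else np.nan,
                "sd_b": gb.std(ddof=1) if len(gb) > 1 else np.nan,
                "n_a": len(ga),
                "n_b": len(gb),
                "delta_da": gb.mean() - ga.mean(),
            }
        )
    return pd.DataFrame(rows)


def hybrid_significance(
    cells: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Flag significant uptake differences with the hybrid test.

    ``cells`` is the output of :func:`differential_matrix`.  The pooled SD is
    the root-mean-square of all per-cell replicate SDs (cells with >= 2
    replicates in at least one state); with no replicated cells at all the
    threshold is undefined and an error is raised.  A cell is significant iff
    ``|delta| > threshold`` AND a Welch t-test on the two replicate groups
    rejects at ``alpha``.
    """
    variances = np.concatenate(
        [
            cells.loc[cells["n_a"] > 1, "sd_a"].dropna().to_numpy() ** 2,
            cells.loc[cells["n_b"] > 1, "sd_b"].dropna().to_numpy() ** 2,
        ]
    )
    if variances.size == 0:
        raise ValueError("hybrid test undefined: no replicated measurements anywhere")
    pooled_sd = float(np.sqrt(variances.mean()))
    threshold = global_threshold(pooled_sd, alpha)

    out = cells.copy()
    pvals = np.ones(len(out))
    for i, row in enumerate(out.itertuples()):
        sd_a = row.sd_a if np.isfinite(row.sd_a) and row.sd_a > 0 else pooled_sd
        sd_b = row.sd_b if np.isfinite(row.sd_b) and row.sd_b > 0 else pooled_sd
        if row.n_a < 2 and row.n_b < 2:
            continue  # no per-cell test possible; stays non-significant
        res = stats.ttest_ind_from_stats(
            row.mean_a, sd_a, row.n_a, row.mean_b, sd_b, row.n_b, equal_var=False
        )
        pvals[i] = res.pvalue
    out["p_value"] = pvals
    out["significant"] = (np.abs(out["delta_da"]) > threshold) & (out["p_value"] < alpha)
    return out, threshold


def residue_ddg(
    peptide_ddgs: dict[PeptideRecord, float] | list[tuple[PeptideRecord, float]],
) -> pd.DataFrame:
    """Average peptide-level ddG onto residues.

    Each residue's value is the arithmetic mean of the ddG of every peptide
    whose exchange-competent span covers it; uncovered residues are absent.
    Returns a DataFrame indexed by residue with ``ddg`` and ``n_peptides``.
    """
    items = peptide_ddgs.items() if isinstance(peptide_ddgs, dict) else peptide_ddgs
    acc: dict[int, list[float]] = {}
    for peptide, ddg in items:
        if not math.isfinite(ddg):
            continue
        for idx in exchangeable_positions(peptide):
            acc.setdefault(idx, []).append(ddg)
    if not acc:
        return pd.DataFrame(columns=["ddg", "n_peptides"])
    residues = sorted(acc)
    return pd.DataFrame(
        {
            "ddg": [float(np.mean(acc[r])) for r in residues],
            "n_peptides": [len(acc[r]) for r in residues],
        },
        index=pd.Index(residues, name="residue"),
    )


def write_structure_map(
    structure_in: str | Path,
    residue_values: dict[int, float] | pd.Series,
    structure_out: str | Path,
    chains: list[str] | None = None,
    sentinel: float = SENTINEL_B,
) -> list[int]:
    """Write per-residue values into the B-factor column of a structure file.

    Residue numbering must match protein coordinates (author seq ids).
    Residues absent from ``residue_values`` get the ``sentinel`` B-factor.
    Returns the sorted list of map keys that matched no residue in the
    structure so callers can report numbering mismatches.
    """
    if isinstance(residue_values, pd.Series):
        residue_values = {int(k): float(v) for k, v in residue_values.items()}
    st = gemmi.read_structure(str(structure_in))
    st.setup_entities()
    matched: set[int] = set()
    for model in st:
        for chain in model:
            if chains is not None and chain.name not in chains:
                continue
            for residue in chain:
                seqid = residue.seqid.num
                value = residue_values.get(seqid)
                if value is None:
                    b = sentinel
                else:
                    b = value
                    matched.add(seqid)
                for atom in residue:
                    atom.b_iso = b
    out = Path(structure_out)
    if out.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(out))
    else:
        st.write_pdb(str(out))
    return sorted(set(residue_values) - matched)


def read_structure_bfactors(path: str | Path, chain: str | None = None) -> dict[int, float]:
    """Per-residue B-factor (first atom) keyed by author residue number."""
    st = gemmi.read_structure(str(path))
    out: dict[int, float] = {}
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for residue in ch:
                if residue.seqid.num not in out and len(residue) > 0:
                    out[residue.seqid.num] = residue[0].b_iso
        break
    return out
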