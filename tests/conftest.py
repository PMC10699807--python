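import warnings

import numpy as np
import pytest

from hdxfold.chem_rates import ExchangeConditions
from hdxfold.cooperativity import UnprotectedResidueWarning
from hdxfold.hdx_io import read_state_table, write_state_table
from hdxfold.normalize import normalize_state_data
from hdxfold.synthetic_data import cooperativity_study, simulate_ex2_uptake


@pytest.fixture(scope="session")
def fast_condition() -> ExchangeConditions:
    """Reference labeling condition: pD_read 7.1, 25 degC, 93% D."""
    return ExchangeConditions(pD_read=7.1, temperature=298.15, d_fraction=0.93)


@pytest.fixture(scope="session")
def slow_condition() -> ExchangeConditions:
    """Slow labeling condition: pD_read 6.1, 0 degC, 93% D."""
    return ExchangeConditions(pD_read=6.1, temperature=273.15, d_fraction=0.93)


def run_cooperativity_pipeline(seed: int, tmp_path):
    """Simulate the two-peptide fraying/cooperative study and normalize it."""
    profiles, spec, peptides, helices, truth = cooperativity_study(seed=seed)
    table = simulate_ex2_uptake(profiles, spec, peptides=peptides)
    seq = profiles["Cl"].sequence
    path = tmp_path / f"states_{seed}.csv"
    write_state_table(table, path)
    data = read_state_table(path, {"SYN": seq})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnprotectedResidueWarning)
        curves = normalize_state_data(
            data, spec.conditions, spec.reference_condition, {"SYN": seq}
        )
    return data, curves, spec, helices, truth


@pytest.fixture(scope="session")
def coop_dataset(tmp_path_factory):
    """Session-cached simulate->normalize run of the cooperativity study."""
    tmp = tmp_path_factory.mktemp("coop")
    return run_cooperativity_pipeline(1, tmp)


def make_curve(times, uptake, peptide=None, n_exchangeable=None, sd=None,
               state="Cl", back_exchange_applied=True):
    """Build an UptakeCurve around explicit arrays for fit tests."""
    from hdxfold.hdx_io import PeptideRecord
    from hdxfold.normalize import UptakeCurve

    times = np.asarray(times, dtype=float)
    uptake = np.asarray(uptake, dtype=float)
    if peptide is None:
        n = n_exchangeable if n_exchangeable is not None else 4
        peptide = PeptideRecord("SYN", 1, n + 2, "A" * (n + 2))
    if n_exchangeable is None:
        n_exchangeable = peptide.length - 2
    return UptakeCurve(
        peptide=peptide,
        state=state,
        times=times,
        uptake=uptake,
        sd=np.zeros_like(times) if sd is None else np.asarray(sd, dtype=float),
        n_exchangeable=n_exchangeable,
        d_fraction_applied=True,
        back_exchange_applied=back_exchange_applied,
    )
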