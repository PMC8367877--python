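import numpy as np
import pytest

from microthermo import (
    ConformerRecord,
    MicrostateEnsemble,
    SolventEnergies,
    ThermoSettings,
)


@pytest.fixture(scope="session")
def settings():
    return ThermoSettings()


def make_microstate(
    microstate_id: str,
    totals,
    formal_charge: int = 0,
    solvents=("water",),
    mu: float = -5.0,
    source_set: str = "orig",
):
    """Build a microstate whose per-conformer E+mu totals are ``totals``.

    ``totals`` may be a sequence of floats (same totals in every solvent)
    or a dict solvent -> sequence.
    """
    if not isinstance(totals, dict):
        totals = {s: totals for s in solvents}
    n = len(next(iter(totals.values())))
    conformers = []
    for c in range(n):
        terms = {
            s: SolventEnergies(e_sol=vals[c] - mu, mu_ex_corr=mu)
            for s, vals in totals.items()
        }
        conformers.append(
            ConformerRecord(
                conformer_id=f"c{c}",
                microstate_id=microstate_id,
                energy_terms=terms,
                source_set=source_set,
            )
        )
    return MicrostateEnsemble(
        microstate_id=microstate_id,
        formal_charge=formal_charge,
        conformers=tuple(conformers),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
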