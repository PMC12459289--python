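import numpy as np
import pytest

from preboq.shin_metiu import ShinMetiuParameters, build_model, compute_integrals
from preboq.workbench import expansion_from_model, generate_fixture
from preboq.vibronic_hamiltonian import build_hamiltonian
from preboq.cmqb_mapping import assemble_cmqb


@pytest.fixture(scope="session")
def random_model():
    """Seeded random vibronic fixture: expansion, modes, assembled Hamiltonians."""
    model = generate_fixture("random-vibronic", seed=3)
    expansion, modes = expansion_from_model(model)
    sq = build_hamiltonian(expansion, modes)
    ham = assemble_cmqb(sq)
    layout = modes.layout(ham.n_qubits)
    return {"expansion": expansion, "modes": modes, "sq": sq, "ham": ham,
            "layout": layout}


@pytest.fixture(scope="session")
def charge_transfer_model():
    """The default single-mode charge-transfer model (grid pipeline, built once)."""
    fit_report = {}
    params = ShinMetiuParameters()
    expansion, table = compute_integrals(params, fit_report=fit_report)
    model = build_model(params, expansion=expansion, orbital_table=table)
    model.fit_report = fit_report
    return model


@pytest.fixture(scope="session")
def exact_eigensystem(charge_transfer_model):
    """Dense eigendecomposition of the model Hamiltonian, shared across tests."""
    sm = charge_transfer_model
    H = sm.hamiltonian.to_matrix(sm.layout)
    w, v = np.linalg.eigh(H)
    return w, v


@pytest.fixture(scope="session")
def exact_state_at(charge_transfer_model, exact_eigensystem):
    """Callable returning the exactly propagated model state at time t."""
    sm = charge_transfer_model
    w, v = exact_eigensystem
    c0 = v.conj().T @ sm.initial_state.amplitudes

    def _at(t):
        return v @ (np.exp(-1j * w * t) * c0)

    return _at
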