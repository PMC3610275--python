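import numpy as np
import pytest

from gpcrgeom.synthetic_structures import (
    EnsembleSpec,
    PeptideSpec,
    build_peptide,
    perturb_ensemble,
)


@pytest.fixture(scope="session")
def ideal_helix_spec():
    return PeptideSpec(sequence="A" * 25, phi=-57.0, psi=-47.0)


@pytest.fixture(scope="session")
def ideal_helix(ideal_helix_spec):
    return build_peptide(ideal_helix_spec)


@pytest.fixture(scope="session")
def caap_helix():
    """25-mer with a central CAAP motif, Cys chi1 at -60 (g+)."""
    seq = "A" * 10 + "CAAP" + "A" * 11
    spec = PeptideSpec(sequence=seq, chi1_targets={10: -60.0})
    return build_peptide(spec)


@pytest.fixture(scope="session")
def small_ensemble():
    spec = EnsembleSpec(
        base=PeptideSpec(sequence="A" * 25),
        n_frames=25,
        noise_sigma=0.05,
        seed=1234,
    )
    return perturb_ensemble(spec)


def parametric_helix(n_residues=25, residues_per_turn=3.6, radius=2.3, rise=1.5):
    """C-alpha trace of a mathematically exact helix (analysis-independent)."""
    t = np.arange(n_residues) * 2.0 * np.pi / residues_per_turn
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), rise * np.arange(n_residues)]
    )
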