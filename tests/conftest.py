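import numpy as np
import pytest

from pepmicelle.core import Ensemble
from pepmicelle.synthetic import AVP_SEQUENCE, BuildSpec, build_peptide, jittered_ensemble


def peptide_with_angles(angles, sequence=AVP_SEQUENCE):
    """Build a peptide realising the given per-residue (phi, psi, omega)."""
    return build_peptide(BuildSpec(sequence=sequence, angles=angles))


def turn_angles(phi1, psi1, phi2, psi2, start=6):
    """Extended-chain angle list with one planted turn at residues
    start..start+3 (the turn torsions land on residues start+1, start+2)."""
    ext = (-120.0, 130.0, 180.0)
    angles = [list(ext) for _ in range(9)]
    angles[start] = [phi1, psi1, 180.0]
    angles[start + 1] = [phi2, psi2, 180.0]
    # pull psi(start-1)/(start) off the extended value so CA distances close
    angles[start - 1][1] = 0.0
    return [tuple(a) for a in angles]


@pytest.fixture(scope="session")
def helix():
    """Single-conformation nonapeptide built at (-57, -47)."""
    angles = [(-57.0, -47.0, 180.0)] * 9
    topo, conf = peptide_with_angles(angles)
    return topo, conf


@pytest.fixture(scope="session")
def helix_ensemble(helix):
    topo, conf = helix
    return jittered_ensemble(topo, conf, n_frames=20, sigma=0.05, seed=11)


@pytest.fixture()
def single_frame_ensemble(helix):
    topo, conf = helix
    return Ensemble(topo, [conf])


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
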