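"""Shared fixtures: synthetic complexes reused across the suite.

Expensive constructions (footprint-calibrated toy dimers, the fitted and
closed template models) are session-scoped so each is built exactly once.
"""

import numpy as np
import pytest

from wingdock.fixtures import (ToyDimerSpec, make_promoter_sequence,
                               make_template_complex, make_toy_dimer_complex,
                               make_toy_dimer_protein, make_toy_monomer)
from wingdock.templates import fit_monomer, restraints_from_template

# sampling density used throughout the tests: coarse enough to be fast,
# fine enough for the ~1% analytic agreement checked explicitly elsewhere
N_POINTS = 240


@pytest.fixture(scope="session")
def template():
    return make_template_complex()


@pytest.fixture(scope="session")
def toy_monomer():
    return make_toy_monomer()


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer_protein()


@pytest.fixture(scope="session")
def fitted(template, toy_monomer):
    monomer, motif = toy_monomer
    return fit_monomer(monomer, motif, template)


@pytest.fixture(scope="session")
def template_restraints(fitted):
    return restraints_from_template(fitted)


@pytest.fixture(scope="session")
def sphere_model():
    """Sphere-pair toy dimer on a 44 bp duplex plus its custom radii set."""
    spec = ToyDimerSpec(envelope="sphere-pair", atom_radius=8.0, standoff=1.0)
    return make_toy_dimer_complex(spec, "AT" * 22)


@pytest.fixture(scope="session")
def footprint_models():
    """Toy dimers calibrated to footprints of 5, 11 and 21 bp."""
    out = {}
    for w in (5, 11, 21):
        out[w] = make_toy_dimer_complex(ToyDimerSpec(footprint_bp=w), "AT" * 20,
                                        n_points=N_POINTS)
    return out


@pytest.fixture(scope="session")
def promoter_fixture():
    """Divergent promoter with planted −10/−35/extended−10 boxes and AT run."""
    return make_promoter_sequence(
        length=300,
        planted=[
            ("TGATAAGCT", "right", -15),   # extended −10: TGn + the −10 hexamer
            ("TTGACT", "left", -35),       # −35 box, one mismatch to consensus
            ("TATTCT", "left", -12),       # left gene's −10 box
        ],
        at_run=(40, 30),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
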