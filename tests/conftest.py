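"""Shared fixtures: one standard toy complex and its protonated form."""

from __future__ import annotations

import warnings

import pytest

from ppargpharm import protonation, synthetic_data as sd


STANDARD_SPEC = sd.ToyComplexSpec(
    pocket=(sd.PocketContact("LEU", 4.0), sd.PocketContact("PHE", 4.2)),
    hbonds=(sd.HBondPlant("SER", "donor", "O20", 2.8),
            sd.HBondPlant("TYR", "donor", "O40", 3.0)),
    water_bridges=(sd.WaterBridgePlant("THR", "O20", 2.8, 2.8),),
    decoys=2,
)


@pytest.fixture(scope="session")
def toy_complex():
    return sd.make_toy_complex(STANDARD_SPEC, seed=7)


@pytest.fixture(scope="session")
def toy_protonated(toy_complex):
    model, manifest = toy_complex
    assignment = protonation.assign_ionization(model)
    return protonation.place_polar_hydrogens(model, assignment), manifest


@pytest.fixture()
def annotated_ligand_factory():
    def _make(fragments, anchors=None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sd.make_annotated_ligand(fragments, anchors=anchors)
    return _make
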