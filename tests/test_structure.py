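import numpy as np
import pytest

import bestqspr as bq
from bestqspr.structure import (
    LocationCutoffs,
    OutOfModelError,
    classify_variant_location,
    interface_residues,
    load_structure,
    site_proximity,
)
from bestqspr.variants import ProteinVariant


def variant_at(pos):
    return ProteinVariant("Ala", pos, "Gly")


def test_fixture_loads_with_planted_ions(ring_structure):
    model, _ = ring_structure
    assert sorted(model.chains) == ["A", "B", "C", "D", "E"]
    species = [i.species for i in model.ions]
    assert species.count("Ca2+") == 5
    assert species.count("K+") == 5
    assert species.count("Cl-") == 1
    # the pore axis recovered from the atom cloud is the construction z axis
    assert abs(model.axis_direction[2]) == pytest.approx(1.0, abs=1e-2)


def test_classification_matches_planted_ground_truth(ring_structure):
    model, truth = ring_structure
    for cid, labels in truth["labels"].items():
        for seqid, expected in labels.items():
            got = classify_variant_location(model, variant_at(seqid), chain=cid)
            assert got.labels == expected, f"{cid}{seqid}"


def test_interface_symmetry(ring_structure):
    model, _ = ring_structure
    # chain A's arm (residue 7) touches chain B's column (residue 4)
    assert interface_residues(model, "A", "B") == {7}
    assert interface_residues(model, "B", "A") == {4}


def test_interface_zero_or_tiny_cutoff_empty(ring_structure):
    model, _ = ring_structure
    assert interface_residues(model, "A", "B", cutoff=0.0) == set()
    assert interface_residues(model, "A", "C", cutoff=5.0) == set()  # distant pair


def test_unknown_chain_raises(ring_structure):
    model, _ = ring_structure
    with pytest.raises(KeyError):
        interface_residues(model, "A", "Z")


def test_labels_monotone_in_cutoffs(ring_structure):
    model, _ = ring_structure
    small = LocationCutoffs(interface=3.0, ion=2.0, pore=5.0)
    big = LocationCutoffs(interface=6.0, ion=10.0, pore=20.0)
    for seqid in range(1, 8):
        a = classify_variant_location(model, variant_at(seqid), small).labels
        b = classify_variant_location(model, variant_at(seqid), big).labels
        assert a - {"other"} <= b


def test_site_proximity_reports_owning_chain(ring_structure):
    model, _ = ring_structure
    # the calcium clasp by chain A's residue 3 belongs to neighbour chain B
    prox = site_proximity(model, ("A", 3), "Ca2+")
    assert prox.within and prox.owning_chain == "B"
    assert prox.distance == pytest.approx(2.5, abs=0.1)
    far = site_proximity(model, ("A", 2), "Ca2+", cutoff=8.0)
    assert not far.within and far.distance > 8.0


def test_absent_species_is_not_applicable(tmp_path):
    path = tmp_path / "ring3.pdb"
    bq.make_fixture_structure(3, seed=1, path=path)
    model = load_structure(path)
    model.ions = [i for i in model.ions if i.species != "Cl-"]
    prox = site_proximity(model, ("A", 1), "Cl-")
    assert not prox.applicable


def test_out_of_model_position_raises(ring_structure):
    model, _ = ring_structure
    with pytest.raises(OutOfModelError):
        classify_variant_location(model, variant_at(400))


def test_single_chain_loads_without_interfaces(tmp_path):
    path = tmp_path / "mono.pdb"
    bq.make_fixture_structure(1, seed=0, path=path)
    model = load_structure(path)
    assert list(model.chains) == ["A"]
    loc = classify_variant_location(model, variant_at(4))
    assert not any(l.startswith("interface") for l in loc.labels)


def test_deterministic_for_fixed_config(ring_structure):
    model, _ = ring_structure
    a = classify_variant_location(model, variant_at(5))
    b = classify_variant_location(model, variant_at(5))
    assert a.labels == b.labels and a.distances == b.distances


def test_consequence_lookup(ring_structure):
    model, _ = ring_structure
    loc = classify_variant_location(model, variant_at(7), chain="A")
    assert "channel formation and stability" in loc.consequences
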