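import numpy as np
import pytest

from topopalm.features import featurize_proteome
from topopalm.model import Hyperparams, PalmSiteModel
from topopalm.simulate import SynthParams, generate_proteome, plant_labels
from topopalm.topology import (
    ProteinRecord,
    SegmentKind,
    TopologySegment,
    assign_tm_orientation,
)


def make_protein(accession, sequence, spans, species="synthetic"):
    """Build a record from (kind, start, end) triples with orientations set."""
    segments = assign_tm_orientation(
        [TopologySegment(kind=k, start=a, end=b) for k, a, b in spans]
    )
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        segments=tuple(segments),
        species=species,
    )


@pytest.fixture(scope="session")
def toy_protein():
    """Single-pass protein: Extracellular 1-50, inward TM 51-71, Cyto 72-120.

    Cysteines at 30 (extracellular), 60 (in-TM), 75 (juxtamembrane
    cytoplasmic) and 100 (deep cytoplasmic).
    """
    seq = list("A" * 120)
    for pos in (30, 60, 75, 100):
        seq[pos - 1] = "C"
    for i in range(50, 71):  # hydrophobic TM core
        if seq[i] == "A":
            seq[i] = "L"
    return make_protein(
        "TOY00001",
        "".join(seq),
        [
            (SegmentKind.EXTRACELLULAR, 1, 50),
            (SegmentKind.TRANSMEMBRANE, 51, 71),
            (SegmentKind.CYTOPLASMIC, 72, 120),
        ],
    )


@pytest.fixture(scope="session")
def small_params():
    return SynthParams(n_proteins=120, seed=7)


@pytest.fixture(scope="session")
def small_proteome(small_params):
    return generate_proteome(small_params)


@pytest.fixture(scope="session")
def small_truth(small_proteome, small_params):
    return plant_labels(small_proteome, small_params)


@pytest.fixture(scope="session")
def small_features(small_proteome):
    return featurize_proteome(small_proteome)


@pytest.fixture(scope="session")
def small_labeled(small_features, small_truth):
    return small_features.features.merge(
        small_truth[["accession", "position", "label"]],
        on=["accession", "position"],
    )


@pytest.fixture(scope="session")
def small_hyperparams():
    return Hyperparams(
        interaction_depth=3,
        n_trees=150,
        shrinkage=0.1,
        min_obs_per_node=5,
        cv_folds=5,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_results(small_labeled, small_hyperparams):
    model = PalmSiteModel.from_dataframe(
        small_labeled, hyperparams=small_hyperparams
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
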