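import numpy as np
import pytest

from offscan import (
    GuideRNA,
    PlantSpec,
    ScoreTables,
    SimFeatureSpec,
    make_genome,
    plant_sites,
    random_guide,
    simulate_feature_table,
)


@pytest.fixture(scope="session")
def tables() -> ScoreTables:
    return ScoreTables.load_default()


@pytest.fixture
def guide() -> GuideRNA:
    return GuideRNA("g1", "ACGTACGTACGTACGTACGT", "TGG", cell_type="HEK293")


@pytest.fixture
def planted():
    """Small genome with planted sites of 0-6 mismatches plus the truth table."""
    g = random_guide(11, "pg", cell_type="K562")
    genome = make_genome(15_000, seed=12)
    spec = PlantSpec(
        guide=g,
        sites=[(0, "+", "GG"), (1, "-", "GG"), (3, "+", "GG"),
               (4, "-", "GG"), (6, "+", "GG")],
        seed=13,
    )
    modified, truth = plant_sites(genome, spec)
    return g, modified, truth


@pytest.fixture(scope="session")
def sim_table():
    """Imbalanced three-cell-type feature table with informative columns."""
    spec = SimFeatureSpec(
        n_rows=4000,
        seed=21,
        cell_types=[("HEK293", 0.4, 0.02), ("K562", 0.2, 0.04), ("HeLa", 0.4, 0.01)],
    )
    return simulate_feature_table(spec)


def make_site(guide: GuideRNA, positions=(), bases=None, pam=None, start=100):
    """Construct a CandidateSite for ``guide`` with mismatches at ``positions``."""
    from offscan import CandidateSite

    proto = list(guide.protospacer)
    for i, p in enumerate(sorted(positions)):
        if bases is not None:
            proto[p - 1] = bases[i]
        else:
            proto[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[p - 1]]
    site_seq = "".join(proto) + (pam or guide.pam)
    return CandidateSite(
        guide_name=guide.name,
        chrom="chr1",
        start=start,
        end=start + 23,
        strand="+",
        site_seq=site_seq,
        n_mismatch=len(positions),
        mismatch_positions=tuple(sorted(positions)),
    )
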