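import numpy as np
import pytest

from dwclens import (
    BackboneEntry,
    Catalogue,
    FixtureConfig,
    OccurrenceRecord,
    TaxonomicBackbone,
    generate_fixture,
)


def make_record(occ_id, dataset="ds1", category="pmls", name="Aequorea victoria",
                lat=None, lon=None, **kw):
    return OccurrenceRecord(
        occurrenceID=occ_id,
        datasetID=dataset,
        sourceCategory=category,
        reportedName=name,
        decimalLatitude=lat,
        decimalLongitude=lon,
        **kw,
    )


@pytest.fixture
def small_backbone():
    return TaxonomicBackbone(
        [
            BackboneEntry(
                acceptedName="Zelentia punicea",
                authority="(Korshunova, Fletcher, Lodin, Picton & Martynov, 2018)",
                phylum="Mollusca", taxonClass="Gastropoda", order="Nudibranchia",
                family="Trinchesiidae", genus="Zelentia",
                synonyms=("Cuthona punicea",),
            ),
            BackboneEntry(
                acceptedName="Tubulanus sexlineatus", authority="(Coe, 1904)",
                phylum="Nemertea", taxonClass="Anopla", order="Palaeonemertea",
                family="Tubulanidae", genus="Tubulanus",
            ),
            BackboneEntry(
                acceptedName="Oncorhynchus mykiss", authority="(Walbaum, 1792)",
                phylum="Chordata", taxonClass="Actinopteri", order="Salmoniformes",
                family="Salmonidae", genus="Oncorhynchus", isMarine=False,
            ),
        ]
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size synthetic five-source study (about 2,000 records)."""
    return generate_fixture(FixtureConfig(seed=42))


@pytest.fixture
def coord_catalogue():
    """500-record catalogue with deterministic in-range coordinates."""
    rng = np.random.default_rng(7)
    records = [
        make_record(
            f"r{i}", name="Metridium farcimen",
            lat=float(rng.uniform(-80, 80)), lon=float(rng.uniform(-170, 170)),
        )
        for i in range(500)
    ]
    return Catalogue(records)
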