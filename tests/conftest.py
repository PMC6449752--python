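import pytest
from hypothesis import HealthCheck, settings

from phatpack.fixtures import FixtureConfig, make_taxonomy_and_alignment
from phatpack.io_formats import SequenceSet, Taxopath

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> FixtureConfig:
    return FixtureConfig(
        seed=7,
        depth=3,
        branching=3,
        seqs_per_clade=4,
        alignment_length=120,
        divergence=0.05,
        diverse_divergence=0.5,
        diverse_clades=("t1",),
        gap_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(taxonomy, alignment, truth taxopaths) for a 3x3x3 synthetic study."""
    return make_taxonomy_and_alignment(small_cfg)


@pytest.fixture
def tiny_alignment() -> SequenceSet:
    return SequenceSet(
        [
            ("S1", "ACGT-"),
            ("S2", "ACGA-"),
            ("S3", "ACGC-"),
            ("S4", "ATTTA"),
        ]
    )


@pytest.fixture
def tiny_assignments() -> list[tuple[str, Taxopath]]:
    return [
        ("S1", Taxopath(("Bac", "Firm", "Clos"))),
        ("S2", Taxopath(("Bac", "Firm", "Clos"))),
        ("S3", Taxopath(("Bac", "Firm", "Bacil"))),
        ("S4", Taxopath(("Euk", "Alv"))),
    ]


@pytest.fixture
def five_tip_jplace_text() -> str:
    """Minimal valid jplace document over a 5-edge tree."""
    return """{
 "version": 3,
 "tree": "((A:0.1{0},B:0.2{1}):0.3{2},C:0.4{3}):0{4};",
 "fields": ["edge_num", "likelihood", "like_weight_ratio",
            "distal_length", "pendant_length"],
 "placements": [
  {"p": [[0, -100.0, 0.7, 0.05, 0.01], [1, -101.0, 0.3, 0.1, 0.02]],
   "nm": [["query1", 3]]},
  {"p": [[3, -90.0, 1.0, 0.2, 0.0]], "n": ["query2"]}
 ],
 "metadata": {"invocation": "test"}
}"""
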