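import pytest
from hypothesis import settings

from qtlome import GenomeAssembly, QTLRecord

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def assembly():
    return GenomeAssembly(
        "toy",
        (("chr1", 10_000_000), ("chr2", 6_000_000), ("chr3", 3_000_000)),
    )


@pytest.fixture
def Q():
    """Factory for QTL records with sensible defaults."""

    counter = {"n": 0}

    def make(
        chrom="chr1",
        start=0,
        end=1_000,
        qtl_id=None,
        trait="growth",
        study="S1",
        **kw,
    ):
        counter["n"] += 1
        return QTLRecord(
            chrom=chrom,
            start=start,
            end=end,
            qtl_id=qtl_id or f"q{counter['n']}",
            trait_name=trait,
            study_id=study,
            **kw,
        )

    return make
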