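import pytest

from svconcord.compare import MatchWindow
from svconcord.model import Breakpoint, GenomeModel, Interval, Rearrangement


@pytest.fixture
def genome() -> GenomeModel:
    """Three small chromosomes with a centromere mask on chr1."""
    return GenomeModel(
        [("chr1", 10_000_000), ("chr2", 8_000_000), ("chr3", 5_000_000)],
        masks={
            "centromere": [Interval("chr1", 4_900_000, 5_100_000)],
            "segdup": [Interval("chr2", 1_000_000, 1_050_000)],
        },
    )


@pytest.fixture
def window() -> MatchWindow:
    return MatchWindow(500)


def make_event(
    chrom1: str,
    pos1: int,
    chrom2: str | None = None,
    pos2: int | None = None,
    sv_type: str | None = None,
    support: int = 10,
    sample_id: str = "s",
    origin: str = "called",
) -> Rearrangement:
    """Event builder; defaults to an intrachromosomal DEL of 50 kb."""
    chrom2 = chrom2 or chrom1
    pos2 = pos2 if pos2 is not None else pos1 + 50_000
    if sv_type is None:
        sv_type = "CTX" if chrom1 != chrom2 else "DEL"
    return Rearrangement(
        Breakpoint(chrom1, pos1),
        Breakpoint(chrom2, pos2),
        sv_type,
        support=support,
        sample_id=sample_id,
        origin=origin,
    )
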