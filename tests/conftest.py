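import numpy as np
import pandas as pd
import pytest

from svscape.records import GenomeModel, assign_sv_ids


@pytest.fixture
def small_genome() -> GenomeModel:
    """Five 50-Mb chromosomes: big enough for realistic spans, fast to fill."""
    return GenomeModel({f"chr{i}": 50_000_000 for i in range(1, 6)})


def make_svs(rows: list[tuple]) -> pd.DataFrame:
    """Build a cohort frame from (chrom1,pos1,chrom2,pos2,type,sample) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom1", "pos1", "chrom2", "pos2", "sv_type", "sample_id"]
    )
    df["strand1"] = "+"
    df["strand2"] = np.where(df["sv_type"] == "TRA", "+", "-")
    df = df[["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
             "sv_type", "sample_id"]]
    return assign_sv_ids(df)


@pytest.fixture
def genes_bed() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": ["chr13", "chr13", "chr9"],
        "start": [48_877_911, 48_892_576, 21_967_751],
        "end": [49_056_122, 49_032_693, 21_995_300],
        "name": ["RB1", "RCBTB2", "CDKN2A"],
    })
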