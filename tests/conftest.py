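import numpy as np
import pytest

from tfse.genomic_io import CoverageTrack, SERecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_catalog():
    """Eight SEs over one toy chromosome with a 2-SE enriched tail.

    Densities are arranged so the slope-1 tangent on the density curve
    separates exactly the two high-signal SEs (checked against the
    brute-force oracle in test_enrichment).
    """
    ses = [SERecord("chrT", i * 3000, i * 3000 + 2000, f"se{i}") for i in range(8)]
    recs = []
    # background SEs: increasing numbers of above-threshold bases
    for i, n_hot in enumerate([100, 200, 300, 400, 500, 600]):
        recs.append(("chrT", ses[i].start, ses[i].start + n_hot, 30.0))
        recs.append(("chrT", ses[i].start + n_hot, ses[i].end, 5.0))
    # two enriched SEs: most bases hot
    for i in (6, 7):
        n_hot = 1500 if i == 6 else 1900
        recs.append(("chrT", ses[i].start, ses[i].start + n_hot, 60.0))
        recs.append(("chrT", ses[i].start + n_hot, ses[i].end, 5.0))
    return ses, CoverageTrack.from_records(recs)
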