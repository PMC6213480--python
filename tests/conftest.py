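import numpy as np
import pytest

from coldzyme import RateTemperaturePoint

# Published characterization of the cold-adapted leucine dehydrogenase used
# throughout as printed-input fixtures.

#: (temperature degC, kcat 1/s) turnover series
RATE_TEMPERATURE_SERIES = [(0.0, 12.25), (10.0, 14.96), (20.0, 20.20), (30.0, 30.13)]

#: substrate -> (Vm umol/min/mg, Km mM, kcat 1/s, kcat/Km mM^-1 s^-1)
SPECIFICITY_ROWS = {
    "l-leucine": (15.24, 0.33, 30.13, 91.30),
    "l-tyrosine": (13.35, 0.48, 26.39, 54.98),
    "l-proline": (10.52, 0.64, 20.80, 32.50),
    "dl-methionine": (8.38, 0.75, 16.57, 22.09),
    "l-arginine": (7.13, 0.84, 14.09, 16.77),
}


@pytest.fixture
def rate_temperature_points():
    return [RateTemperaturePoint(t, k) for t, k in RATE_TEMPERATURE_SERIES]


def random_orf(n_codons: int, seed: int) -> str:
    """A valid ORF: ATG start, TAA stop, no internal stop codons."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons - 2:
        codon = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if codon not in stops:
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"
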