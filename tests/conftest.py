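import numpy as np
import pytest

from chexfit.datamodel import ResidueID, RelaxationSeries, ShiftTable


@pytest.fixture
def rid() -> ResidueID:
    return ResidueID("A", 122, "VAL")


@pytest.fixture
def amide_shift_table() -> ShiftTable:
    """Ten residues with amide 1H/15N shifts in realistic ranges."""
    rng = np.random.default_rng(42)
    table = ShiftTable(temperature=291.0)
    for i in range(10):
        r = ResidueID("A", 101 + i, "ALA")
        table[(r, "N")] = float(rng.uniform(110, 128))
        table[(r, "H")] = float(rng.uniform(7.0, 9.5))
    return table


def make_series(rate: float, delays, amplitude: float = 1.0,
                noise: float = 0.0, seed: int = 0,
                kind: str = "T2") -> RelaxationSeries:
    rng = np.random.default_rng(seed)
    delays = np.asarray(delays, dtype=float)
    y = amplitude * np.exp(-rate * delays)
    if noise:
        y = y + rng.normal(0.0, noise * amplitude, size=len(delays))
    return RelaxationSeries(
        residue=ResidueID("A", 110, "GLN"),
        delays=delays, intensities=y,
        errors=np.full(len(delays), noise or 1e-6), kind=kind)
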