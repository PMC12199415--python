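import numpy as np
import pytest

from scans.data import AnnotatedProtein, Label, extract_segments
from scans.simulate import SimulationConfig, simulate_proteins


def make_protein(pid: str, sequence: str, annotations=()) -> AnnotatedProtein:
    """Protein with explicit (1-based position, label) annotations."""
    labels = [Label.NONFUNCTIONAL if aa in "KPRT" else Label.NOT_TARGET
              for aa in sequence]
    for pos, lab in annotations:
        labels[pos - 1] = lab
    return AnnotatedProtein(pid, sequence, labels)


@pytest.fixture(scope="session")
def small_proteins():
    cfg = SimulationConfig(n_proteins=30, length_range=(60, 120), seed=42)
    return simulate_proteins(cfg)


@pytest.fixture(scope="session")
def small_segments(small_proteins):
    return [s for p in small_proteins for rt in "KPRT"
            for s in extract_segments(p, rt, 27)]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
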