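import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isoita.seed_model import IsomiRId, IsomiRSequence, TranscriptRecord
from isoita.synthetic_data import SimulationConfig, write_fixture_bundle

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

_NTS = np.array(list("ACGU"))


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_NTS[rng.integers(0, 4, size=length)])


def random_isomir(rng: np.random.Generator, i: int = 0, length: int = 22) -> IsomiRSequence:
    return IsomiRSequence(IsomiRId(f"t-miR-{i:03d}", 0), random_rna(rng, length))


def random_transcripts(rng, n, length_range=(100, 500), utr_frac=(0.15, 0.70)):
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(
            TranscriptRecord(
                f"RT{i:04d}",
                random_rna(rng, L),
                int(round(utr_frac[0] * L)),
                int(round(utr_frac[1] * L)),
            )
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    # desk-scale configuration for pipeline-level smoke and round-trip tests
    return SimulationConfig(
        n_transcripts=200,
        n_isomirs=8,
        n_active=3,
        targets_per_isomir=8,
        nontargets_per_isomir=10,
        n_silent_transcripts=5,
        n_samples_per_group=60,
        group_labels=("LumA", "Normal"),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_cfg):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(small_cfg, outdir)
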