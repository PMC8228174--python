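import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cyclasescan import builtin_catalog


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def gc_strict(catalog):
    return catalog["GC_CORE_STRICT"]


@pytest.fixture(scope="session")
def gc_monocot(catalog):
    return catalog["GC_CORE_MONOCOT"]


@pytest.fixture
def rng():
    return np.random.default_rng(20210610)


@pytest.fixture
def fasta_file(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    def _write(records, name="input.fasta", width=60):
        path = tmp_path / name
        lines = []
        for rec_id, desc, seq in records:
            header = f">{rec_id} {desc}".rstrip()
            lines.append(header)
            for i in range(0, len(seq), width):
                lines.append(seq[i : i + width])
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
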