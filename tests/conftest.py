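import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fasta_file(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    def _write(records, name="seqs.fasta", width=60):
        from atx2kit.io import write_fasta

        path = tmp_path / name
        write_fasta(records, path, width=width)
        return path

    return _write
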