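import numpy as np
import pytest

from pcafe.io_geo import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 probes x 6 samples, alternating treated/control, times 1..8 h."""
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        values=rng.normal(size=(4, 6)),
        probe_ids=[f"p{i}" for i in range(4)],
        sample_ids=[f"s{j}" for j in range(6)],
        condition=["treated", "control"] * 3,
        time_h=np.array([1.0, 1.0, 2.0, 4.0, 4.0, 8.0]),
    )


@pytest.fixture
def series_matrix_file(tmp_path):
    """A tiny hand-written series-matrix fixture plus matching annotation."""
    path = tmp_path / "fixture_series_matrix.txt"
    path.write_text(
        "!Series_title\t\"fixture\"\n"
        "!Sample_geo_accession\t\"GSM1\"\t\"GSM2\"\n"
        "!series_matrix_table_begin\n"
        '"ID_REF"\t"GSM1"\t"GSM2"\n'
        '"1007_s_at"\t1.5\t2.5\n'
        '"1053_at"\t-0.5\t0.25\n'
        '"117_at"\t3\t4\n'
        "!series_matrix_table_end\n"
    )
    annotation = SampleAnnotation.from_rows(
        [("GSM1", "treated", 1.0), ("GSM2", "control", 2.0)]
    )
    return path, annotation


def random_expression_matrix(
    rng: np.random.Generator, n_probes: int = 30, n_samples: int = 7
) -> ExpressionMatrix:
    times = rng.choice([1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0], size=n_samples)
    while np.unique(times).size < 2:
        times = rng.choice([1.0, 2.0, 4.0, 8.0], size=n_samples)
    return ExpressionMatrix(
        values=rng.normal(size=(n_probes, n_samples)),
        probe_ids=[f"p{i}" for i in range(n_probes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        condition=["treated"] * n_samples,
        time_h=times,
    )
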