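import pytest

from ontorank.pipeline import PipelineConfig, run_benchmark
from ontorank.synthetic import SynthConfig, generate


@pytest.fixture
def write_axioms(tmp_path):
    """Write tsv_simple axiom lines to a temp file, return the path."""

    def _write(lines, name="axioms.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def pipeline_runs():
    """Memoized end-to-end benchmark runs keyed by (signal, seed, shuffled).

    The full pipeline (graph -> walks -> embeddings -> 10-fold ranking)
    is expensive, so tests that probe different properties of the same
    run share results.
    """
    cache = {}

    def run(signal: float, seed: int, shuffle_labels: bool = False):
        key = (signal, seed, shuffle_labels)
        if key not in cache:
            bundle = generate(SynthConfig(signal=signal, seed=seed))
            report, _ = run_benchmark(
                bundle, PipelineConfig(seed=seed), shuffle_labels=shuffle_labels
            )
            cache[key] = report
        return cache[key]

    return run
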