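import numpy as np
import pytest

import splicedelay as sd
from splicedelay import _solver
from splicedelay.simulate import RECOVERY_MRNA_TIMES
from splicedelay.timecourse import Series, TimeGrid


@pytest.fixture(scope="session", autouse=True)
def _warm_solver():
    # trigger the (optional) JIT compile once, outside of timed tests
    _solver.warmup()


@pytest.fixture(scope="session")
def recovery_grid() -> TimeGrid:
    return TimeGrid(np.array(RECOVERY_MRNA_TIMES))


@pytest.fixture(scope="session")
def uniform_delays() -> np.ndarray:
    return np.arange(0.0, 24.5, 0.5)


def make_linear_gene(gene_id="GLIN", beta=(2.0, -1.0), seed=0, n_points=8):
    """A gene whose transcripts are arbitrary at the knots and whose protein
    is the exact (undelayed) linear combination at the same knots: the model
    is exactly linear and piecewise-linear interpolation is exact.
    """
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, 24.0, n_points - 2))
    times = np.concatenate([[0.0], times, [24.0]])
    grid = TimeGrid(times)
    beta = np.asarray(beta, float)
    X = rng.uniform(1.0, 10.0, size=(beta.size, n_points))
    y = beta @ X + 3.0
    gene = sd.TimeSeriesGene(
        gene_id=gene_id,
        transcript_ids=tuple(f"{gene_id}.t{k+1}" for k in range(beta.size)),
        X=X,
        grid=grid,
    )
    protein = sd.ProteinSeries(
        protein_id=f"{gene_id}_P", gene_id=gene_id, y=Series(y, grid)
    )
    return gene, protein, beta


@pytest.fixture
def linear_gene():
    return make_linear_gene()


@pytest.fixture(scope="session")
def recovery_experiment(recovery_grid, uniform_delays):
    """200 simulated genes with fits and double-CV predictions.

    Shared between the parameter-recovery and model-class-ordering
    acceptance tests (the heavy part of the suite).
    """
    dataset, truths = sd.simulate_dataset(
        200,
        transcript_counts=(2, 3, 4),
        delay_choices=(0.0, 2.0, 6.0),
        noise=0.05,
        grid=recovery_grid,
        seed=123,
    )
    fits = [
        sd.fit_protein_model(g, p, uniform_delays, n_lams=12) for g, p in dataset
    ]
    oos_delayed = {}
    oos_static = {}
    for g, p in dataset:
        oos_delayed[p.protein_id] = sd.double_cv_predict(g, p, uniform_delays, 12)
        oos_static[p.protein_id] = sd.double_cv_predict(g, p, [0.0], 12)
    return dataset, truths, fits, oos_delayed, oos_static
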