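import dataclasses

import pytest

from introskim import pipeline, synthetic
from introskim.genome import Chromosome, GenomeSpec, make_windows


@pytest.fixture(scope="session")
def full_spec():
    """The 28-chromosome miniature genome (21 wheat + 7 alien, 100 Mb each)."""
    return synthetic.default_genome()


@pytest.fixture(scope="session")
def full_grid(full_spec):
    return make_windows(full_spec)


@pytest.fixture(scope="session")
def mini_spec():
    """One homoeologous group with uneven chromosome lengths."""
    return GenomeSpec(
        [
            Chromosome("1A", 5_500_000, "A", 1),
            Chromosome("1B", 5_000_000, "B", 1),
            Chromosome("1D", 4_200_000, "D", 1),
            Chromosome("1T", 6_000_000, "T", 1),
        ]
    )


@dataclasses.dataclass
class Panel:
    cfg: synthetic.SimConfig
    parents: list
    lines: list
    grid: object
    truth: synthetic.TruthSet
    result: pipeline.PanelAnalysis
    evaluation: synthetic.EvalResult


def _build_panel(seed: int, null: bool = False) -> Panel:
    cfg = synthetic.default_panel(seed)
    if null:
        cfg.events = []
    parents, lines, grid, truth = synthetic.simulate_panel(cfg)
    result = pipeline.analyse_panel(parents, lines, cfg.spec, grid)
    evaluation = synthetic.evaluate_calls(
        result.events, truth, grid, result.leftover_duplications
    )
    return Panel(cfg, parents, lines, grid, truth, result, evaluation)


@pytest.fixture(scope="session")
def default_panel_run():
    """Default synthetic study panel, simulated and fully analysed (seed 1)."""
    return _build_panel(1)


@pytest.fixture(scope="session")
def build_panel():
    return _build_panel
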