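"""Shared configuration for the numbered analysis scripts.

The demo study is a single active mark ("H3K27ac") in one synthetic cell
type, 400 genes on 8 chromosomes with 1-2 planted enhancers per gene —
large enough to train both models meaningfully, small enough to run the
whole pipeline in a couple of minutes on one CPU.
"""

from pathlib import Path

from epitx.experiments import prepare_bundle
from epitx.models import DistalModelConfig, PromoterModelConfig, TrainingSchedule
from epitx.synthetic import SyntheticConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA_DIR = RESULTS / "data"
MODEL_DIR = RESULTS / "models"

SEED = 7
MARK = "H3K27ac"


def demo_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=SEED, n_genes=400, n_chromosomes=8, enhancers_per_gene=(1, 2),
        noise_sd=0.3, cell="C1",
    )


def demo_bundle():
    return prepare_bundle(demo_config(), mark=MARK)


def promoter_config() -> PromoterModelConfig:
    return PromoterModelConfig(seed=SEED)


def distal_config(seed: int = SEED) -> DistalModelConfig:
    return DistalModelConfig(seed=seed)


def schedule() -> TrainingSchedule:
    return TrainingSchedule(max_epochs=60)
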