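"""Connectionist agents learning 2x2 games, and what they transfer to new games.

Populations of small feedforward networks repeatedly play randomly drawn
2x2 normal-form games, learning online toward the ex-post best response to
each opponent's realized action.  Training a population on one strategic
class of games (zero-sum, Prisoner's dilemma, stag hunt, ...) and then
freezing it on test games from other classes measures transfer of
learning: how much of the learned behavior reflects the deep strategic
structure of games versus superficial payoff similarity.
"""

from .games import (
    ALL,
    GAME_CLASSES,
    TRAINING_CLASSES,
    Game2x2,
    EquilibriumReport,
    TransformStep,
    build_transform_loop,
    classify_game,
    classify_games,
    default_transform_bases,
    dominance_analysis,
    dominance_labels,
    equilibrium_report,
    generate_game,
    generate_games,
    mixed_nash,
    pure_nash,
)
from .agents import (
    AgentNet,
    Population,
    encode_perspective,
    expost_best_response,
    sample_action,
)
from .engine import (
    SimulationConfig,
    TrainingResult,
    Evaluation,
    run_training,
    evaluate_frozen,
    run_grid,
)
from .analysis import (
    agent_similarity,
    cross_training_correlation,
    payoff_table,
    psne_attainment,
    equilibrium_selection,
    transform_profile,
)
from .config import ExperimentManifest, load_config, replicate_study

__version__ = "0.1.0"

__all__ = [
    "ALL",
    "GAME_CLASSES",
    "TRAINING_CLASSES",
    "Game2x2",
    "EquilibriumReport",
    "TransformStep",
    "build_transform_loop",
    "classify_game",
    "classify_games",
    "default_transform_bases",
    "dominance_analysis",
    "dominance_labels",
    "equilibrium_report",
    "generate_game",
    "generate_games",
    "mixed_nash",
    "pure_nash",
    "AgentNet",
    "Population",
    "encode_perspective",
    "expost_best_response",
    "sample_action",
    "SimulationConfig",
    "TrainingResult",
    "Evaluation",
    "run_training",
    "evaluate_frozen",
    "run_grid",
    "agent_similarity",
    "cross_training_correlation",
    "payoff_table",
    "psne_attainment",
    "equilibrium_selection",
    "transform_profile",
    "ExperimentManifest",
    "load_config",
    "replicate_study",
]
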