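"""Shared study configuration for the numbered analysis drivers.

Every driver regenerates its inputs deterministically from SEED through the
library (the seed offsets match riversdm.pipeline.run_pipeline), so each
script can be run on its own; fitted-model outputs are written once by
04_fit_and_project.py and read back by 05_report.py.
"""

from pathlib import Path

from riversdm import pipeline

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

#: desk-scale study conditions: 500 reaches, 30 virtual species, 300 survey
#: sites, 50 community cross-validation splits
CONFIG = pipeline.PipelineConfig(
    n_reaches=500,
    n_species=30,
    n_sites=300,
    n_splits=50,
    n_trees=300,
    n_anchors=100,
    min_occurrences=25,
)


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS


def scratch() -> Path:
    """Bulky per-reach intermediates live outside the deliverable tables."""
    SCRATCH.mkdir(exist_ok=True)
    return SCRATCH
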