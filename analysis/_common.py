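"""Shared paths and dataset handling for the numbered analysis scripts.

The simulated raw data (FASTA, hit tables, per-contig tables) is bulky
and lives under scratch/; each script regenerates it deterministically
from the committed config when missing. Small summary tables go under
results/tables/.
"""

from pathlib import Path

from salivome.synthetic_data import GeneratorConfig

REPO = Path(__file__).resolve().parent.parent
SCRATCH_DATA = REPO / "scratch" / "data"
TABLES = REPO / "results" / "tables"
CONFIG_PATH = REPO / "results" / "config.yaml"

#: study conditions of the simulated comparison
DEFAULT_CONFIG = GeneratorConfig(n_genes=5000, seed=1)


def load_config() -> GeneratorConfig:
    if CONFIG_PATH.exists():
        return GeneratorConfig.from_yaml(CONFIG_PATH)
    return DEFAULT_CONFIG


def ensure_dirs() -> None:
    SCRATCH_DATA.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
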