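"""Shared constants for the analysis drivers: seed, paths, study design."""

from pathlib import Path

from poolseq_assoc import SimulationConfig

SEED = 1

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
OUT_DIR = ROOT / "results"

#: the emulated study design: 3 collections x 2 phenotypes x 2 replicate
#: pools of 25 females; 100 genes on 3 chromosomes, 20 causal at delta 0.35
STUDY_CONFIG = SimulationConfig(seed=SEED)

COLLECTIONS = ("VCP", "VCD", "VeP")
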