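"""Shared locations for the analysis drivers.

Regenerable bulk intermediates (PLINK binaries, per-SNP posterior tables)
live under scratch/; compact summary tables go to results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(parents=True, exist_ok=True)

# study conditions shared by every driver
H2 = 0.44            # liability heritability of the simulated score
SEED = 20250927
N_ANIMALS = 800
TRAIT = "score"
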