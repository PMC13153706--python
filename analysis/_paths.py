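"""Shared locations for the analysis scripts.

Large intermediates (genome, database, per-peptide tables) live under
scratch/; small summary tables go to results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

MASTER_SEED = 17

for _d in (SCRATCH, RESULTS):
    _d.mkdir(parents=True, exist_ok=True)
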