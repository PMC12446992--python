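"""Shared locations and study conditions for the numbered analysis scripts.

The synthetic study emulates the real design: a plant-like query organism
(2,000 CDS, 200 of them planted with codon usage mixed toward the partner at
lambda = 0.9), a bacterium-like partner organism (2,000 CDS), a four-group x
three-replicate count matrix with 200 genes planted on the rescue pattern
(up under calcium stress, restored by the bacterium), fabricated DEG tables
for one contrast, and a Ct table with known fold changes.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

SEED = 2025
N_GENES = 2000
N_PLANTED = 200
LAMBDA = 0.9
RESCUE_PATTERN = (0, 0, 1, 0)
EFFECT = 2.0
DISPERSION = 0.1


def require_dataset() -> Path:
    if not (DATA / "truth.json").exists():
        raise SystemExit(
            "synthetic dataset not found - run `python analysis/01_simulate_data.py` first"
        )
    return DATA
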