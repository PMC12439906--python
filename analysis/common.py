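"""Shared settings for the numbered analysis drivers."""

from pathlib import Path

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

CONDITIONS = [
    ("parental", "vehicle"),
    ("CANX_KO", "vehicle"),
    ("parental", "VX445"),
    ("CANX_KO", "VX445"),
]
N_VARIANTS = 60
N_REPLICATES = 3
CELLS_PER_POOL = 40_000
READS_PER_FRACTION = 40_000
KO_ATTENUATION = 0.26
CORRECTOR_FOLD = 2.0
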